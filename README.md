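# tisk

An interactive-activation simulator of spoken word recognition built on
**time-invariant string-kernel (open-diphone) coding**, with optional
**lexical feedback** from words to sublexical units.

## The problem and the model

Speech unfolds in time, so a model of spoken word recognition must encode
*order* (/kæt/ CAT vs. /tæk/ TACK vs. /ækt/ ACT) and *repetition* (/sol/
SOUL vs. /solo/ SOLO) without giving every phoneme and word a copy at every
point in time. This package implements the TISK family of models, which
solves the sequence-encoding problem with **ordered open diphones**: a word
is coded by the multiset of all ordered phoneme pairs it contains, at any
separation. For a word *w* of length *n* the code is the phoneme × phoneme
count matrix

    C[x, y] = #{ (i, j) : i < j, w[i] = x, w[j] = y },     Σ C = n(n−1)/2,

a string kernel that represents words of any length in a fixed dimension.
The dynamic variant grades each pair by its gap and order,

    weight(x, y) = Σ_{i<j, w[i]=x, w[j]=y} γ^(j−i−1)  +  ρ · Σ_{reversed} γ^(j−i−1),

with gap decay γ = 0.5 and reverse-order attenuation ρ = 0.1 by default, so
/st/ is activated more by STOP than by SPOT, and /sa/ more by *sock* than
*stock* than *strong*.

The network has three layers updated synchronously, cycle by cycle:

* a **time-specific input layer** (phoneme × temporal slot) that latches
  the stimulus amplitude while it is presented (one phoneme per slot, 10
  cycles per phoneme) and decays afterwards;
* a **time-invariant N-phone layer** of single-phone nodes plus one node
  per ordered diphone, driven through a gated symmetry mapping (a diphone
  receives input while its later member is being stimulated, scaled by
  γ^gap and ρ for reversed order);
* a **word layer** with lateral inhibition, receiving each word's graded
  diphone weights and single-phone support, with the standard
  interactive-activation saturating update.

With feedback enabled, each word sends positive support to its constituent
N-phones — gated by the bottom-up evidence a node has received, so
top-down support can amplify but never hallucinate — and weak negative
feedback to all other N-phones. A word is *recognized* at the first cycle
where its activation exceeds every other word's by ≥ 0.05, holds that
margin for 10 cycles, and stays the most active word to the end of the
trial.

Three shipped parameter presets (`ORIGINAL`, `OPT_NOFB`, `OPT_FB`)
correspond to the original no-feedback parameterization, parameters
re-optimized for noise robustness without feedback, and parameters
optimized for running with feedback.

## The five experiments

| harness | question |
| --- | --- |
| `sim1_timecourse` | time course of target / cohort / rhyme competition; RT correlates of lexical dimensions |
| `sim2_ganong` | lexical shifts of phoneme-continuum identification (Ganong effect) |
| `sim3_right_context` | retroactive disambiguation of an ambiguous /p/–/b/ onset by the final phoneme |
| `sim4_restoration` | phoneme restoration: noise restores a replaced phoneme, silence does not |
| `sim5_noise_sweep` | graceful vs. catastrophic degradation of accuracy under input noise |

Because the classic 211-word lexicon is distributed separately, a seeded
synthetic-lexicon generator with controllable cohort / rhyme / embedding
densities makes every experiment self-contained.

## Worked example

```python
from tisk import (build_network, ganong_lexicon, preset, recognition_time,
                  run_trial, word_schedule)

lexicon = ganong_lexicon()                  # ten 4-phoneme probe words
params = preset("OPT_FB")                   # feedback-optimized parameters
network = build_network(lexicon, params=params)

schedule = word_schedule(lexicon.phonemes("duty"), params)
trace = run_trial(network, schedule, feedback_on=True)
outcome = recognition_time(trace, "duty")
print(f"recognized={outcome.recognized} rt_cycle={outcome.rt_cycle}")
print(f"final duty activation: {trace.word_activation('duty')[-1]:.3f}")
```

prints

```
recognized=True rt_cycle=15
final duty activation: 0.622
```

— /duti/ is presented one phoneme per 10 cycles; by cycle 15 the word node
for *duty* leads every competitor by the 0.05 margin and keeps the lead,
settling at activation 0.62 while feedback sustains its constituent
N-phones. The encoding itself is available from the shell:

```
$ tisk encode --word solo
lo      1
ol      1
oo      1
sl      1
so      2
```

showing SOLO's repeated /o/ yielding the multiplicity-2 /so/ entry. The
experiment harnesses are also CLI subcommands, e.g.

```
tisk sim4 --preset OPT_FB --out out/sim4
tisk sim5 --synthetic 50 --runs 5 --levels 0.0,0.05,0.10,0.15 --out out/sim5
```

each writing tidy CSV tables plus a `run_metadata.json` sidecar.

## Documentation

`docs/methods.md` describes the model equations, the parameter presets,
the synthetic-lexicon generator and its limits, and the numerical design
choices in detail.
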