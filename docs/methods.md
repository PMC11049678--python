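# Methods

## Representation: ordered open diphones

A word over a closed phoneme inventory is coded by its **ordered open
diphones**: every pair of phonemes `(w[i], w[j])` with `i < j`, adjacent or
not. The plain code counts occurrences (`open_diphones`); the graded code
(`graded_weights`) weights each occurrence by `γ^(j−i−1)` — an adjacent
ordered pair contributes exactly 1 — and credits the reversed pair with a
factor `ρ` of the same amount:

    weight(x, y) = Σ_{i<j, w[i]=x, w[j]=y} γ^(j−i−1) + ρ · Σ_{i<j, w[i]=y, w[j]=x} γ^(j−i−1)

Defaults `γ = 0.5`, `ρ = 0.1` (both exposed in `TISKParams`). Only the
ordinal contract is fixed by the modeling literature — ordered pairs
dominate reversed ones, and weight decreases with gap — so the exponential
form and the two constants are this package's choices; both are
property-tested against an independent index-pair oracle.

## Network architecture and update equations

Three layers; all updates are synchronous from a pre-update snapshot, and
only supra-rest activation is transmitted (`f(a) = max(a − rest, 0)`).
Bounds are `act_min = 0`, `rest = 0`, `act_max = 1`.

**Input layer** — time-specific nodes, one per (phoneme, slot). A word
schedule presents phoneme `s` with amplitude 1.0 during cycles
`[10s, 10s+10)` (cycles-per-phoneme and slot count are configurable;
defaults 10 and 10, trial length 100 cycles). While a schedule entry is
nonzero the node *latches* that amplitude; otherwise it decays by
`input_phoneme_decay` per cycle. Latching (rather than additive
integration) keeps the node's activation equal to the stimulus amplitude,
which is what makes blended stimuli (e.g. a 50/50 /p/–/b/ mixture) and
noise tokens graded instead of everything saturating; the slowly decaying
latched value serves as the model's sensory memory of earlier slots.

**N-phone layer** — `P` single-phone nodes plus `P²` diphone nodes, decay
`nphone_decay`. On cycle `t` with stimulus matrix `E_t` and input-layer
snapshot `A`:

* diphone `(x, y)` receives
  `w_phoneme_to_nphone · (M + ρ·Mᵀ)[x, y]`, where
  `M[x, y] = Σ_{i<j} A[x, i] · γ^(j−i−1) · E_t[y, j]` — the later member
  must be *currently* stimulated (the gating half of the symmetry mapping),
  the earlier member is read from sensory memory. This realizes the graded
  code dynamically: after a clean word presentation, diphone drive is
  proportional to the word's graded weights.
* single phone `p` receives `w_phoneme_to_nphone · Σ_s f(A[p, s])` —
  single phones are time-invariant copies of the input and track it
  continuously.

**Word layer** — one node per lexicon entry, decay `word_decay`, with the
standard interactive-activation saturating update:

    a ← clip( a·(1 − word_decay) + exc·(act_max − a) + inh·(a − act_min) )

`exc` is the word's bottom-up input: its graded diphone weights times
diphone activations (`w_diphone_to_word`) plus binary-per-type single-phone
support (`w_singlephone_to_word`). `inh = w_word_word_inhibition · Σ_{j≠i}
f(a_j)` (not normalized by competitor count). Scaling excitation by
headroom and inhibition by distance-from-floor makes equilibrium activation
graded in net input, which the recognition margin requires; with a hard
clip instead, every strongly driven word pins at the ceiling and no margin
can form.

Two normalizations proved necessary and are part of the design:

* **Diphone→word weights are normalized** by the word's total ordered
  grade sum, rescaled to a 4-phoneme reference word. Words then compete on
  the *fraction* of their ordered structure matched; without this, raw
  pair counts grow quadratically with length and long words win every
  trial.
* **Single-phone support is binary per phoneme type** (not per
  occurrence). Single phones are order-blind and persistent, so
  per-occurrence counting hands words with repeated phonemes a permanent
  advantage that eventually overtakes any target.

**Lexical feedback** (the structural addition this package exists to
study) runs from words to *all* N-phones when enabled:

* **Positive feedback** to a word's constituents (its phonemes and its
  ordered diphones), strength `fb_positive`, scaled by three factors:
  the activation of the **most active containing word** (winner-dominated:
  a coalition of weakly active words must not outvote the winner), the
  receiver's **bottom-up evidence trace**, and the receiver's headroom
  `(act_max − a)`.
* **Negative feedback** to every non-constituent, strength `fb_negative`,
  summed over all non-containing words and scaled by the receiver's own
  activation (shunting, so it cannot push below the floor).

The evidence trace is the pooled input-layer activation for single phones,
and a leaky integral (leak `input_phoneme_decay`, clipped to [0, 1]) of the
gated coincidence drive for diphones. Evidence gating is the mechanism
behind the restoration asymmetry: noise provides bottom-up evidence that
feedback amplifies and sustains, while a silent gap provides none, so the
expected phoneme stays exactly at rest no matter how active its word
becomes. Setting `fb_gated=False` switches to plain additive feedback for
comparison; in that regime silence-replaced phonemes are restored to
ceiling and feedback destabilizes recognition under noise, which is why
gating is the default.

## Parameter presets

All rates are per cycle; weights are dimensionless connection strengths.

| parameter | ORIGINAL | OPT_NOFB | OPT_FB |
| --- | --- | --- | --- |
| input_phoneme_decay | 0.010 | 0.001 | 0.001 |
| nphone_decay | 0.001 | 0.001 | 0.100 |
| word_decay | 0.010 | 0.050 | 0.050 |
| w_phoneme_to_nphone | 1.000 | 0.100 | 0.100 |
| w_diphone_to_word | 0.050 | 0.050 | 0.050 |
| w_singlephone_to_word | 0.010 | 0.010 | 0.010 |
| w_word_word_inhibition | −0.005 | −0.005 | −0.010 |
| fb_positive | 0 | 0 | 0.150 |
| fb_negative | 0 | 0 | −0.050 |

`ORIGINAL` is the historical no-feedback parameterization; `OPT_NOFB`
re-optimizes the feedforward model for noise robustness; `OPT_FB` carries
the feedback weights plus the higher N-phone decay and stronger lateral
inhibition that keep word–N-phone resonance from running away. The high
`w_phoneme_to_nphone` of `ORIGINAL` saturates N-phones on any input, which
is what makes it collapse under noise (the catastrophic-degradation
baseline).

## Recognition criterion

`recognition_time` returns the first cycle `c` such that the target's
margin over the *maximum* competitor is ≥ 0.05 (threshold) at every cycle
in `[c, c+10)` (hold window, first cycle included), and the target is the
strict argmax from `c+10` to the end of the trial. Ties count against
recognition. Raising the threshold or lengthening the hold can only delay
or abolish recognition (property-tested), and the scanner is tested for
exact agreement with a brute-force triple loop on 1000 random traces.

## Stimulus degradation

* **Blends**: at one slot, the two endpoint phonemes receive `1−α` and `α`
  (7-step continua, α = 0 … 1, by default; the center step is α = 0.5).
* **Silence**: the slot's active cycles are zeroed.
* **Noise replacement**: the slot is zeroed, then i.i.d. Gaussian(0, sd)
  drive is added to *every* phoneme node at that slot, truncated at 0
  (inputs are nonnegative evidence). One draw per (phoneme, slot) held
  constant over the slot's 10-cycle block by default (`per_cycle=True`
  redraws each cycle).
* **Global noise** (the degradation sweep): the same per-block scheme
  applied to every occupied slot, added on top of the intact word; values
  may exceed 1 (no upper truncation of inputs; node activations still clip
  at `act_max`).

All draws are seeded; per-trial seeds derive from a master seed and stable
integer keys via `numpy.random.SeedSequence`, so experiments are
bit-reproducible and noise tokens can be shared across conditions. The
restoration experiment reuses one token per (item, SD) across positions
and feedback settings, so condition contrasts are paired.

## The synthetic-lexicon generator

The generator emulates the *structure* of the classic 211-word
interactive-activation lexicon: 2–9-phoneme words over a 14-symbol
inventory with controllable densities of cohorts (shared first two
phonemes), rhymes (same length, first phoneme differs), and embeddings
(one word a contiguous substring of another). Density is the proportion of
words with at least one classmate. Words are added one at a time, derived
from an existing word for whichever class is furthest below target, with
rejection sampling against overshooting met targets; generation is
deterministic under the spec's seed, strings are unique, and achieved
densities land within ±50 % relative of feasible targets (tested).

What it does **not** emulate: English phonotactics, word frequency, the
length distribution of real vocabularies, or natural co-occurrence of
competitor types. Random 14-symbol strings are far denser in accidental
structure than English words, so absolute accuracy on synthetic lexicons
(~0.8 noise-free at 50 words with the optimized presets) is expected to be
below the published values for the English lexicon; tests on synthetic
lexicons therefore check *ordinal* patterns (who beats whom, what rises
and falls with noise), not absolute accuracies. The checks that do pin
absolute accuracy activate only when the external lexicon file is
supplied.

## Default problem sizes

Simulations 1–4 run at their full published designs (they are small: one
trial per word; 10 words × 4 positions × 7 steps × 2 feedback settings for
the Ganong continua; 480 trials for restoration). The degradation sweep
defaults to a 50-word synthetic lexicon, noise SD ∈ {0, 0.05, 0.10, 0.15},
5 runs, and four model variants — a deliberate scaled-down study that a
laptop completes in under a minute; `Sim5Config` accepts the full 15-level
(SD 0.01–0.15), 15-run design and an external lexicon for the
paper-scale sweep.

## Numerical choices and degenerate inputs

* Synchronous updates from a snapshot: order-independent and reproducible.
* Ties at argmax resolve against recognition; the hold window includes its
  first cycle.
* Slots beyond the word's end receive no input and stay at rest.
* A single-word lexicon is recognized at cycle 0 (margin over an empty
  competitor set); empty outcome lists make `accuracy` raise.
* An all-zero schedule leaves the network exactly at rest (fixed point).
* Two rhyme predicates are exposed deliberately: the time-course taxonomy
  uses same-length first-phoneme substitution; the lexical *dimension*
  additionally admits first-phoneme deletion/addition (so for CAT both AT
  and SCAT count). Edit-distance-1 neighbors use edlib.
* Lateral inhibition is not normalized by the number of competitors.

## Known limitations

* The symmetry mapping's functional form (γ/ρ exponential) and the
  feedback gating scheme are this package's concrete realizations of
  contracts the modeling literature states only ordinally; other forms
  satisfying the same contracts would differ quantitatively.
* Competitor suppression is softer than in published implementations:
  close competitors (cohorts/rhymes in tiny dense lexicons) settle near
  0.7 × target rather than being crushed. Feedback strictly *reduces*
  every competitor-to-target ratio (no runaway), but margins are thinner
  than the published figures suggest.
* Restoration magnitude depends on the noise token actually drawn for the
  expected phoneme (truncation zeroes roughly half the draws), so
  condition means at a given SD have substantial item-level variance.
* With feedback enabled the model recognizes more words under noise but
  is slower on shared items at low noise; the matched-item analysis
  quantifies this trade-off.
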