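"""Ganong effect: lexical context shifts identification of phoneme continua.

For each 4-phoneme probe word and each position, a continuum is built
between the lexical phoneme and a nonword-forming replacement, and run
with lexical feedback on and off.  "Predicted proportion of choices" is
the ratio of the peak activations of the two continuum-endpoint
single-phone nodes; the lexical shift is the feedback-on minus
feedback-off proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..diphones import blend_schedule, word_schedule
from ..network import build_network, run_trial
from ..phonolex import Lexicon
from .common import resolve_lexicon, variant_params

__all__ = ["Sim2Config", "Sim2Result", "sim2_ganong", "DEFAULT_REPLACEMENTS"]

#: Nonword-forming replacement phoneme per word and position.  The row for
#: ``duty`` (/buti/, /d^ti/, /duri/, /dut^/) is the published set; the other
#: rows follow the same recipe (consonants swap with consonants of a
#: different place/manner, vowels with vowels) and are checked against the
#: lexicon at run time.
DEFAULT_REPLACEMENTS: dict[str, tuple[str, str, str, str]] = {
    "appeal": ("^", "b", "u", "r"),  # apil -> ^pil, abil, apul, apir
    "box": ("g", "u", "t", "S"),  # baks -> gaks, buks, bats, bakS
    "boost": ("d", "a", "r", "k"),  # bust -> dust, bast, burt, busk
    "duty": ("b", "^", "r", "^"),  # duti -> buti, d^ti, duri, dut^
    "greet": ("b", "l", "u", "p"),  # grit -> brit, glit, grut, grip
    "least": ("r", "u", "k", "p"),  # list -> rist, lust, likt, lisp
    "school": ("S", "p", "i", "r"),  # skul -> Skul, spul, skil, skur
    "shield": ("s", "a", "r", "t"),  # Sild -> sild, Sald, Sird, Silt
    "screw": ("S", "t", "l", "a"),  # skru -> Skru, stru, sklu, skra
    "ugly": ("a", "b", "r", "u"),  # ^gli -> agli, ^bli, ^gri, ^glu
}


@dataclass(frozen=True)
class Sim2Config:
    lexicon: object = None  # defaults to the ten-word fixture
    words: tuple = ()  # empty = all 4-phoneme words with a replacement row
    replacements: dict | None = None
    preset: str = "OPT_FB"
    n_steps: int = 7


@dataclass
class Sim2Result:
    trials: pd.DataFrame  # word, position, step, alpha, feedback, peaks, proportion
    by_position: pd.DataFrame  # position, step, alpha, feedback, mean, se
    shifts: pd.DataFrame  # position, mean_shift (feedback-on minus feedback-off)

    def tables(self) -> dict:
        return {
            "trials": self.trials,
            "by_position": self.by_position,
            "shifts": self.shifts,
        }


def sim2_ganong(config: Sim2Config = Sim2Config()) -> Sim2Result:
    lexicon: Lexicon = resolve_lexicon(config.lexicon)
    replacements = config.replacements or DEFAULT_REPLACEMENTS
    words = list(config.words) or [
        label for label, ph in lexicon if len(ph) == 4 and label in replacements
    ]
    params = variant_params(config.preset)
    network = build_network(lexicon, params=params)
    strings = {tuple(ph) for _, ph in lexicon}
    alphas = np.linspace(0.0, 1.0, config.n_steps)

    rows = []
    for label in words:
        word = lexicon.phonemes(label)
        for pos in range(4):
            repl = replacements[label][pos]
            nonword = word[:pos] + (repl,) + word[pos + 1 :]
            if nonword in strings:
                warnings.warn(
                    f"replacement {repl!r} at position {pos + 1} of {label!r} "
                    f"forms the real word {''.join(nonword)!r}",
                    stacklevel=2,
                )
            base = word_schedule(word, params)
            for step, alpha in enumerate(alphas, start=1):
                sched = blend_schedule(base, pos, word[pos], repl, float(alpha))
                for fb in (False, True):
                    trace = run_trial(network, sched, feedback_on=fb)
                    peak_lex = float(trace.single_activation(word[pos]).max())
                    peak_repl = float(trace.single_activation(repl).max())
                    total = peak_lex + peak_repl
                    prop = peak_lex / total if total > 0 else 0.5
                    rows.append(
                        {
                            "word": label,
                            "position": pos + 1,
                            "step": step,
                            "alpha": float(alpha),
                            "feedback": fb,
                            "peak_lexical": peak_lex,
                            "peak_replacement": peak_repl,
                            "proportion_lexical": prop,
                        }
                    )
    trials = pd.DataFrame(rows)

    grp = trials.groupby(["position", "step", "alpha", "feedback"])["proportion_lexical"]
    by_position = grp.agg(
        mean="mean", se=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0
    ).reset_index()

    wide = trials.pivot_table(
        index=["word", "position", "step"], columns="feedback", values="proportion_lexical"
    )
    wide["shift"] = wide[True] - wide[False]
    shifts = (
        wide.reset_index().groupby("position")["shift"].mean().rename("mean_shift").reset_index()
    )
    return Sim2Result(trials=trials, by_position=by_position, shifts=shifts)
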