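"""Retroactive disambiguation by right context.

The onsets of *plug* and *blush* are replaced by a stimulus halfway
between /p/ and /b/ (written /#/), so the input stays ambiguous until the
final phoneme (/g/ resolves to plug, /S/ to blush).  Without feedback the
/p/ and /b/ trajectories are identical by construction; with feedback they
diverge after the final phoneme arrives, in favor of the lexically
consistent phoneme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..diphones import blend_schedule, word_schedule
from ..network import build_network, run_trial
from ..phonolex import Lexicon, add_word, ganong_lexicon
from .common import resolve_lexicon, variant_params

__all__ = ["Sim3Config", "Sim3Result", "sim3_right_context", "sim3_lexicon"]

_CONTEXTS = {"lug": "pl^g", "lush": "bl^S"}
_CONSISTENT = {"lug": "p", "lush": "b"}


def sim3_lexicon() -> Lexicon:
    """Ten-word fixture plus *plug* and *blush* (and no *plush* or *blug*)."""
    lex = ganong_lexicon()
    lex = add_word(lex, "plug", tuple("pl^g"))
    return add_word(lex, "blush", tuple("bl^S"))


@dataclass(frozen=True)
class Sim3Config:
    lexicon: object = "sim3"  # "sim3" = fixture + plug + blush
    preset: str = "OPT_FB"
    alpha: float = 0.5  # the /#/ stimulus


@dataclass
class Sim3Result:
    traces: pd.DataFrame  # cycle, context, stimulus, feedback, phoneme, activation
    summary: pd.DataFrame  # context, feedback, end and peak /p/, /b/ activations

    def tables(self) -> dict:
        return {"traces": self.traces, "summary": self.summary}


def sim3_right_context(config: Sim3Config = Sim3Config()) -> Sim3Result:
    if config.lexicon == "sim3" or config.lexicon is None:
        lexicon = sim3_lexicon()
    else:
        lexicon = resolve_lexicon(config.lexicon)
    for needed in ("plug", "blush"):
        if needed not in lexicon.labels:
            raise ValueError(f"sim3 lexicon must contain {needed!r}")
    if any(ph == tuple("pl^S") for _, ph in lexicon):
        raise ValueError("sim3 lexicon must not contain plush (/pl^S/)")

    params = variant_params(config.preset)
    network = build_network(lexicon, params=params)

    rows, summary_rows = [], []
    for context, wordstr in _CONTEXTS.items():
        word = tuple(wordstr)
        intact = word_schedule(word, params)
        ambiguous = blend_schedule(intact, 0, "p", "b", config.alpha)
        for stim_name, sched in (("intact", intact), ("ambiguous", ambiguous)):
            for fb in (False, True):
                trace = run_trial(network, sched, feedback_on=fb)
                for phoneme in ("p", "b"):
                    act = trace.single_activation(phoneme)
                    rows.append(
                        pd.DataFrame(
                            {
                                "cycle": np.arange(trace.n_cycles),
                                "context": context,
                                "stimulus": stim_name,
                                "feedback": fb,
                                "phoneme": phoneme,
                                "activation": act,
                            }
                        )
                    )
                pa = trace.single_activation("p")
                ba = trace.single_activation("b")
                summary_rows.append(
                    {
                        "context": context,
                        "stimulus": stim_name,
                        "feedback": fb,
                        "consistent_phoneme": _CONSISTENT[context],
                        "p_end": float(pa[-1]),
                        "b_end": float(ba[-1]),
                        "p_peak": float(pa.max()),
                        "b_peak": float(ba.max()),
                        "max_abs_p_minus_b": float(np.abs(pa - ba).max()),
                    }
                )
    return Sim3Result(
        traces=pd.concat(rows, ignore_index=True), summary=pd.DataFrame(summary_rows)
    )
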