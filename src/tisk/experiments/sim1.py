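"""Time course of lexical competition and lexical-dimension correlates.

One noise-free trial per word in the lexicon, for one or more model
variants (a parameter preset plus a feedback flag).  Produces the class
time-course curves (target / cohort / rhyme / all-word baseline), the
per-word recognition outcomes, between-variant RT correlations over
shared recognized words, and Spearman correlations between RT and the six
lexical dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from ..diphones import word_schedule
from ..metrics import (
    accuracy,
    class_timecourse,
    dimensions_table,
    recognition_time,
    rt_correlation,
)
from ..network import build_network, run_trial
from ..phonolex import Lexicon
from .common import resolve_lexicon, variant_params

__all__ = ["Sim1Config", "Sim1Result", "sim1_timecourse"]

#: (name, preset, feedback_on) triples simulated by default
DEFAULT_VARIANTS = (
    ("nofb", "OPT_NOFB", False),
    ("fb", "OPT_FB", True),
)


@dataclass(frozen=True)
class Sim1Config:
    lexicon: object = None  # Lexicon | path | SyntheticLexiconSpec | None
    variants: tuple = DEFAULT_VARIANTS
    threshold: float = 0.05
    hold: int = 10


@dataclass
class Sim1Result:
    outcomes: pd.DataFrame  # variant, word, recognized, rt
    timecourse: pd.DataFrame  # variant, cycle, class, mean, se
    dimensions: pd.DataFrame  # word x lexical dimensions
    dimension_correlations: pd.DataFrame  # variant, dimension, spearman_r, p, n
    rt_correlations: pd.DataFrame  # variant_a, variant_b, pearson_r, p, n_shared
    accuracies: dict = field(default_factory=dict)

    def tables(self) -> dict:
        return {
            "outcomes": self.outcomes,
            "timecourse": self.timecourse,
            "dimensions": self.dimensions,
            "dimension_correlations": self.dimension_correlations,
            "rt_correlations": self.rt_correlations,
        }


_DIMENSIONS = (
    "length",
    "embeddings",
    "onset_competitors",
    "ex_embeddings",
    "das_neighbors",
    "rhymes",
)


def sim1_timecourse(config: Sim1Config = Sim1Config()) -> Sim1Result:
    lexicon: Lexicon = resolve_lexicon(config.lexicon)
    dims = dimensions_table(lexicon)

    out_rows, tc_frames, per_variant_outcomes = [], [], {}
    for name, preset_name, fb in config.variants:
        params = variant_params(preset_name)
        network = build_network(lexicon, params=params)
        traces, outcomes = {}, {}
        for label, word in lexicon:
            trace = run_trial(network, word_schedule(word, params), feedback_on=fb)
            traces[label] = trace
            outcomes[label] = recognition_time(
                trace, label, threshold=config.threshold, hold=config.hold
            )
        per_variant_outcomes[name] = outcomes
        for label, o in outcomes.items():
            out_rows.append(
                {
                    "variant": name,
                    "word": label,
                    "recognized": o.recognized,
                    "rt": o.rt_cycle,
                    "final_winner": o.final_winner,
                }
            )
        tc = class_timecourse(traces, lexicon)
        tc.insert(0, "variant", name)
        tc_frames.append(tc)

    outcomes_df = pd.DataFrame(out_rows)

    corr_rows = []
    for name, outcomes in per_variant_outcomes.items():
        rts = {
            w: o.rt_cycle for w, o in outcomes.items() if o.recognized
        }
        sub = dims[dims["word"].isin(rts)]
        rt_vec = sub["word"].map(rts).astype(float)
        for dim in _DIMENSIONS:
            if len(sub) >= 3 and sub[dim].nunique() > 1 and rt_vec.nunique() > 1:
                r, p = stats.spearmanr(sub[dim], rt_vec)
            else:
                r, p = float("nan"), float("nan")
            corr_rows.append(
                {"variant": name, "dimension": dim, "spearman_r": r, "p": p, "n": len(sub)}
            )

    rtc_rows = []
    names = list(per_variant_outcomes)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r, p, n = rt_correlation(per_variant_outcomes[a], per_variant_outcomes[b])
            rtc_rows.append(
                {"variant_a": a, "variant_b": b, "pearson_r": r, "p": p, "n_shared": n}
            )

    return Sim1Result(
        outcomes=outcomes_df,
        timecourse=pd.concat(tc_frames, ignore_index=True),
        dimensions=dims,
        dimension_correlations=pd.DataFrame(corr_rows),
        rt_correlations=pd.DataFrame(rtc_rows),
        accuracies={
            name: accuracy(list(o.values())) for name, o in per_variant_outcomes.items()
        },
    )
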