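"""Graceful degradation: full-lexicon accuracy and RT under input noise.

Gaussian noise is added to every input entry over each word's span, and one
recognition trial is run per word, per noise level, per run, for several
model variants.  Noise tokens are shared across variants (the same noisy
stimulus is presented to every model), so the matched-item RT analysis —
restricted to words recognized by both the feedback and no-feedback
models — is paired by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..diphones import add_global_noise, word_schedule
from ..metrics import recognition_time
from ..network import build_network, run_trial
from ..phonolex import Lexicon, SyntheticLexiconSpec
from .common import derive_seed, resolve_lexicon, variant_params

__all__ = ["Sim5Config", "Sim5Result", "sim5_noise_sweep", "DEFAULT_VARIANTS"]

#: (name, preset, feedback_on); mirrors the four curves of the noise sweep
DEFAULT_VARIANTS = (
    ("original", "ORIGINAL", False),
    ("nofb_opt", "OPT_NOFB", False),
    ("fb", "OPT_FB", True),
    ("fb_params_nofb", "OPT_FB", False),
)

#: default scaled-down study: 50-word synthetic lexicon, 5 runs, 4 levels
DEFAULT_LEXICON_SPEC = SyntheticLexiconSpec(n_words=50, length_range=(2, 9), seed=7)
DEFAULT_LEVELS = (0.0, 0.05, 0.10, 0.15)
PAPER_SCALE_LEVELS = tuple(round(0.01 * i, 2) for i in range(1, 16))


@dataclass(frozen=True)
class Sim5Config:
    lexicon: object = DEFAULT_LEXICON_SPEC
    variants: tuple = DEFAULT_VARIANTS
    noise_levels: tuple = DEFAULT_LEVELS
    runs: int = 5
    seed: int = 0
    threshold: float = 0.05
    hold: int = 10
    matched_pair: tuple = ("fb", "nofb_opt")  # with- vs without-feedback models


@dataclass
class Sim5Result:
    outcomes: pd.DataFrame  # variant, level, run, word, recognized, rt
    summary: pd.DataFrame  # variant, level, run, accuracy, mean_rt
    curves: pd.DataFrame  # variant, level, accuracy/rt mean +- se over runs
    matched_pairs: pd.DataFrame  # level, run, word, rt for both models
    matched_summary: pd.DataFrame  # level, run, counts and paired means

    def tables(self) -> dict:
        return {
            "outcomes": self.outcomes,
            "summary": self.summary,
            "curves": self.curves,
            "matched_pairs": self.matched_pairs,
            "matched_summary": self.matched_summary,
        }


def sim5_noise_sweep(config: Sim5Config = Sim5Config()) -> Sim5Result:
    lexicon: Lexicon = resolve_lexicon(config.lexicon)
    nets = {
        name: (build_network(lexicon, params=variant_params(preset_name)), fb, variant_params(preset_name))
        for name, preset_name, fb in config.variants
    }

    rows = []
    for level_i, sd in enumerate(config.noise_levels):
        for run in range(config.runs):
            for word_i, (label, word) in enumerate(lexicon):
                schedules = {}
                for name, (network, fb, params) in nets.items():
                    key = (params.cycles_per_phoneme, params.n_slots, params.total_cycles)
                    if key not in schedules:
                        base = word_schedule(word, params)
                        if sd > 0:
                            base = add_global_noise(
                                base, sd, rng_seed=derive_seed(config.seed, level_i, run, word_i)
                            )
                        schedules[key] = base
                    trace = run_trial(network, schedules[key], feedback_on=fb)
                    outcome = recognition_time(
                        trace, label, threshold=config.threshold, hold=config.hold
                    )
                    rows.append(
                        {
                            "variant": name,
                            "level": sd,
                            "run": run,
                            "word": label,
                            "recognized": outcome.recognized,
                            "rt": outcome.rt_cycle,
                        }
                    )
    outcomes = pd.DataFrame(rows)

    summary = (
        outcomes.groupby(["variant", "level", "run"])
        .agg(
            accuracy=("recognized", "mean"),
            mean_rt=("rt", lambda x: float(np.mean(x.dropna())) if x.notna().any() else np.nan),
        )
        .reset_index()
    )

    def _se(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0

    curves = (
        summary.groupby(["variant", "level"])
        .agg(
            accuracy=("accuracy", "mean"),
            accuracy_se=("accuracy", _se),
            mean_rt=("mean_rt", "mean"),
            mean_rt_se=("mean_rt", _se),
        )
        .reset_index()
    )

    a, b = config.matched_pair
    wide = outcomes[outcomes["variant"].isin([a, b])].pivot_table(
        index=["level", "run", "word"],
        columns="variant",
        values="rt",
        aggfunc="first",
    )
    pair_rows, match_rows = [], []
    for (level, run), grp in wide.groupby(level=[0, 1]):
        rt_a, rt_b = grp.get(a), grp.get(b)
        valid_a = int(rt_a.notna().sum()) if rt_a is not None else 0
        valid_b = int(rt_b.notna().sum()) if rt_b is not None else 0
        both = grp.dropna() if rt_a is not None and rt_b is not None else grp.iloc[0:0]
        for word, r in both.iterrows():
            pair_rows.append(
                {"level": level, "run": run, "word": word[2], f"rt_{a}": r[a], f"rt_{b}": r[b]}
            )
        n_pairs = len(both)
        match_rows.append(
            {
                "level": level,
                "run": run,
                f"n_valid_{a}": valid_a,
                f"n_valid_{b}": valid_b,
                "n_pairs": n_pairs,
                f"mean_rt_{a}": float(both[a].mean()) if n_pairs else np.nan,
                f"mean_rt_{b}": float(both[b].mean()) if n_pairs else np.nan,
                f"prop_faster_{a}": float((both[a] < both[b]).mean()) if n_pairs else np.nan,
            }
        )
    return Sim5Result(
        outcomes=outcomes,
        summary=summary,
        curves=curves,
        matched_pairs=pd.DataFrame(pair_rows),
        matched_summary=pd.DataFrame(match_rows),
    )
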