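"""Recognition criterion, accuracy, competitor taxonomy and lexical dimensions.

Recognition time is the first cycle at which the target word's activation
exceeds every other word's by at least ``threshold`` (default 0.05), keeps
that margin for ``hold`` cycles (default 10, including the first), and the
target then remains the single most active word until the end of the trial.

Two rhyme notions are exposed deliberately.  For the *time-course* class
taxonomy a rhyme is a same-length word mismatching only at the first
phoneme.  The *rhyme dimension* additionally admits first-phoneme deletion
and addition (so for CAT both AT and SCAT count).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .network import TrialTrace
from .phonolex import Lexicon

__all__ = [
    "RecognitionOutcome",
    "CompetitorClasses",
    "LexicalDimensions",
    "recognition_time",
    "accuracy",
    "competitor_classes",
    "lexical_dimensions",
    "dimensions_table",
    "class_timecourse",
    "rt_correlation",
]


@dataclass(frozen=True)
class RecognitionOutcome:
    recognized: bool
    rt_cycle: int | None
    final_winner: str

    def __post_init__(self) -> None:
        if self.recognized and self.rt_cycle is None:
            raise ValueError("recognized outcomes must carry an rt_cycle")


def recognition_time(
    trace: TrialTrace, target: str, threshold: float = 0.05, hold: int = 10
) -> RecognitionOutcome:
    """Apply the margin-and-hold recognition criterion to a trial trace."""
    T = trace.n_cycles
    if hold > T:
        raise ValueError(f"hold={hold} exceeds trace length {T}")
    ti = trace.labels.index(target)
    act = trace.word
    final_winner = trace.labels[int(np.argmax(act[-1]))]
    if act.shape[1] == 1:  # no competitors: margin over an empty set
        return RecognitionOutcome(True, 0, final_winner)

    others = np.delete(act, ti, axis=1).max(axis=1)
    margin = act[:, ti] - others
    meets = margin >= threshold
    leads = margin > 0.0  # strict: ties resolve against recognition

    # all-true over each length-`hold` window starting at c
    window_ok = np.lib.stride_tricks.sliding_window_view(meets, hold).all(axis=1)
    # leads at every cycle from c to the end
    tail_ok = np.flip(np.logical_and.accumulate(np.flip(leads)))
    for c in range(T - hold + 1):
        if window_ok[c] and (c + hold >= T or tail_ok[c + hold]):
            return RecognitionOutcome(True, int(c), final_winner)
    return RecognitionOutcome(False, None, final_winner)


def accuracy(outcomes: list[RecognitionOutcome]) -> float:
    """Fraction of outcomes with ``recognized=True``; errors on empty input."""
    if not outcomes:
        raise ValueError("accuracy of an empty outcome list is undefined")
    return sum(o.recognized for o in outcomes) / len(outcomes)


@dataclass(frozen=True)
class CompetitorClasses:
    cohorts: frozenset
    rhymes: frozenset
    unrelated: frozenset


def competitor_classes(lexicon: Lexicon, target: str) -> CompetitorClasses:
    """Partition the other words into cohorts, rhymes, and the remainder.

    Cohorts share the first two phonemes with the target (classified
    first); rhymes are same-length words mismatching only at the first
    phoneme.  The remainder feeds the all-word baseline.
    """
    tw = lexicon.phonemes(target)
    cohorts, rhymes, unrelated = set(), set(), set()
    for label, w in lexicon:
        if label == target:
            continue
        if len(tw) >= 2 and len(w) >= 2 and w[:2] == tw[:2]:
            cohorts.add(label)
        elif len(w) == len(tw) and w[1:] == tw[1:] and w[0] != tw[0]:
            rhymes.add(label)
        else:
            unrelated.add(label)
    return CompetitorClasses(frozenset(cohorts), frozenset(rhymes), frozenset(unrelated))


@dataclass(frozen=True)
class LexicalDimensions:
    length: int
    embeddings: int
    onset_competitors: int
    ex_embeddings: int
    das_neighbors: int
    rhymes: int


def _contains(long_: tuple, short: tuple) -> bool:
    n, m = len(short), len(long_)
    return n < m and any(long_[i : i + n] == short for i in range(m - n + 1))


def _edit_distance(a: tuple, b: tuple) -> int:
    return edlib.align("".join(a), "".join(b), task="distance")["editDistance"]


def lexical_dimensions(lexicon: Lexicon, target: str) -> LexicalDimensions:
    """Count the competitor-structure dimensions of one word.

    embeddings: other words occurring as a contiguous substring of the
    target (counted once per word type); ex_embeddings: words the target
    occurs in; das_neighbors: words at exactly one phoneme deletion,
    addition, or substitution; rhymes: words mismatching only at the first
    phoneme, by substitution, deletion, or addition.
    """
    tw = lexicon.phonemes(target)
    emb = exe = das = rhy = coh = 0
    for label, w in lexicon:
        if label == target:
            continue
        if _contains(tw, w):
            emb += 1
        if _contains(w, tw):
            exe += 1
        if w != tw and _edit_distance(w, tw) == 1:
            das += 1
        if (
            (len(w) == len(tw) and w[0] != tw[0] and w[1:] == tw[1:])
            or w == tw[1:]
            or w[1:] == tw
        ):
            rhy += 1
        if len(tw) >= 2 and len(w) >= 2 and w[:2] == tw[:2]:
            coh += 1
    return LexicalDimensions(
        length=len(tw),
        embeddings=emb,
        onset_competitors=coh,
        ex_embeddings=exe,
        das_neighbors=das,
        rhymes=rhy,
    )


def dimensions_table(lexicon: Lexicon) -> pd.DataFrame:
    """One row of lexical dimensions per word."""
    rows = []
    for label, _ in lexicon:
        d = lexical_dimensions(lexicon, label)
        rows.append({"word": label, **d.__dict__})
    return pd.DataFrame(rows)


def class_timecourse(traces: dict[str, TrialTrace], lexicon: Lexicon) -> pd.DataFrame:
    """Mean activation curves for target / cohort / rhyme / all-word classes.

    ``traces`` maps each target label to the trace of its own trial.  For
    each trial the cohort (rhyme) curve is the mean over that target's
    cohort (rhyme) set; targets without members in a class do not
    contribute to that class's mean.  Returns tidy rows
    (cycle, class, mean, se) with the standard error taken over targets.
    """
    per_class: dict[str, list[np.ndarray]] = {
        "target": [],
        "cohort": [],
        "rhyme": [],
        "unrelated": [],
    }
    for target, trace in traces.items():
        classes = competitor_classes(lexicon, target)
        per_class["target"].append(trace.word_activation(target))
        if classes.cohorts:
            cols = [trace.labels.index(l) for l in classes.cohorts]
            per_class["cohort"].append(trace.word[:, cols].mean(axis=1))
        if classes.rhymes:
            cols = [trace.labels.index(l) for l in classes.rhymes]
            per_class["rhyme"].append(trace.word[:, cols].mean(axis=1))
        per_class["unrelated"].append(trace.word.mean(axis=1))

    rows = []
    for cls, curves in per_class.items():
        if not curves:
            continue
        arr = np.stack(curves)  # (n_contributing_targets, T)
        mean = arr.mean(axis=0)
        se = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 else np.zeros_like(mean)
        rows.append(
            pd.DataFrame(
                {"cycle": np.arange(arr.shape[1]), "class": cls, "mean": mean, "se": se}
            )
        )
    return pd.concat(rows, ignore_index=True)


def rt_correlation(
    outcomes_a: dict[str, RecognitionOutcome], outcomes_b: dict[str, RecognitionOutcome]
) -> tuple[float, float, int]:
    """Pearson correlation of RTs over words recognized by both variants.

    Returns ``(r, p_value, n_shared)``; ``(nan, nan, n)`` when fewer than
    three shared words exist.
    """
    shared = [
        w
        for w in outcomes_a
        if w in outcomes_b and outcomes_a[w].recognized and outcomes_b[w].recognized
    ]
    if len(shared) < 3:
        return float("nan"), float("nan"), len(shared)
    a = np.array([outcomes_a[w].rt_cycle for w in shared], dtype=float)
    b = np.array([outcomes_b[w].rt_cycle for w in shared], dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan"), float("nan"), len(shared)
    r, p = stats.pearsonr(a, b)
    return float(r), float(p), len(shared)
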