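"""Ordered open-diphone codes and per-cycle input schedules.

An *open diphone* is an ordered pair of phonemes co-occurring anywhere in a
word (adjacent or not).  The multiset of open diphones is a string kernel:
a fixed-dimension (phoneme x phoneme) code that represents order and
repetition independently of word length.  The graded variant attenuates a
pair's weight by ``gamma`` per intervening phoneme and credits the reversed
order with a small factor ``rho``, which is the input/output contract of
the symmetry network that maps time-specific phoneme input onto
time-invariant diphone nodes.

Input schedules describe the external stimulus: which (phoneme, slot) input
nodes receive how much drive on each cycle.  Blending, silence/noise
replacement and global additive noise are all schedule transformations, so
every source of stochasticity lives here rather than in the network
dynamics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .params import TISKParams
from .phonolex import PhonemeInventory, default_inventory

__all__ = [
    "open_diphones",
    "graded_weights",
    "InputSchedule",
    "word_schedule",
    "blend_schedule",
    "degrade_schedule",
    "add_global_noise",
]


def open_diphones(word: Sequence[str]) -> Counter:
    """Ordered open-diphone counts of ``word``.

    ``counts[(x, y)]`` is the number of index pairs ``i < j`` with
    ``word[i] == x`` and ``word[j] == y``; the total over all pairs is
    ``n * (n - 1) / 2`` for a word of length ``n``.
    """
    if len(word) < 1:
        raise ValueError("word must have length >= 1")
    counts: Counter = Counter()
    for i in range(len(word)):
        for j in range(i + 1, len(word)):
            counts[(word[i], word[j])] += 1
    return counts


def graded_weights(word: Sequence[str], gamma: float = 0.5, rho: float = 0.1) -> dict:
    """Distance-weighted, order-asymmetric diphone weights of ``word``.

    weight[(x, y)] = sum over ordered occurrences of gamma**gap
                   + rho * sum over reversed occurrences of gamma**gap

    where ``gap = j - i - 1`` is the number of intervening phonemes, so an
    adjacent ordered pair contributes exactly 1.  With ``rho < 1`` the
    ordered direction always dominates the reversed one.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    weights: dict = {}
    for i in range(len(word)):
        for j in range(i + 1, len(word)):
            g = gamma ** (j - i - 1)
            x, y = word[i], word[j]
            weights[(x, y)] = weights.get((x, y), 0.0) + g
            weights[(y, x)] = weights.get((y, x), 0.0) + rho * g
    return weights


@dataclass(frozen=True)
class InputSchedule:
    """Per-cycle external drive to the time-specific phoneme input layer.

    ``external`` has shape (n_cycles, n_phonemes, n_slots); entry
    ``[t, p, s]`` is the drive to the copy of phoneme ``p`` at temporal slot
    ``s`` on cycle ``t``.  ``word_len`` is the number of slots the stimulus
    occupies.
    """

    external: np.ndarray
    inventory: PhonemeInventory
    cycles_per_phoneme: int
    word_len: int

    def __post_init__(self) -> None:
        if self.external.ndim != 3:
            raise ValueError("external must be (n_cycles, n_phonemes, n_slots)")
        if not np.all(np.isfinite(self.external)):
            raise ValueError("external input values must be finite")
        if self.external.shape[1] != len(self.inventory):
            raise ValueError("phoneme axis does not match inventory size")
        if self.word_len > self.n_slots:
            raise ValueError("word does not fit in the slot count")

    @property
    def n_cycles(self) -> int:
        return self.external.shape[0]

    @property
    def n_slots(self) -> int:
        return self.external.shape[2]

    def slot_window(self, slot: int) -> tuple[int, int]:
        """Half-open cycle range during which ``slot`` receives its stimulus."""
        cpp = self.cycles_per_phoneme
        return slot * cpp, min((slot + 1) * cpp, self.n_cycles)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (cycle, phoneme, slot, value) rows for the nonzero entries."""
        t, p, s = np.nonzero(self.external)
        return pd.DataFrame(
            {
                "cycle": t,
                "phoneme": [self.inventory.symbols[i] for i in p],
                "slot": s,
                "value": self.external[t, p, s],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def word_schedule(
    word: Sequence[str],
    params: TISKParams,
    total_cycles: int | None = None,
    inventory: PhonemeInventory | None = None,
) -> InputSchedule:
    """Schedule presenting ``word`` one phoneme per slot, ``cycles_per_phoneme``
    cycles each: the node (word[s], slot s) receives drive 1.0 on cycles
    [s*cpp, (s+1)*cpp) and everything else is 0.
    """
    inventory = inventory or default_inventory()
    inventory.validate_word(word)
    if len(word) > params.n_slots:
        raise ValueError(f"word of length {len(word)} exceeds {params.n_slots} slots")
    total = params.total_cycles if total_cycles is None else total_cycles
    cpp = params.cycles_per_phoneme
    ext = np.zeros((total, len(inventory), params.n_slots))
    for s, ph in enumerate(word):
        ext[s * cpp : min((s + 1) * cpp, total), inventory.index(ph), s] = 1.0
    return InputSchedule(
        external=ext, inventory=inventory, cycles_per_phoneme=cpp, word_len=len(word)
    )


def blend_schedule(
    base: InputSchedule, slot: int, phon_a: str, phon_b: str, alpha: float
) -> InputSchedule:
    """Replace the stimulus at ``slot`` with an ``alpha`` blend of two phonemes.

    During the slot's active cycles, node (phon_a, slot) receives 1 - alpha
    and (phon_b, slot) receives alpha; ``alpha=0`` reproduces the base
    stimulus amplitude on phon_a only.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if not 0 <= slot < base.word_len:
        raise ValueError("slot outside the word span")
    lo, hi = base.slot_window(slot)
    ext = base.external.copy()
    ext[lo:hi, :, slot] = 0.0
    ext[lo:hi, base.inventory.index(phon_a), slot] = 1.0 - alpha
    ext[lo:hi, base.inventory.index(phon_b), slot] = alpha
    return replace(base, external=ext)


def degrade_schedule(
    base: InputSchedule,
    slot: int,
    mode: str,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    per_cycle: bool = False,
) -> InputSchedule:
    """Replace the stimulus at ``slot`` with silence or with noise.

    ``mode='silence'`` zeroes the slot's active cycles.  ``mode='noise'``
    zeroes them and then adds i.i.d. Gaussian(0, noise_sd) drive to *every*
    phoneme node at that slot, truncated at 0 (inputs are nonnegative
    evidence).  By default one draw per phoneme is held constant over the
    slot's active block; ``per_cycle=True`` redraws each cycle.  Seeded and
    deterministic.
    """
    if mode not in ("silence", "noise"):
        raise ValueError("mode must be 'silence' or 'noise'")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0 <= slot < base.word_len:
        raise ValueError("slot outside the word span")
    lo, hi = base.slot_window(slot)
    ext = base.external.copy()
    ext[lo:hi, :, slot] = 0.0
    if mode == "noise" and noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        n_ph = ext.shape[1]
        if per_cycle:
            draws = rng.normal(0.0, noise_sd, size=(hi - lo, n_ph))
        else:
            draws = np.broadcast_to(rng.normal(0.0, noise_sd, size=n_ph), (hi - lo, n_ph))
        ext[lo:hi, :, slot] = np.maximum(draws, 0.0)
    return replace(base, external=ext)


def add_global_noise(
    base: InputSchedule, noise_sd: float, rng_seed: int = 0, per_cycle: bool = False
) -> InputSchedule:
    """Add Gaussian(0, noise_sd) to every input entry over the word's span.

    Noise is applied, per occupied slot, to all phoneme nodes during that
    slot's active cycles; the result is truncated at 0 but not clipped above
    (a noisy intact phoneme may exceed 1).  One draw per (phoneme, slot)
    block by default; seeded and deterministic.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return base
    rng = np.random.default_rng(rng_seed)
    ext = base.external.copy()
    n_ph = ext.shape[1]
    for s in range(base.word_len):
        lo, hi = base.slot_window(s)
        if per_cycle:
            draws = rng.normal(0.0, noise_sd, size=(hi - lo, n_ph))
        else:
            draws = np.broadcast_to(rng.normal(0.0, noise_sd, size=n_ph), (hi - lo, n_ph))
        ext[lo:hi, :, s] = np.maximum(ext[lo:hi, :, s] + draws, 0.0)
    return replace(base, external=ext)
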