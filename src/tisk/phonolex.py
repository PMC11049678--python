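"""Phoneme inventories, lexicon I/O and synthetic lexicons.

The model operates over a closed phoneme inventory and a phonemically
transcribed lexicon (one word per line, ``label<TAB>phoneme-string``).
Because the classic 211-word interactive-activation lexicon is distributed
separately, this module also provides a seeded synthetic-lexicon generator
with controllable densities of the competitor relations that drive lexical
dynamics (cohorts, rhymes, embeddings), so every simulation can run
self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "PhonemeInventory",
    "Lexicon",
    "LexiconError",
    "SyntheticLexiconSpec",
    "default_inventory",
    "load_inventory",
    "write_inventory",
    "load_lexicon",
    "write_lexicon",
    "add_word",
    "generate_synthetic_lexicon",
    "lexicon_density_report",
    "ganong_word_fixture",
]


class LexiconError(ValueError):
    """Raised for invalid inventories, lexicon files, or lexicon edits."""


@dataclass(frozen=True)
class PhonemeInventory:
    """A closed, ordered set of single-character phoneme symbols.

    ``silence`` is a reserved symbol (used in stimulus specifications for
    gaps) that is not itself a phoneme.
    """

    symbols: tuple[str, ...]
    silence: str = "-"

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise LexiconError("inventory needs at least 2 phonemes")
        if len(set(self.symbols)) != len(self.symbols):
            raise LexiconError("inventory symbols must be unique")
        if any(len(s) != 1 for s in self.symbols):
            raise LexiconError("phoneme symbols must be single characters")
        if self.silence in self.symbols:
            raise LexiconError("silence symbol must not be a phoneme")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    def validate_word(self, phonemes: Sequence[str]) -> None:
        for ph in phonemes:
            if ph not in self.symbols:
                raise LexiconError(f"unknown phoneme symbol {ph!r}")


#: 14-symbol inventory in the style of the classic interactive-activation
#: simulations (stops, fricatives, liquids and four vowels), plus '-' for
#: silence.  Configurable everywhere; this is only the default fixture.
_DEFAULT_SYMBOLS = ("p", "b", "t", "d", "k", "g", "s", "S", "r", "l", "a", "i", "u", "^")


def default_inventory() -> PhonemeInventory:
    return PhonemeInventory(symbols=_DEFAULT_SYMBOLS, silence="-")


def load_inventory(path: str | Path) -> PhonemeInventory:
    """Read an inventory from YAML (keys: ``symbols``, ``silence``)."""
    data = yaml.safe_load(Path(path).read_text())
    return PhonemeInventory(symbols=tuple(data["symbols"]), silence=data.get("silence", "-"))


def write_inventory(inventory: PhonemeInventory, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump({"symbols": list(inventory.symbols), "silence": inventory.silence})
    )


@dataclass(frozen=True)
class Lexicon:
    """Labeled phoneme strings; the word layer is built from one of these."""

    entries: tuple[tuple[str, tuple[str, ...]], ...]
    inventory: PhonemeInventory = field(default_factory=default_inventory)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, phonemes in self.entries:
            if label in seen:
                raise LexiconError(f"duplicate label {label!r}")
            seen.add(label)
            if len(phonemes) < 1:
                raise LexiconError(f"entry {label!r} has no phonemes")
            self.inventory.validate_word(phonemes)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.entries)

    def phonemes(self, label: str) -> tuple[str, ...]:
        for lab, ph in self.entries:
            if lab == label:
                return ph
        raise KeyError(label)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def max_length(self) -> int:
        return max(len(ph) for _, ph in self.entries) if self.entries else 0


def load_lexicon(path: str | Path, inventory: PhonemeInventory | None = None) -> Lexicon:
    """Load a TSV lexicon (``label<TAB>phonemes``; ``#`` comments ignored).

    Every phoneme must belong to the inventory; violations are reported with
    the offending line number and symbol.
    """
    inventory = inventory or default_inventory()
    entries: list[tuple[str, tuple[str, ...]]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise LexiconError(f"line {lineno}: expected 'label<TAB>phonemes', got {raw!r}")
        label, phonstr = parts[0].strip(), parts[1].strip()
        phonemes = tuple(phonstr)
        for ph in phonemes:
            if ph not in inventory:
                raise LexiconError(f"line {lineno}: unknown phoneme symbol {ph!r} in {label!r}")
        entries.append((label, phonemes))
    return Lexicon(entries=tuple(entries), inventory=inventory)


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    lines = [f"{label}\t{''.join(ph)}" for label, ph in lexicon]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def add_word(lexicon: Lexicon, label: str, phonemes: Sequence[str]) -> Lexicon:
    """Return a new lexicon with one entry appended (labels stay unique)."""
    if label in lexicon.labels:
        raise LexiconError(f"duplicate label {label!r}")
    lexicon.inventory.validate_word(phonemes)
    return Lexicon(
        entries=lexicon.entries + ((label, tuple(phonemes)),),
        inventory=lexicon.inventory,
    )


@dataclass(frozen=True)
class SyntheticLexiconSpec:
    """Targets for the synthetic-lexicon generator.

    Densities are the proportion of words that have at least one classmate
    of the given relation (cohort = shares first two phonemes; rhyme =
    same-length words differing only at the first phoneme; embedding = one
    word is a contiguous substring of the other).
    """

    n_words: int
    length_range: tuple[int, int] = (2, 9)
    target_cohort_density: float = 0.3
    target_rhyme_density: float = 0.2
    target_embedding_density: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if self.n_words < 1:
            raise LexiconError("n_words must be >= 1")
        if lo < 2 or hi < lo:
            raise LexiconError("length_range must satisfy 2 <= min <= max")
        for d in (
            self.target_cohort_density,
            self.target_rhyme_density,
            self.target_embedding_density,
        ):
            if not 0.0 <= d <= 1.0:
                raise LexiconError("densities must lie in [0, 1]")


def _has_cohort(w: tuple[str, ...], others: Iterable[tuple[str, ...]]) -> bool:
    return len(w) >= 2 and any(o[:2] == w[:2] for o in others if o != w and len(o) >= 2)


def _is_rhyme(a: tuple[str, ...], b: tuple[str, ...]) -> bool:
    return len(a) == len(b) and a != b and a[1:] == b[1:]


def _is_embedding(a: tuple[str, ...], b: tuple[str, ...]) -> bool:
    """True if the shorter of a/b occurs contiguously inside the longer."""
    if a == b:
        return False
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    n, m = len(short), len(long_)
    return any(long_[i : i + n] == short for i in range(m - n + 1))


def _densities(words: list[tuple[str, ...]]) -> dict[str, float]:
    n = len(words)
    if n == 0:
        return {"cohort": 0.0, "rhyme": 0.0, "embedding": 0.0}
    coh = sum(_has_cohort(w, words) for w in words)
    rhy = sum(any(_is_rhyme(w, o) for o in words) for w in words)
    emb = sum(any(_is_embedding(w, o) for o in words) for w in words)
    return {"cohort": coh / n, "rhyme": rhy / n, "embedding": emb / n}


def lexicon_density_report(lexicon: Lexicon) -> dict[str, float]:
    """Achieved competitor densities (proportion of words with >= 1 classmate)."""
    return _densities([ph for _, ph in lexicon])


def generate_synthetic_lexicon(
    spec: SyntheticLexiconSpec, inventory: PhonemeInventory | None = None
) -> Lexicon:
    """Generate a lexicon with roughly the requested competitor structure.

    Words are added one at a time.  Each new word is derived from an existing
    word using whichever relation (cohort / rhyme / embedding) is currently
    furthest below its target density, or drawn at random when all targets
    are met.  Deterministic under ``spec.seed``; phoneme strings are unique.
    """
    inventory = inventory or default_inventory()
    lo, hi = spec.length_range
    rng = np.random.default_rng(spec.seed)
    symbols = list(inventory.symbols)

    n_strings = sum(len(symbols) ** k for k in range(lo, hi + 1))
    if spec.n_words > n_strings:
        raise LexiconError(
            f"n_words={spec.n_words} exceeds the {n_strings} distinct strings "
            f"of length {lo}..{hi} over {len(symbols)} symbols"
        )

    def random_word() -> tuple[str, ...]:
        length = int(rng.integers(lo, hi + 1))
        return tuple(rng.choice(symbols, size=length))

    words: list[tuple[str, ...]] = []
    used: set[tuple[str, ...]] = set()
    targets = {
        "cohort": spec.target_cohort_density,
        "rhyme": spec.target_rhyme_density,
        "embedding": spec.target_embedding_density,
    }

    def derive(move: str, base: tuple[str, ...]) -> tuple[str, ...] | None:
        if move == "cohort":
            if len(base) < 2:
                return None
            length = int(rng.integers(max(lo, 2), hi + 1))
            tail = tuple(rng.choice(symbols, size=max(0, length - 2)))
            return base[:2] + tail
        if move == "rhyme":
            alternatives = [s for s in symbols if s != base[0]]
            return (str(rng.choice(alternatives)),) + base[1:]
        if move == "embedding":
            if len(base) >= hi:  # embed a substring of base instead
                length = int(rng.integers(lo, len(base)))
                start = int(rng.integers(0, len(base) - length + 1))
                return base[start : start + length]
            extra = int(rng.integers(1, hi - len(base) + 1))
            pre = int(rng.integers(0, extra + 1))
            head = tuple(rng.choice(symbols, size=pre))
            tail = tuple(rng.choice(symbols, size=extra - pre))
            return head + base + tail
        raise ValueError(move)

    def relations(cand: tuple[str, ...]) -> dict[str, list[int]]:
        """Indices of existing words that would become classmates of ``cand``."""
        rel = {"cohort": [], "rhyme": [], "embedding": []}
        for i, w in enumerate(words):
            if len(cand) >= 2 and len(w) >= 2 and w[:2] == cand[:2]:
                rel["cohort"].append(i)
            if _is_rhyme(cand, w):
                rel["rhyme"].append(i)
            if _is_embedding(cand, w):
                rel["embedding"].append(i)
        return rel

    # has_rel[c][i] == word i already has a classmate of class c
    has_rel: dict[str, list[bool]] = {k: [] for k in targets}

    def density(cls: str) -> float:
        return sum(has_rel[cls]) / len(words) if words else 0.0

    while len(words) < spec.n_words:
        move = None
        if words:
            deficits = {k: targets[k] - density(k) for k in targets}
            move = max(deficits, key=lambda k: deficits[k])
            if deficits[move] <= 0:
                move = None
        candidate: tuple[str, ...] | None = None
        rel: dict[str, list[int]] = {}
        for attempt in range(60):
            if move is not None and attempt < 30:
                base = words[int(rng.integers(0, len(words)))]
                candidate = derive(move, base)
            else:
                candidate = random_word()
            if candidate is None or not lo <= len(candidate) <= hi or candidate in used:
                candidate = None
                continue
            rel = relations(candidate)
            # avoid pushing an already-met density further above its target
            overshoot = any(
                rel[c] and density(c) >= targets[c] and (move != c) for c in targets
            )
            if not overshoot or attempt >= 45:
                break
            candidate = None
        if candidate is None:
            raise LexiconError("could not generate a fresh word; relax the spec")
        for c in targets:
            for i in rel[c]:
                has_rel[c][i] = True
            has_rel[c].append(bool(rel[c]))
        words.append(candidate)
        used.add(candidate)

    entries = tuple((f"w{i:03d}_{''.join(ph)}", ph) for i, ph in enumerate(words))
    return Lexicon(entries=entries, inventory=inventory)


#: Ten 4-phoneme probe words used in the lexical-context experiments, in the
#: default 14-symbol inventory.  DUTY is /duti/; the other transcriptions are
#: fixed here (nearest-symbol renderings of the English forms, documented in
#: the methods note).
_GANONG_WORDS: tuple[tuple[str, str], ...] = (
    ("appeal", "apil"),
    ("box", "baks"),
    ("boost", "bust"),
    ("duty", "duti"),
    ("greet", "grit"),
    ("least", "list"),
    ("school", "skul"),
    ("shield", "Sild"),
    ("screw", "skru"),
    ("ugly", "^gli"),
)


def ganong_word_fixture() -> list[tuple[str, tuple[str, ...]]]:
    """The ten 4-phoneme probe words for the Ganong / restoration experiments."""
    return [(label, tuple(ph)) for label, ph in _GANONG_WORDS]


def ganong_lexicon() -> Lexicon:
    """The ten probe words as a stand-alone lexicon over the default inventory."""
    return Lexicon(entries=tuple(ganong_word_fixture()), inventory=default_inventory())
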