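"""Shared plumbing for the simulation harnesses.

Every experiment is a pure function of (config, master seed): per-trial
seeds are derived from the master seed and stable integer keys via
``numpy.random.SeedSequence``, so outputs are bit-reproducible and noise
tokens can be shared across conditions by construction.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ..params import PRESET_NAMES, preset
from ..phonolex import (
    Lexicon,
    SyntheticLexiconSpec,
    ganong_lexicon,
    generate_synthetic_lexicon,
    load_lexicon,
)

__all__ = ["derive_seed", "resolve_lexicon", "write_report", "variant_params"]


def derive_seed(master_seed: int, *keys: int) -> int:
    """A stable sub-seed (< 2**31) for one trial, from integer keys."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def resolve_lexicon(
    source: str | Path | Lexicon | SyntheticLexiconSpec | None,
) -> Lexicon:
    """Accept a lexicon object, a TSV path, a synthetic spec, or the
    bundled ten-word fixture (``None`` or ``"fixture"``)."""
    if source is None or source == "fixture":
        return ganong_lexicon()
    if isinstance(source, Lexicon):
        return source
    if isinstance(source, SyntheticLexiconSpec):
        return generate_synthetic_lexicon(source)
    return load_lexicon(source)


def variant_params(preset_name: str, **overrides):
    if preset_name.upper() not in PRESET_NAMES:
        raise ValueError(f"unknown preset {preset_name!r}")
    return preset(preset_name, **overrides)


def write_report(
    out_dir: str | Path,
    tables: Mapping[str, pd.DataFrame],
    metadata: Mapping,
) -> Path:
    """Write tidy CSV tables plus a JSON metadata sidecar; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    meta = {k: _jsonable(v) for k, v in metadata.items()}
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out


def _jsonable(v):
    if dataclasses.is_dataclass(v) and not isinstance(v, type):
        return dataclasses.asdict(v)
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (tuple, list)):
        return [_jsonable(x) for x in v]
    return v
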