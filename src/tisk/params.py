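"""Model parameters and the three shipped presets.

All per-cycle rates and weights of the interactive-activation network live
in :class:`TISKParams`.  The three presets correspond to the published
parameter columns: the original no-feedback parameterization (``ORIGINAL``),
parameters re-optimized for robustness to noise without feedback
(``OPT_NOFB``), and parameters optimized for running with lexical feedback
(``OPT_FB``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["TISKParams", "preset", "PRESET_NAMES", "load_params", "write_params"]


@dataclass(frozen=True)
class TISKParams:
    # per-cycle decay rates, one per layer
    input_phoneme_decay: float = 0.001
    nphone_decay: float = 0.001
    word_decay: float = 0.050
    # connection weights
    w_phoneme_to_nphone: float = 0.100
    w_diphone_to_word: float = 0.050
    w_singlephone_to_word: float = 0.010
    w_word_word_inhibition: float = -0.005
    fb_positive: float = 0.0
    fb_negative: float = 0.0
    # open-diphone grading: gap decay and reverse-order attenuation
    gamma: float = 0.5
    rho: float = 0.1
    # architecture constants
    cycles_per_phoneme: int = 10
    n_slots: int = 10
    total_cycles: int = 100
    # activation bounds
    act_min: float = 0.0
    act_max: float = 1.0
    rest: float = 0.0
    # feedback delivery: when True (default) top-down input to an N-phone is
    # scaled by the receiver's own supra-rest activation (and, for the
    # excitatory part, by its headroom act_max - a), so feedback amplifies
    # bottom-up evidence but cannot create activation out of silence.
    fb_gated: bool = True

    def __post_init__(self) -> None:
        for name in ("input_phoneme_decay", "nphone_decay", "word_decay"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.w_word_word_inhibition > 0:
            raise ValueError("w_word_word_inhibition must be <= 0")
        if not (self.fb_negative <= 0.0 <= self.fb_positive):
            raise ValueError("need fb_negative <= 0 <= fb_positive")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if not self.act_min <= self.rest <= self.act_max:
            raise ValueError("need act_min <= rest <= act_max")
        if self.cycles_per_phoneme < 1 or self.n_slots < 1 or self.total_cycles < 1:
            raise ValueError("architecture constants must be positive")

    def replace(self, **kwargs) -> "TISKParams":
        return dataclasses.replace(self, **kwargs)


_PRESETS: dict[str, dict] = {
    "ORIGINAL": dict(
        input_phoneme_decay=0.010,
        nphone_decay=0.001,
        word_decay=0.010,
        w_phoneme_to_nphone=1.000,
        w_diphone_to_word=0.050,
        w_singlephone_to_word=0.010,
        w_word_word_inhibition=-0.005,
        fb_positive=0.0,
        fb_negative=0.0,
    ),
    "OPT_NOFB": dict(
        input_phoneme_decay=0.001,
        nphone_decay=0.001,
        word_decay=0.050,
        w_phoneme_to_nphone=0.100,
        w_diphone_to_word=0.050,
        w_singlephone_to_word=0.010,
        w_word_word_inhibition=-0.005,
        fb_positive=0.0,
        fb_negative=0.0,
    ),
    "OPT_FB": dict(
        input_phoneme_decay=0.001,
        nphone_decay=0.100,
        word_decay=0.050,
        w_phoneme_to_nphone=0.100,
        w_diphone_to_word=0.050,
        w_singlephone_to_word=0.010,
        w_word_word_inhibition=-0.010,
        fb_positive=0.150,
        fb_negative=-0.050,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, **overrides) -> TISKParams:
    """Return a named preset, optionally overriding individual fields.

    The shipped YAML files under ``tisk/presets/`` mirror these values; the
    in-code table is authoritative and covered by tests.
    """
    try:
        base = _PRESETS[name.upper()]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}") from None
    return TISKParams(**{**base, **overrides})


def load_params(path: str | Path) -> TISKParams:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "preset" in data:
        name = data.pop("preset")
        return preset(name, **data)
    return TISKParams(**data)


def write_params(params: TISKParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(params)))


def preset_yaml_path(name: str) -> Path:
    """Path of the shipped YAML file for a preset (for CLI/config use)."""
    if name.upper() not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}")
    return Path(str(resources.files("tisk").joinpath("presets", f"{name.lower()}.yaml")))
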