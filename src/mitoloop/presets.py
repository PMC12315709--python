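"""Versioned registry of species presets and frozen estimator calibration.

Provenance of every number:

* mean mitotic loop sizes — reported species averages: chicken 250 kb,
  human 450 kb, mouse 1.25 Mb (prometaphase condensin loop arrays).
* interphase_reference cohesin loop scale — the ~100 kb average interphase
  loop size seen in derivative plots of nonsynchronized cells.
* mouse helical period — the ~10 Mb secondary derivative peak reflecting
  one helical turn of the prometaphase scaffold; the amplitude and comb
  width are this package's choices (no published value), set for a
  detectable but subdominant secondary peak.
* kernel exponents, gap shape, mixture weights — model choices of the
  generators (see docs/methods.md), not measured quantities.
* CALIBRATION — fitted once as the median ratio s_peak / L over a
  simulation grid (scripts/calibrate.py: five loop sizes, three seeds each,
  per regime) and frozen here; regenerate only when the generator or the
  derivative pipeline changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from .core import ValidationError
from .sim_hic import InterphaseParams, LoopArrayParams


@dataclass(frozen=True)
class SpeciesPreset:
    name: str
    chrom_length_bp: int          # recommended simulation chromosome length
    bin_size_bp: int              # recommended analysis resolution
    params: Union[LoopArrayParams, InterphaseParams]
    regime: str                   # "mitotic" | "interphase"


_REGISTRY = {
    "chicken": SpeciesPreset(
        name="chicken",
        chrom_length_bp=150_000_000,
        bin_size_bp=25_000,
        params=LoopArrayParams(mean_loop_bp=250_000),
        regime="mitotic",
    ),
    "human": SpeciesPreset(
        name="human",
        chrom_length_bp=150_000_000,
        bin_size_bp=25_000,
        params=LoopArrayParams(mean_loop_bp=450_000),
        regime="mitotic",
    ),
    "mouse": SpeciesPreset(
        name="mouse",
        chrom_length_bp=150_000_000,
        bin_size_bp=50_000,
        params=LoopArrayParams(
            mean_loop_bp=1_250_000,
            helix_period_bp=10_000_000,
            helix_amp=0.3,
        ),
        regime="mitotic",
    ),
    "interphase_reference": SpeciesPreset(
        name="interphase_reference",
        chrom_length_bp=150_000_000,
        bin_size_bp=10_000,
        params=InterphaseParams(cohesin_loop_bp=100_000),
        regime="interphase",
    ),
}

#: Frozen estimator calibration constants (s_peak / L), one per regime.
#: Values produced by scripts/calibrate.py; see module docstring.
CALIBRATION = {
    "mitotic": 0.5886,
    "interphase": 0.6011,
}


def get_preset(name: str) -> SpeciesPreset:
    """Look up an immutable species preset by name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; valid names: {sorted(_REGISTRY)}"
        ) from None


def preset_names() -> list[str]:
    return sorted(_REGISTRY)
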