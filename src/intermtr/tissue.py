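"""Two-pool tissue parameter sets and packaged presets.

The two-pool model describes brain tissue as a free water pool (observable,
with ordinary T1/T2 relaxation) exchanging longitudinal magnetization with a
restricted macromolecular pool (invisible, T2 of order 10 microseconds) at a
pseudo-first-order rate ``kr``.  The pool-size ratio ``F = M0_r / M0_f`` sets
the equilibrium restricted magnetization.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources

__all__ = ["TissuePoolParams", "load_tissue_presets", "get_tissue"]


@dataclass(frozen=True)
class TissuePoolParams:
    """Relaxation, exchange and lineshape parameters of one tissue.

    Parameters
    ----------
    t1_free, t2_free : float
        Longitudinal / transverse relaxation times of the free pool, s.
    t1_restricted, t2_restricted : float
        Relaxation times of the restricted (macromolecular) pool, s.
    pool_ratio_F : float
        Pool-size ratio ``M0_r / M0_f`` (dimensionless).
    exchange_rate_kr : float
        Pseudo-first-order exchange rate, s^-1.
    m0_free : float
        Equilibrium free-pool magnetization, arbitrary units.
    g_zero : float
        On-resonance value of the absorption lineshape, s.
    """

    t1_free: float
    t2_free: float
    t1_restricted: float
    t2_restricted: float
    pool_ratio_F: float
    exchange_rate_kr: float
    m0_free: float = 1.0
    g_zero: float = 1.4e-5
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        for attr in ("t1_free", "t2_free", "t1_restricted", "t2_restricted"):
            value = getattr(self, attr)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{attr} must be positive and finite, got {value!r}")
        if not (math.isfinite(self.pool_ratio_F) and self.pool_ratio_F >= 0):
            raise ValueError(f"pool_ratio_F must be >= 0, got {self.pool_ratio_F!r}")
        if not (math.isfinite(self.exchange_rate_kr) and self.exchange_rate_kr >= 0):
            raise ValueError(f"exchange_rate_kr must be >= 0, got {self.exchange_rate_kr!r}")
        if not (math.isfinite(self.g_zero) and self.g_zero >= 0):
            raise ValueError(f"g_zero must be >= 0, got {self.g_zero!r}")
        if not (math.isfinite(self.m0_free) and self.m0_free > 0):
            raise ValueError(f"m0_free must be positive, got {self.m0_free!r}")

    @property
    def m0_restricted(self) -> float:
        """Equilibrium restricted-pool magnetization ``F * M0_f``."""
        return self.pool_ratio_F * self.m0_free


_ALIASES = {"wm": "white_matter", "gm": "gray_matter"}


def load_tissue_presets() -> dict[str, TissuePoolParams]:
    """Load the packaged tissue parameter sets (key-value config file)."""
    text = resources.files("intermtr.presets").joinpath("tissues.toml").read_text()
    raw = tomllib.loads(text)
    return {name: TissuePoolParams(name=name, **entry) for name, entry in raw.items()}


def get_tissue(name: str) -> TissuePoolParams:
    """Return a named tissue preset (``white_matter``/``wm``, ``gray_matter``/``gm``,
    ``agar``, ``saline``, ``csf``)."""
    presets = load_tissue_presets()
    key = _ALIASES.get(name.lower(), name.lower())
    try:
        return presets[key]
    except KeyError:
        raise KeyError(
            f"unknown tissue preset {name!r}; available: {sorted(presets)}"
        ) from None
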