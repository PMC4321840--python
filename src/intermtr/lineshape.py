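"""Absorption lineshape of the restricted pool and RF saturation rate.

Semi-solid (macromolecular) protons have a broad absorption spectrum that is
well described by a super-Lorentzian: an orientation average of Gaussian
lines whose width depends on the angle between the inter-proton vector and
B0.  Off-resonance irradiation saturates the restricted pool at a rate
proportional to the lineshape value at the irradiation frequency and to the
square of the RF amplitude.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.integrate import quad

from .constants import G_ZERO_DEFAULT, GAMMA, NEAR_RESONANCE_CUTOFF_HZ

__all__ = ["super_lorentzian", "saturation_rate"]

_SINGULARITY = 1.0 / math.sqrt(3.0)  # integrand's removable singular point


def super_lorentzian(
    offset_hz: float,
    t2_restricted: float,
    *,
    g_zero: float = G_ZERO_DEFAULT,
    cutoff_hz: float = NEAR_RESONANCE_CUTOFF_HZ,
) -> float:
    """Super-Lorentzian absorption lineshape ``G`` at an offset, in seconds.

    ``G(w) = sqrt(2/pi) * T2r * int_0^1 du / |3u^2 - 1|
             * exp(-2 * (w * T2r / (3u^2 - 1))^2)``

    with ``w = 2*pi*offset_hz`` the angular frequency offset from the
    restricted-pool resonance (taken equal to the free-pool resonance; no MT
    asymmetry).  The integral diverges as the offset approaches zero, so
    offsets below ``cutoff_hz`` return the conventional finite on-resonance
    value ``g_zero``.

    Parameters
    ----------
    offset_hz : float
        Frequency offset of the irradiation from water resonance, Hz.
        Symmetric in sign.
    t2_restricted : float
        Transverse relaxation time of the restricted pool, s.
    g_zero : float
        Value returned at (near-)zero offset, s.
    cutoff_hz : float
        Near-resonance cutoff, Hz.

    Returns
    -------
    float
        Lineshape value in seconds (>= 0).
    """
    if not math.isfinite(offset_hz):
        raise ValueError(f"offset_hz must be finite, got {offset_hz!r}")
    if not (t2_restricted > 0):
        raise ValueError(f"t2_restricted must be positive, got {t2_restricted!r}")
    if abs(offset_hz) < cutoff_hz:
        return g_zero
    return _super_lorentzian_integral(abs(float(offset_hz)), float(t2_restricted))


@lru_cache(maxsize=4096)
def _super_lorentzian_integral(offset_hz: float, t2r: float) -> float:
    w = 2.0 * math.pi * offset_hz
    wt = w * t2r

    def integrand(u: float) -> float:
        x = 3.0 * u * u - 1.0
        if x == 0.0:
            return 0.0
        return math.exp(-2.0 * (wt / x) ** 2) / abs(x)

    value, abserr = quad(
        integrand, 0.0, 1.0, points=[_SINGULARITY], limit=200,
        epsabs=1e-13, epsrel=1e-10,
    )
    if not math.isfinite(value) or abserr > 1e-6 * abs(value) + 1e-12:
        raise RuntimeError(
            "super-Lorentzian quadrature did not converge: "
            f"offset_hz={offset_hz}, t2r={t2r}, value={value}, abserr={abserr}"
        )
    return math.sqrt(2.0 / math.pi) * t2r * value


def saturation_rate(b1_now: float, lineshape_value: float) -> float:
    """Instantaneous restricted-pool saturation rate ``W = pi * g^2 * b1^2 * G``.

    Parameters
    ----------
    b1_now : float
        RF amplitude at this instant, T.
    lineshape_value : float
        Absorption lineshape at the irradiation frequency, s.

    Returns
    -------
    float
        Saturation rate, s^-1; exactly quadratic in ``b1_now``.
    """
    if not (np.isfinite(b1_now) and np.isfinite(lineshape_value)):
        raise ValueError("b1_now and lineshape_value must be finite")
    if lineshape_value < 0:
        raise ValueError(f"lineshape_value must be >= 0, got {lineshape_value!r}")
    return math.pi * GAMMA * GAMMA * b1_now * b1_now * lineshape_value
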