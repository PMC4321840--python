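"""Two-pool Bloch-McConnell state and evolution operators.

The state is four-dimensional: transverse and longitudinal magnetization of
the free water pool plus longitudinal magnetization of the restricted pool
(whose transverse magnetization decays in microseconds and is never tracked).
During an RF pulse the system is integrated in the frame rotating at the
free-pool Larmor frequency, with the RF field written explicitly as a
rotating field at the carrier offset; between pulses the free evolution has a
closed-form solution (T2 decay plus a 2x2 longitudinal exchange system).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from . import _kernels
from .constants import GAMMA
from .lineshape import super_lorentzian
from .pulse import GAUSS_WINDOW_SIGMA_FRACTION, RFPulse
from .tissue import TissuePoolParams

__all__ = [
    "MagnetizationState",
    "bloch_mcconnell_rhs",
    "evolve_pulse",
    "evolve_free",
]

DEFAULT_RTOL = 1e-8


@dataclass(frozen=True)
class MagnetizationState:
    """Magnetization state (Mx_f, My_f, Mz_f, Mz_r) in units of ``m0_free``."""

    mx_free: float
    my_free: float
    mz_free: float
    mz_restricted: float

    def __post_init__(self) -> None:
        if not all(
            math.isfinite(v)
            for v in (self.mx_free, self.my_free, self.mz_free, self.mz_restricted)
        ):
            raise ValueError("magnetization components must be finite")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.mx_free, self.my_free, self.mz_free, self.mz_restricted], dtype=float
        )

    @classmethod
    def from_array(cls, arr) -> "MagnetizationState":
        arr = np.asarray(arr, dtype=float)
        return cls(float(arr[0]), float(arr[1]), float(arr[2]), float(arr[3]))

    @classmethod
    def equilibrium(cls, tissue: TissuePoolParams) -> "MagnetizationState":
        """Thermal equilibrium: (0, 0, M0_f, F*M0_f)."""
        return cls(0.0, 0.0, tissue.m0_free, tissue.m0_restricted)

    @property
    def transverse_magnitude(self) -> float:
        return math.hypot(self.mx_free, self.my_free)


def _pulse_lineshape(pulse: RFPulse, tissue: TissuePoolParams) -> float:
    """Lineshape value at the pulse carrier offset (single G per pulse)."""
    return super_lorentzian(
        pulse.offset_hz, tissue.t2_restricted, g_zero=tissue.g_zero
    )


def bloch_mcconnell_rhs(
    state,
    t: float,
    pulse: RFPulse,
    tissue: TissuePoolParams,
    lineshape_value: float | None = None,
):
    """Time derivative of the two-pool state during a shaped pulse.

    The four coupled equations (free-pool Bloch equations with the rotating
    RF field at the carrier offset, longitudinal exchange at rate ``kr``
    weighted by the pool ratio ``F``, and restricted-pool saturation
    ``-Mz_r * W(t)``) evaluated at time ``t`` in ``[0, pulse.duration]``.

    Accepts a :class:`MagnetizationState` or a length-4 array; returns a
    length-4 array.  This pure-Python form is the reference implementation
    used by external ODE solvers; the compiled integrator mirrors it.
    """
    if isinstance(state, MagnetizationState):
        y = state.to_array()
    else:
        y = np.asarray(state, dtype=float)
    if lineshape_value is None:
        lineshape_value = _pulse_lineshape(pulse, tissue)
    b1 = float(pulse.b1(t))
    gb = GAMMA * b1
    arg = 2.0 * math.pi * pulse.offset_hz * t + pulse.phase
    s, c = math.sin(arg), math.cos(arg)
    w = math.pi * GAMMA * GAMMA * b1 * b1 * lineshape_value
    fkr = tissue.pool_ratio_F * tissue.exchange_rate_kr
    kr = tissue.exchange_rate_kr
    mx, my, mzf, mzr = y
    return np.array(
        [
            gb * mzf * s - mx / tissue.t2_free,
            gb * mzf * c - my / tissue.t2_free,
            -gb * mx * s
            - gb * my * c
            - (mzf - tissue.m0_free) / tissue.t1_free
            - mzf * fkr
            + mzr * kr,
            -(mzr - tissue.m0_restricted) / tissue.t1_restricted
            + mzf * fkr
            - mzr * kr
            - mzr * w,
        ]
    )


def _pulse_kernel_args(pulse: RFPulse, tissue: TissuePoolParams) -> tuple:
    shape_id = 0 if pulse.shape == "rect" else 1
    sigma = GAUSS_WINDOW_SIGMA_FRACTION * pulse.duration
    g = _pulse_lineshape(pulse, tissue)
    wcoef = math.pi * GAMMA * GAMMA * pulse.peak_b1 ** 2 * g
    dw = 2.0 * math.pi * pulse.offset_hz
    return (
        GAMMA * pulse.peak_b1,
        pulse.duration,
        shape_id,
        pulse.bandwidth_hz,
        sigma,
        dw,
        wcoef,
    )


def _tissue_kernel_args(tissue: TissuePoolParams) -> tuple:
    return (
        1.0 / tissue.t2_free,
        1.0 / tissue.t1_free,
        1.0 / tissue.t1_restricted,
        tissue.pool_ratio_F * tissue.exchange_rate_kr,
        tissue.exchange_rate_kr,
        tissue.m0_free,
        tissue.m0_restricted,
    )


def evolve_pulse(
    state: MagnetizationState,
    pulse: RFPulse,
    tissue: TissuePoolParams,
    tol: float = DEFAULT_RTOL,
) -> MagnetizationState:
    """Integrate the state across one shaped pulse (adaptive RK 4(5)).

    Parameters
    ----------
    state : MagnetizationState
        State at the start of the pulse.
    pulse : RFPulse
        The excitation event (envelope, carrier offset, phase).
    tissue : TissuePoolParams
        Two-pool parameters.
    tol : float
        Relative integration tolerance (> 0); the absolute tolerance is
        ``tol * m0_free``.
    """
    if not (tol > 0):
        raise ValueError(f"tol must be positive, got {tol!r}")
    y = state.to_array()
    status = _kernels.integrate_pulse(
        y,
        *_pulse_kernel_args(pulse, tissue),
        pulse.phase,
        *_tissue_kernel_args(tissue),
        tol,
        tol * tissue.m0_free,
    )
    if status != _kernels.STATUS_OK:
        raise RuntimeError(
            "adaptive step size underflow while integrating pulse "
            f"(duration={pulse.duration}, offset_hz={pulse.offset_hz})"
        )
    return MagnetizationState.from_array(y)


def free_propagator(tissue: TissuePoolParams, duration: float) -> np.ndarray:
    """Closed-form free-evolution propagator over ``duration`` seconds.

    Returns the 7-vector ``(e2, p11, p12, p21, p22, c1, c2)`` consumed by the
    compiled kernels: transverse components scale by ``e2 = exp(-dt/T2_f)``
    and the longitudinal pair maps affinely through the matrix exponential of
    the coupled relaxation/exchange system, whose fixed point is thermal
    equilibrium.
    """
    if duration < 0:
        raise ValueError(f"duration must be >= 0, got {duration!r}")
    fkr = tissue.pool_ratio_F * tissue.exchange_rate_kr
    kr = tissue.exchange_rate_kr
    a = np.array(
        [
            [-1.0 / tissue.t1_free - fkr, kr],
            [fkr, -1.0 / tissue.t1_restricted - kr],
        ]
    )
    p = expm(a * duration)
    meq = np.array([tissue.m0_free, tissue.m0_restricted])
    c = meq - p @ meq
    e2 = math.exp(-duration / tissue.t2_free)
    return np.array([e2, p[0, 0], p[0, 1], p[1, 0], p[1, 1], c[0], c[1]])


def evolve_free(
    state: MagnetizationState, duration: float, tissue: TissuePoolParams
) -> MagnetizationState:
    """Evolve the state with no RF for ``duration`` seconds (closed form)."""
    if duration == 0:
        return state
    y = state.to_array()
    _kernels.free_step(y, free_propagator(tissue, duration))
    return MagnetizationState.from_array(y)
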