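"""Compiled numerical kernels for the two-pool Bloch-McConnell system.

The simulator plays thousands of shaped RF pulses per experiment, so the
adaptive Dormand-Prince 4(5) integration of the four-state system
(Mx_f, My_f, Mz_f, Mz_r) runs inside numba-compiled loops.  Free evolution
between pulses uses precomputed closed-form propagators (transverse T2 decay
and the 2x2 longitudinal exchange matrix exponential) supplied by the caller.

Parameter packing convention
----------------------------
pulse: (gb_peak, duration, shape_id, bandwidth_hz, sigma, dw, wcoef)
    gb_peak = gamma * peak_b1 [rad/s]; shape_id 0 = rect, 1 = gauss_sinc;
    sigma = Gaussian window std [s]; dw = 2*pi*offset_hz [rad/s];
    wcoef = pi * gamma^2 * peak_b1^2 * G [1/s] so W(t) = wcoef * env(t)^2.
tissue: (r2f, r1f, r1r, F*kr, kr, m0f, m0r)   (r = 1/T rates)
free propagator: (e2, p11, p12, p21, p22, c1, c2)
    transverse *= e2;  [Mz_f, Mz_r] <- P @ [Mz_f, Mz_r] + c.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Dormand-Prince 4(5) tableau
_C2, _C3, _C4, _C5 = 1.0 / 5.0, 3.0 / 10.0, 4.0 / 5.0, 8.0 / 9.0
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = 19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0, -212.0 / 729.0
_A61, _A62, _A63, _A64, _A65 = (
    9017.0 / 3168.0,
    -355.0 / 33.0,
    46732.0 / 5247.0,
    49.0 / 176.0,
    -5103.0 / 18656.0,
)
_B1, _B3, _B4, _B5, _B6 = 35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0, -2187.0 / 6784.0, 11.0 / 84.0
# 5th-order minus embedded 4th-order weights (error estimate)
_E1 = 71.0 / 57600.0
_E3 = -71.0 / 16695.0
_E4 = 71.0 / 1920.0
_E5 = -17253.0 / 339200.0
_E6 = 22.0 / 525.0
_E7 = -1.0 / 40.0

STATUS_OK = 0
STATUS_STEP_UNDERFLOW = 1


@njit(cache=True)
def envelope(t, duration, shape_id, bandwidth_hz, sigma):
    """Unit-peak RF envelope at time t within [0, duration]."""
    if shape_id == 0:
        return 1.0
    tau = t - 0.5 * duration
    x = np.pi * bandwidth_hz * tau
    if abs(x) < 1e-8:
        s = 1.0 - x * x / 6.0
    else:
        s = np.sin(x) / x
    return s * np.exp(-0.5 * (tau / sigma) ** 2)


@njit(cache=True)
def _rhs(t, y, dy, gb_peak, duration, shape_id, bandwidth_hz, sigma, dw, wcoef, phase,
         r2f, r1f, r1r, fkr, kr, m0f, m0r):
    env = envelope(t, duration, shape_id, bandwidth_hz, sigma)
    gb = gb_peak * env
    arg = dw * t + phase
    s = np.sin(arg)
    c = np.cos(arg)
    w = wcoef * env * env
    mx, my, mzf, mzr = y[0], y[1], y[2], y[3]
    dy[0] = gb * mzf * s - mx * r2f
    dy[1] = gb * mzf * c - my * r2f
    dy[2] = -gb * mx * s - gb * my * c - (mzf - m0f) * r1f - mzf * fkr + mzr * kr
    dy[3] = -(mzr - m0r) * r1r + mzf * fkr - mzr * kr - mzr * w


@njit(cache=True)
def integrate_pulse(y, gb_peak, duration, shape_id, bandwidth_hz, sigma, dw, wcoef,
                    phase, r2f, r1f, r1r, fkr, kr, m0f, m0r, rtol, atol):
    """Integrate the two-pool system across one pulse, in place.

    Adaptive Dormand-Prince 4(5) with a scaled-RMS error norm.  Returns
    STATUS_OK or STATUS_STEP_UNDERFLOW.
    """
    t = 0.0
    k1 = np.empty(4)
    k2 = np.empty(4)
    k3 = np.empty(4)
    k4 = np.empty(4)
    k5 = np.empty(4)
    k6 = np.empty(4)
    k7 = np.empty(4)
    ytmp = np.empty(4)
    ynew = np.empty(4)

    h = duration / 64.0
    if dw != 0.0:
        # resolve the carrier oscillation from the start
        hosc = 0.5 / abs(dw)
        if hosc < h:
            h = hosc
    hmin = duration * 1e-14

    while t < duration:
        if h > duration - t:
            h = duration - t
        _rhs(t, y, k1, gb_peak, duration, shape_id, bandwidth_hz, sigma, dw, wcoef,
             phase, r2f, r1f, r1r, fkr, kr, m0f, m0r)
        for i in range(4):
            ytmp[i] = y[i] + h * _A21 * k1[i]
        _rhs(t + _C2 * h, ytmp, k2, gb_peak, duration, shape_id, bandwidth_hz, sigma,
             dw, wcoef, phase, r2f, r1f, r1r, fkr, kr, m0f, m0r)
        for i in range(4):
            ytmp[i] = y[i] + h * (_A31 * k1[i] + _A32 * k2[i])
        _rhs(t + _C3 * h, ytmp, k3, gb_peak, duration, shape_id, bandwidth_hz, sigma,
             dw, wcoef, phase, r2f, r1f, r1r, fkr, kr, m0f, m0r)
        for i in range(4):
            ytmp[i] = y[i] + h * (_A41 * k1[i] + _A42 * k2[i] + _A43 * k3[i])
        _rhs(t + _C4 * h, ytmp, k4, gb_peak, duration, shape_id, bandwidth_hz, sigma,
             dw, wcoef, phase, r2f, r1f, r1r, fkr, kr, m0f, m0r)
        for i in range(4):
            ytmp[i] = y[i] + h * (_A51 * k1[i] + _A52 * k2[i] + _A53 * k3[i] + _A54 * k4[i])
        _rhs(t + _C5 * h, ytmp, k5, gb_peak, duration, shape_id, bandwidth_hz, sigma,
             dw, wcoef, phase, r2f, r1f, r1r, fkr, kr, m0f, m0r)
        for i in range(4):
            ytmp[i] = y[i] + h * (
                _A61 * k1[i] + _A62 * k2[i] + _A63 * k3[i] + _A64 * k4[i] + _A65 * k5[i]
            )
        _rhs(t + h, ytmp, k6, gb_peak, duration, shape_id, bandwidth_hz, sigma,
             dw, wcoef, phase, r2f, r1f, r1r, fkr, kr, m0f, m0r)
        for i in range(4):
            ynew[i] = y[i] + h * (
                _B1 * k1[i] + _B3 * k3[i] + _B4 * k4[i] + _B5 * k5[i] + _B6 * k6[i]
            )
        _rhs(t + h, ynew, k7, gb_peak, duration, shape_id, bandwidth_hz, sigma,
             dw, wcoef, phase, r2f, r1f, r1r, fkr, kr, m0f, m0r)

        err = 0.0
        for i in range(4):
            ei = h * (
                _E1 * k1[i] + _E3 * k3[i] + _E4 * k4[i] + _E5 * k5[i]
                + _E6 * k6[i] + _E7 * k7[i]
            )
            sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
            err += (ei / sc) ** 2
        err = np.sqrt(err / 4.0)

        if err <= 1.0:
            t += h
            for i in range(4):
                y[i] = ynew[i]

        if err == 0.0:
            fac = 5.0
        else:
            fac = 0.9 * err ** -0.2
            if fac < 0.2:
                fac = 0.2
            elif fac > 5.0:
                fac = 5.0
        h *= fac
        if h < hmin and t < duration:
            return STATUS_STEP_UNDERFLOW
    return STATUS_OK


@njit(cache=True)
def free_step(y, prop):
    """Apply one precomputed free-evolution propagator in place."""
    y[0] *= prop[0]
    y[1] *= prop[0]
    zf = y[2]
    zr = y[3]
    y[2] = prop[1] * zf + prop[2] * zr + prop[5]
    y[3] = prop[3] * zf + prop[4] * zr + prop[6]


@njit(cache=True)
def run_saturation_slice(y, n_reps, gb_peak, duration, shape_id, bandwidth_hz, sigma,
                         dw, wcoef, r2f, r1f, r1r, fkr, kr, m0f, m0r,
                         prop_rest, rtol, atol):
    """One off-resonance slice: n_reps x {pulse; free evolution; spoil}."""
    for _ in range(n_reps):
        status = integrate_pulse(y, gb_peak, duration, shape_id, bandwidth_hz, sigma,
                                 dw, wcoef, 0.0, r2f, r1f, r1r, fkr, kr, m0f, m0r,
                                 rtol, atol)
        if status != STATUS_OK:
            return status
        free_step(y, prop_rest)
        y[0] = 0.0
        y[1] = 0.0
    return STATUS_OK


@njit(cache=True)
def run_imaging_slice(y, n_dummy, n_acq, gb_peak, duration, shape_id, bandwidth_hz,
                      sigma, wcoef, r2f, r1f, r1r, fkr, kr, m0f, m0r,
                      prop_te, prop_rest, rtol, atol, trace):
    """On-resonance balanced readout with 180-degree RF phase alternation.

    Plays n_dummy startup pulses then n_acq acquired pulses; |Mxy_f| at the
    echo time is written into ``trace`` for each acquired pulse.  Transverse
    magnetization is retained between repetitions.
    """
    for rep in range(n_dummy + n_acq):
        phase = np.pi * (rep % 2)
        status = integrate_pulse(y, gb_peak, duration, shape_id, bandwidth_hz, sigma,
                                 0.0, wcoef, phase, r2f, r1f, r1r, fkr, kr, m0f, m0r,
                                 rtol, atol)
        if status != STATUS_OK:
            return status
        free_step(y, prop_te)
        if rep >= n_dummy:
            trace[rep - n_dummy] = np.sqrt(y[0] * y[0] + y[1] * y[1])
        free_step(y, prop_rest)
    return STATUS_OK
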