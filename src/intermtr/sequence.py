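"""Sequential multi-slice SSFP simulation with interslice MT effects.

During multi-slice 2D acquisition, the excitation pulses played for one slice
irradiate every other slice off resonance.  The slice acquired next has just
received a full train of off-resonance pulses, which saturates its
macromolecular pool and, through exchange, lowers the free-water signal: an
MT-weighted image with no dedicated saturation pulse.  Inserting an
interslice delay lets the longitudinal magnetization recover, giving a
reference image; the pair yields a magnetization transfer ratio (MTR) map.

This module simulates that experiment slice by slice with the two-pool
Bloch-McConnell model: off-resonance pulse trains for prior slices, then an
on-resonance balanced readout whose transverse magnitude at the center line
of k-space is the image signal.
"""

from __future__ import annotations

import math
import tomllib
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from . import _kernels
from .bloch import (
    DEFAULT_RTOL,
    MagnetizationState,
    _pulse_kernel_args,
    _tissue_kernel_args,
    evolve_free,
    free_propagator,
)
from .pulse import make_rf_pulse
from .tissue import TissuePoolParams

__all__ = [
    "SliceGeometry",
    "ProtocolParams",
    "SimSignal",
    "FULL_RELAXATION",
    "load_protocol_presets",
    "get_protocol",
    "offset_frequency",
    "simulate_saturation_slice",
    "simulate_imaging_slice",
    "simulate_mt_weighted",
    "simulate_reference",
    "mtr_percent",
    "accumulation_curve",
    "dummy_slices_needed",
    "flip_angle_sweep",
    "delay_sweep",
]

#: Sentinel delay meaning "fully relaxed reference" (imaging slice starts
#: from thermal equilibrium, no prior-slice saturation).
FULL_RELAXATION = math.inf


@dataclass(frozen=True)
class SliceGeometry:
    """Slice-stack geometry that sets the interslice offset frequencies."""

    rf_bandwidth_hz: float
    slice_thickness_mm: float
    interslice_gap_mm: float
    slice_order: str = "descending"
    gradient_polarity: int = 1

    def __post_init__(self) -> None:
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice_thickness_mm must be positive")
        if self.interslice_gap_mm < 0:
            raise ValueError("interslice_gap_mm must be >= 0")
        if self.slice_order not in ("ascending", "descending"):
            raise ValueError("slice_order must be 'ascending' or 'descending'")
        if self.gradient_polarity not in (1, -1):
            raise ValueError("gradient_polarity must be +1 or -1")


@dataclass(frozen=True)
class ProtocolParams:
    """Full acquisition description of one multi-slice SSFP protocol."""

    geometry: SliceGeometry
    tr: float
    te: float
    flip_deg: float
    n_pe_steps: int
    n_dummy_pe: int = 0
    pe_order: str = "centric"
    rf_duration: float = 1.0e-3
    rf_shape: str = "gauss_sinc"
    n_prior_slices: int = 6
    n_dummy_slices: int = 0
    interslice_delay: float = 0.0
    reference_delay: float = FULL_RELAXATION
    partial_fourier: float = 1.0
    integration_rtol: float = DEFAULT_RTOL
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not (0 < self.te <= self.tr):
            raise ValueError("need 0 < te <= tr")
        if self.n_pe_steps < 1:
            raise ValueError("n_pe_steps must be >= 1")
        if self.n_dummy_pe < 0 or self.n_prior_slices < 0 or self.n_dummy_slices < 0:
            raise ValueError("counts must be >= 0")
        if self.pe_order not in ("centric", "linear"):
            raise ValueError("pe_order must be 'centric' or 'linear'")
        if self.interslice_delay < 0:
            raise ValueError("interslice_delay must be >= 0")
        if not (0 < self.partial_fourier <= 1):
            raise ValueError("partial_fourier must be in (0, 1]")
        if self.rf_duration <= 0 or self.rf_duration > self.tr:
            raise ValueError("need 0 < rf_duration <= tr")
        if self.te < 0.5 * self.rf_duration or self.tr - self.te < 0.5 * self.rf_duration:
            raise ValueError("te must leave room for half the RF pulse on each side")

    @property
    def center_k_index(self) -> int:
        """0-based index of the k-space center line within the acquired train."""
        if self.pe_order == "centric":
            return 0
        idx = math.ceil(self.n_pe_steps * self.partial_fourier / 2)
        return min(max(idx - 1, 0), self.n_pe_steps - 1)

    def prior_slice_offsets(self) -> list[float]:
        """Offsets seen from the imaging slice while the prior slices were
        acquired, in the order they were experienced (farthest first)."""
        return [
            offset_frequency(-n, self.geometry)
            for n in range(self.n_prior_slices, 0, -1)
        ]


@dataclass(frozen=True)
class SimSignal:
    """Result of simulating one imaging slice."""

    trace: np.ndarray
    center_k_signal: float
    final_state: MagnetizationState


def load_protocol_presets() -> dict[str, ProtocolParams]:
    """Load the packaged protocol presets (named after the experiments)."""
    text = resources.files("intermtr.presets").joinpath("protocols.toml").read_text()
    raw = tomllib.loads(text)
    out = {}
    for name, entry in raw.items():
        geometry = SliceGeometry(
            rf_bandwidth_hz=entry.pop("rf_bandwidth_hz"),
            slice_thickness_mm=entry.pop("slice_thickness_mm"),
            interslice_gap_mm=entry.pop("interslice_gap_mm"),
            slice_order=entry.pop("slice_order"),
            gradient_polarity=entry.pop("gradient_polarity"),
        )
        out[name] = ProtocolParams(geometry=geometry, name=name, **entry)
    return out


def get_protocol(name: str, **overrides) -> ProtocolParams:
    """Return a named protocol preset, optionally overriding fields."""
    presets = load_protocol_presets()
    try:
        protocol = presets[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown protocol preset {name!r}; available: {sorted(presets)}"
        ) from None
    return replace(protocol, **overrides) if overrides else protocol


def offset_frequency(n: int, geometry: SliceGeometry) -> float:
    """Off-resonance frequency (Hz, signed) a slice at relative index ``n``
    receives while the current slice is excited.

    ``delta_n = -BW * (1 + GAP/THK) * n * sign(GRAD) * ORD`` with ``ORD`` +1
    for ascending and -1 for descending slice order.  Positive ``n`` is
    superior to the acquisition slice.
    """
    if n != int(n):
        raise ValueError(f"slice index must be an integer, got {n!r}")
    ord_sign = 1.0 if geometry.slice_order == "ascending" else -1.0
    return (
        -geometry.rf_bandwidth_hz
        * (1.0 + geometry.interslice_gap_mm / geometry.slice_thickness_mm)
        * float(n)
        * float(geometry.gradient_polarity)
        * ord_sign
    )


def _saturation_pulse(protocol: ProtocolParams, offset_hz: float):
    return make_rf_pulse(
        flip_deg=protocol.flip_deg,
        duration=protocol.rf_duration,
        bandwidth_hz=protocol.geometry.rf_bandwidth_hz,
        offset_hz=offset_hz,
        shape=protocol.rf_shape,
    )


def simulate_saturation_slice(
    state: MagnetizationState,
    tissue: TissuePoolParams,
    protocol: ProtocolParams,
    slice_offset_hz: float,
) -> MagnetizationState:
    """Propagate the state through one neighbouring slice's acquisition.

    Applies ``n_dummy_pe + n_pe_steps`` repetitions of {shaped pulse at the
    slice offset; free evolution over the rest of TR}.  The free-pool
    transverse magnetization is spoiled (zeroed) after each repetition:
    at multi-kilohertz offsets the imaging gradients fully dephase any
    transverse component, so only the longitudinal MT effect survives.
    """
    if slice_offset_hz == 0:
        raise ValueError("slice_offset_hz must be nonzero for a saturation slice")
    pulse = _saturation_pulse(protocol, slice_offset_hz)
    y = state.to_array()
    rtol = protocol.integration_rtol
    status = _kernels.run_saturation_slice(
        y,
        protocol.n_dummy_pe + protocol.n_pe_steps,
        *_pulse_kernel_args(pulse, tissue),
        *_tissue_kernel_args(tissue),
        free_propagator(tissue, protocol.tr - protocol.rf_duration),
        rtol,
        rtol * tissue.m0_free,
    )
    if status != _kernels.STATUS_OK:
        raise RuntimeError("step size underflow in saturation slice")
    return MagnetizationState.from_array(y)


def simulate_imaging_slice(
    state: MagnetizationState,
    tissue: TissuePoolParams,
    protocol: ProtocolParams,
) -> SimSignal:
    """Simulate the on-resonance balanced readout of the imaging slice.

    ``n_dummy_pe`` startup pulses are followed by ``n_pe_steps`` acquired
    pulses, all with 180-degree RF phase alternation and retained transverse
    magnetization.  ``|Mxy_f|`` at the echo time of each acquired repetition
    forms the trace; the element at the phase-encode index of the k-space
    center line is the image signal.
    """
    pulse = _saturation_pulse(protocol, 0.0)
    y = state.to_array()
    trace = np.empty(protocol.n_pe_steps)
    rtol = protocol.integration_rtol
    kargs = _pulse_kernel_args(pulse, tissue)  # (.., dw, wcoef); dw = 0 on resonance
    status = _kernels.run_imaging_slice(
        y,
        protocol.n_dummy_pe,
        protocol.n_pe_steps,
        *kargs[:5],
        kargs[6],
        *_tissue_kernel_args(tissue),
        free_propagator(tissue, protocol.te - 0.5 * protocol.rf_duration),
        free_propagator(tissue, protocol.tr - protocol.te - 0.5 * protocol.rf_duration),
        rtol,
        rtol * tissue.m0_free,
        trace,
    )
    if status != _kernels.STATUS_OK:
        raise RuntimeError("step size underflow in imaging slice")
    return SimSignal(
        trace=trace,
        center_k_signal=float(trace[protocol.center_k_index]),
        final_state=MagnetizationState.from_array(y),
    )


def simulate_mt_weighted(
    tissue: TissuePoolParams, protocol: ProtocolParams
) -> SimSignal:
    """MT-weighted acquisition: prior-slice saturation trains then readout.

    Starting from thermal equilibrium, the ``n_prior_slices`` neighbouring
    slices are played farthest-offset first with zero interslice delay, then
    the imaging slice is read out.
    """
    state = MagnetizationState.equilibrium(tissue)
    for offset in protocol.prior_slice_offsets():
        state = simulate_saturation_slice(state, tissue, protocol, offset)
        if protocol.interslice_delay > 0:
            state = evolve_free(state, protocol.interslice_delay, tissue)
    return simulate_imaging_slice(state, tissue, protocol)


def simulate_reference(
    tissue: TissuePoolParams,
    protocol: ProtocolParams,
    delay: float | None = None,
) -> SimSignal:
    """Reference acquisition with interslice delay ``delay`` (s).

    ``FULL_RELAXATION`` (infinity) starts the imaging slice from thermal
    equilibrium, the idealized fully-recovered reference.  A finite delay
    plays the same prior-slice trains as the MT-weighted acquisition but lets
    the magnetization recover for ``delay`` seconds after each slice.
    """
    if delay is None:
        delay = protocol.reference_delay
    if delay < 0:
        raise ValueError(f"delay must be >= 0, got {delay!r}")
    state = MagnetizationState.equilibrium(tissue)
    if not math.isinf(delay):
        for offset in protocol.prior_slice_offsets():
            state = simulate_saturation_slice(state, tissue, protocol, offset)
            if delay > 0:
                state = evolve_free(state, delay, tissue)
    return simulate_imaging_slice(state, tissue, protocol)


def mtr_percent(signal_mt: float, signal_ref: float) -> float:
    """Magnetization transfer ratio ``(ref - mt) / ref * 100`` in percent."""
    if not (signal_ref > 0):
        raise ValueError(f"signal_ref must be positive, got {signal_ref!r}")
    return (signal_ref - signal_mt) / signal_ref * 100.0


def accumulation_curve(
    tissue: TissuePoolParams, protocol: ProtocolParams, max_prior: int
) -> np.ndarray:
    """Free-pool longitudinal magnetization after k prior slices, k = 0..max.

    Element k is ``Mz_f`` just before the imaging slice when k prior slices
    were played: the k-th-from-last at k times the base offset down to the
    last at the base offset itself, with no interslice delay.
    """
    if max_prior < 1:
        raise ValueError(f"max_prior must be >= 1, got {max_prior!r}")
    base = offset_frequency(-1, protocol.geometry)
    curve = np.empty(max_prior + 1)
    curve[0] = tissue.m0_free
    for k in range(1, max_prior + 1):
        state = MagnetizationState.equilibrium(tissue)
        for j in range(k, 0, -1):
            state = simulate_saturation_slice(state, tissue, protocol, j * base)
        curve[k] = state.mz_free
    return curve


def dummy_slices_needed(curve, rel_tol: float) -> int | None:
    """Smallest k with relative change |curve[k]-curve[k-1]|/curve[k-1] below
    ``rel_tol``; ``None`` (with a warning) if never reached."""
    if not (rel_tol > 0):
        raise ValueError(f"rel_tol must be positive, got {rel_tol!r}")
    curve = np.asarray(curve, dtype=float)
    for k in range(1, len(curve)):
        if abs(curve[k] - curve[k - 1]) < rel_tol * abs(curve[k - 1]):
            return k
    warnings.warn(
        f"steady MT saturation not reached within {len(curve) - 1} prior slices",
        RuntimeWarning,
        stacklevel=2,
    )
    return None


def flip_angle_sweep(
    tissue: TissuePoolParams, protocol: ProtocolParams, angles
) -> pd.DataFrame:
    """MT-weighted/reference signals and MTR for each flip angle (degrees)."""
    angles = list(angles)
    if not angles:
        raise ValueError("angles must be non-empty")
    rows = []
    for angle in angles:
        p = replace(protocol, flip_deg=float(angle))
        mt = simulate_mt_weighted(tissue, p).center_k_signal
        ref = simulate_reference(tissue, p).center_k_signal
        rows.append(
            {
                "flip_deg": float(angle),
                "signal_mt": mt,
                "signal_ref": ref,
                "mtr_percent": mtr_percent(mt, ref),
            }
        )
    return pd.DataFrame(rows)


def delay_sweep(
    tissue: TissuePoolParams, protocol: ProtocolParams, delays
) -> pd.DataFrame:
    """MTR versus interslice delay of the reference acquisition (s)."""
    delays = list(delays)
    if not delays:
        raise ValueError("delays must be non-empty")
    mt = simulate_mt_weighted(tissue, protocol).center_k_signal
    rows = []
    for delay in delays:
        ref = simulate_reference(tissue, protocol, delay=float(delay)).center_k_signal
        rows.append(
            {
                "delay_s": float(delay),
                "signal_mt": mt,
                "signal_ref": ref,
                "mtr_percent": mtr_percent(mt, ref),
            }
        )
    return pd.DataFrame(rows)
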