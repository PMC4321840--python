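"""Digital phantoms: label maps rendered into MT-weighted/reference volumes.

The generator stands in for scanner data: cylindrical gel/saline analogues
and a brain-like slab (white-matter core, gray-matter ribbon, CSF border) are
rendered by running the two-pool simulator per tissue label, broadcasting the
center-of-k-space signals to the labelled voxels, and adding seeded noise.
Dummy slices (noise-only padding at the first-acquired end) are appended per
protocol so the downstream discard/mask/MTR pipeline can be exercised
end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .imaging import ImageVolume
from .sequence import ProtocolParams, simulate_mt_weighted, simulate_reference
from .tissue import TissuePoolParams, get_tissue

__all__ = [
    "DigitalPhantom",
    "NoiseModel",
    "make_cylinder_phantom",
    "make_brain_slab",
    "render_acquisition",
]


@dataclass(frozen=True)
class DigitalPhantom:
    """An integer label volume plus a label -> tissue parameter map."""

    labels: np.ndarray
    tissues: dict[int, TissuePoolParams]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {labels.shape}")
        present = set(np.unique(labels)) - {0}
        missing = present - set(self.tissues)
        if missing:
            raise ValueError(f"labels {sorted(missing)} have no tissue parameters")
        object.__setattr__(self, "labels", labels.astype(np.int32))


@dataclass(frozen=True)
class NoiseModel:
    """Additive image noise: ``sd`` as a fraction of the mean object signal."""

    kind: str = "gaussian"
    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "rician"):
            raise ValueError("kind must be 'gaussian' or 'rician'")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def make_cylinder_phantom(
    diameter_mm: float,
    height_mm: float,
    grid_shape: tuple[int, int, int],
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    tissue: TissuePoolParams | str = "agar",
    label: int = 1,
) -> DigitalPhantom:
    """Axis-aligned cylinder (axis along the slice direction) on a grid.

    Emulates the cylindrical gel/saline test objects: e.g. a 140 mm diameter
    10% agar cylinder or a 120 mm saline cylinder.  A voxel is labelled if
    its center lies inside the cylinder.
    """
    if diameter_mm <= 0 or height_mm <= 0:
        raise ValueError("diameter_mm and height_mm must be positive")
    if isinstance(tissue, str):
        tissue = get_tissue(tissue)
    nx, ny, nz = grid_shape
    vx, vy, vz = voxel_size_mm
    if diameter_mm > nx * vx or diameter_mm > ny * vy or height_mm > nz * vz:
        raise ValueError(
            f"cylinder ({diameter_mm} mm diameter, {height_mm} mm height) "
            f"exceeds the grid ({nx * vx} x {ny * vy} x {nz * vz} mm)"
        )
    x = (np.arange(nx) + 0.5 - nx / 2.0) * vx
    y = (np.arange(ny) + 0.5 - ny / 2.0) * vy
    z = (np.arange(nz) + 0.5 - nz / 2.0) * vz
    in_disc = (x[:, None] ** 2 + y[None, :] ** 2) <= (diameter_mm / 2.0) ** 2
    in_height = np.abs(z) <= height_mm / 2.0
    labels = np.where(in_disc[:, :, None] & in_height[None, None, :], label, 0)
    return DigitalPhantom(
        labels=labels, tissues={label: tissue}, voxel_size_mm=voxel_size_mm
    )


#: Labels used by the brain slab.
WM_LABEL, GM_LABEL, CSF_LABEL = 1, 2, 3


def make_brain_slab(
    grid_shape: tuple[int, int, int],
    seed: int = 0,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    tissues: dict[int, TissuePoolParams] | None = None,
) -> DigitalPhantom:
    """Brain-like label slab: WM core, GM ribbon, CSF border.

    Each slice is a slightly irregular ellipse whose normalized elliptical
    radius is perturbed by a low-order Fourier series with seeded
    coefficients; radius < 0.55 is white matter, 0.55-0.8 gray matter,
    0.8-1.0 CSF.  Identical seeds give identical maps.
    """
    if tissues is None:
        tissues = {
            WM_LABEL: get_tissue("white_matter"),
            GM_LABEL: get_tissue("gray_matter"),
            CSF_LABEL: get_tissue("csf"),
        }
    rng = np.random.default_rng(seed)
    nx, ny, nz = grid_shape
    a, b = 0.42 * nx, 0.42 * ny  # ellipse semi-axes, voxels
    x = np.arange(nx) + 0.5 - nx / 2.0
    y = np.arange(ny) + 0.5 - ny / 2.0
    xx, yy = np.meshgrid(x, y, indexing="ij")
    theta = np.arctan2(yy / b, xx / a)
    rho0 = np.sqrt((xx / a) ** 2 + (yy / b) ** 2)
    labels = np.zeros(grid_shape, dtype=np.int32)
    for k in range(nz):
        # per-slice boundary irregularity, small enough to keep topology
        coeffs = rng.normal(0.0, 0.03, size=(3, 2))
        wobble = np.zeros_like(theta)
        for m in range(3):
            wobble += coeffs[m, 0] * np.cos((m + 2) * theta)
            wobble += coeffs[m, 1] * np.sin((m + 2) * theta)
        rho = rho0 * (1.0 + wobble)
        sl = np.zeros((nx, ny), dtype=np.int32)
        sl[rho < 1.0] = CSF_LABEL
        sl[rho < 0.8] = GM_LABEL
        sl[rho < 0.55] = WM_LABEL
        labels[:, :, k] = sl
    return DigitalPhantom(labels=labels, tissues=dict(tissues), voxel_size_mm=voxel_size_mm)


def render_acquisition(
    phantom: DigitalPhantom,
    protocol: ProtocolParams,
    noise: NoiseModel = NoiseModel(),
) -> tuple[ImageVolume, ImageVolume]:
    """Render MT-weighted and reference volumes from a phantom.

    For every label the two-pool simulator provides the MT-weighted (prior
    slices, zero delay) and reference (protocol's reference delay)
    center-of-k-space signals, which become the voxel intensities.  Seeded
    noise is added independently to both volumes; ``protocol.n_dummy_slices``
    noise-only padding slices are appended to the MT-weighted volume at its
    first-acquired end.
    """
    labels = phantom.labels
    signals_mt = {0: 0.0}
    signals_ref = {0: 0.0}
    for lbl, tissue in phantom.tissues.items():
        signals_mt[lbl] = simulate_mt_weighted(tissue, protocol).center_k_signal
        signals_ref[lbl] = simulate_reference(tissue, protocol).center_k_signal

    mt_data = np.zeros(labels.shape)
    ref_data = np.zeros(labels.shape)
    for lbl in np.unique(labels):
        sel = labels == lbl
        mt_data[sel] = signals_mt[int(lbl)]
        ref_data[sel] = signals_ref[int(lbl)]

    n_dummy = protocol.n_dummy_slices
    if n_dummy:
        pad = np.zeros((*labels.shape[:2], n_dummy))
        if protocol.geometry.slice_order == "descending":
            mt_data = np.concatenate([pad, mt_data], axis=2)
        else:
            mt_data = np.concatenate([mt_data, pad], axis=2)

    if noise.sd > 0:
        sd_abs = noise.sd * float(ref_data[labels > 0].mean())
        rng = np.random.default_rng(noise.seed)
        mt_data = _add_noise(mt_data, sd_abs, noise.kind, rng)
        ref_data = _add_noise(ref_data, sd_abs, noise.kind, rng)

    order = protocol.geometry.slice_order
    mt_vol = ImageVolume(
        data=mt_data,
        voxel_size_mm=phantom.voxel_size_mm,
        slice_order=order,
        n_dummy_slices=n_dummy,
    )
    ref_vol = ImageVolume(
        data=ref_data,
        voxel_size_mm=phantom.voxel_size_mm,
        slice_order=order,
        n_dummy_slices=0,
    )
    return mt_vol, ref_vol


def _add_noise(data: np.ndarray, sd: float, kind: str, rng: np.random.Generator):
    if kind == "gaussian":
        return data + rng.normal(0.0, sd, size=data.shape)
    # Rician: magnitude of complex signal with independent Gaussian channels
    re = data + rng.normal(0.0, sd, size=data.shape)
    im = rng.normal(0.0, sd, size=data.shape)
    return np.hypot(re, im)
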