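"""Image-domain MTR computation: volumes, masks, maps and ROI statistics.

Volumes are plain 3D intensity arrays (nx, ny, nslices) with voxel geometry
and slice-order metadata, read and written as NIfTI-1 through nibabel with a
JSON sidecar for acquisition metadata (slice order, dummy-slice count).
Slice index 0 is the superior-most slice; "descending" acquisition order
therefore acquires slice 0 first.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "MaskVolume",
    "ROIStats",
    "discard_dummy_slices",
    "interleave",
    "de_interleave",
    "head_mask",
    "compute_mtr_map",
    "roi_mean_mtr",
    "snr_difference",
]

#: Percentile used as the "robust maximum" (resists hot pixels).
ROBUST_MAX_PERCENTILE = 99.0


@dataclass(frozen=True)
class ImageVolume:
    """A 3D intensity volume with voxel geometry and slice-order metadata."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    slice_order: str = "descending"
    n_dummy_slices: int = 0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3 or data.shape[2] < 1:
            raise ValueError(f"data must be 3D with >= 1 slice, got shape {data.shape}")
        if self.slice_order not in ("ascending", "descending"):
            raise ValueError("slice_order must be 'ascending' or 'descending'")
        if self.n_dummy_slices < 0:
            raise ValueError("n_dummy_slices must be >= 0")
        object.__setattr__(self, "data", data)

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    @property
    def affine(self) -> np.ndarray:
        return np.diag([*self.voxel_size_mm, 1.0])

    def save(self, path) -> None:
        """Write the volume as NIfTI-1 plus a JSON metadata sidecar."""
        path = Path(path)
        nib.save(nib.Nifti1Image(self.data.astype(np.float64), self.affine), path)
        sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "voxel_size_mm": list(self.voxel_size_mm),
                    "slice_order": self.slice_order,
                    "n_dummy_slices": self.n_dummy_slices,
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path) -> "ImageVolume":
        """Read a NIfTI-1 volume, picking up the sidecar metadata if present."""
        path = Path(path)
        img = nib.load(path)
        data = np.asarray(img.get_fdata(), dtype=float)
        voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
        meta = {}
        sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(
            data=data,
            voxel_size_mm=tuple(meta.get("voxel_size_mm", voxel)),
            slice_order=meta.get("slice_order", "descending"),
            n_dummy_slices=int(meta.get("n_dummy_slices", 0)),
        )


@dataclass(frozen=True)
class MaskVolume:
    """A boolean volume congruent with an :class:`ImageVolume`."""

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=bool)
        if data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {data.shape}")
        object.__setattr__(self, "data", data)

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def save(self, path) -> None:
        nib.save(
            nib.Nifti1Image(self.data.astype(np.uint8), np.eye(4)), Path(path)
        )

    @classmethod
    def load(cls, path) -> "MaskVolume":
        return cls(np.asarray(nib.load(Path(path)).get_fdata()) > 0.5)


@dataclass(frozen=True)
class ROIStats:
    """Mean/spread of MTR over a region of interest."""

    mean: float
    sd: float
    count: int
    snr: float | None = None


def discard_dummy_slices(vol: ImageVolume) -> ImageVolume:
    """Drop the first-acquired ``n_dummy_slices`` from a volume.

    Descending acquisition acquires slice 0 (superior-most) first, so the
    dummies are the leading slices; ascending acquisition acquires the
    inferior-most (last-index) slice first, so they are the trailing slices.
    """
    n = vol.n_dummy_slices
    if n == 0:
        return vol
    if n >= vol.n_slices:
        raise ValueError(
            f"cannot discard {n} dummy slices from a {vol.n_slices}-slice volume"
        )
    if vol.slice_order == "descending":
        data = vol.data[:, :, n:]
    else:
        data = vol.data[:, :, : vol.n_slices - n]
    return replace(vol, data=data, n_dummy_slices=0)


def interleave(vol_a: ImageVolume, vol_b: ImageVolume) -> ImageVolume:
    """Merge two slice-interleaved acquisitions, alternating a0,b0,a1,b1,...

    The two stacks must match in-plane and may differ by at most one slice
    (``vol_a`` holding the extra slice).
    """
    a, b = vol_a.data, vol_b.data
    if a.shape[:2] != b.shape[:2]:
        raise ValueError(f"in-plane shapes differ: {a.shape[:2]} vs {b.shape[:2]}")
    if not 0 <= a.shape[2] - b.shape[2] <= 1:
        raise ValueError(
            "slice counts must satisfy 0 <= slices_a - slices_b <= 1, got "
            f"{a.shape[2]} and {b.shape[2]}"
        )
    out = np.empty((*a.shape[:2], a.shape[2] + b.shape[2]), dtype=float)
    out[:, :, 0::2] = a
    out[:, :, 1::2] = b
    return replace(vol_a, data=out)


def de_interleave(vol: ImageVolume) -> tuple[ImageVolume, ImageVolume]:
    """Split an interleaved volume back into its two constituent stacks."""
    return (
        replace(vol, data=vol.data[:, :, 0::2]),
        replace(vol, data=vol.data[:, :, 1::2]),
    )


def _robust_max(data: np.ndarray) -> float:
    return float(np.percentile(data, ROBUST_MAX_PERCENTILE))


def head_mask(vol: ImageVolume, threshold_fraction: float = 0.2) -> MaskVolume:
    """Whole-head mask by intensity thresholding.

    A voxel is included iff its intensity is at least ``threshold_fraction``
    times the robust maximum (99th percentile) of the volume.
    """
    if not (0 < threshold_fraction < 1):
        raise ValueError(
            f"threshold_fraction must be in (0, 1), got {threshold_fraction!r}"
        )
    mask = vol.data >= threshold_fraction * _robust_max(vol.data)
    if not mask.any():
        warnings.warn("head mask is empty", RuntimeWarning, stacklevel=2)
    return MaskVolume(mask)


def compute_mtr_map(
    mt: ImageVolume,
    ref: ImageVolume,
    mask: MaskVolume,
) -> tuple[ImageVolume, dict]:
    """Pixel-wise MTR map ``(ref - mt) / ref * 100`` inside a mask.

    Voxels outside the mask, and masked voxels whose reference intensity is
    at or below the division guard ``eps = 1e-6 * robust max(ref)``, are set
    to NaN; the guard count is reported.

    Returns
    -------
    (ImageVolume, dict)
        The MTR map (percent, NaN where undefined) and a report with the
        number of masked voxels and of guarded (undefined) voxels.
    """
    if mt.data.shape != ref.data.shape or mt.data.shape != mask.data.shape:
        raise ValueError(
            "shape mismatch: "
            f"mt {mt.data.shape}, ref {ref.data.shape}, mask {mask.data.shape}"
        )
    eps = 1e-6 * _robust_max(ref.data)
    out = np.full(mt.data.shape, np.nan)
    valid = mask.data & (ref.data > eps)
    out[valid] = (ref.data[valid] - mt.data[valid]) / ref.data[valid] * 100.0
    report = {
        "n_masked": int(mask.data.sum()),
        "n_undefined_reference": int((mask.data & ~(ref.data > eps)).sum()),
        "division_guard": eps,
    }
    return replace(ref, data=out, n_dummy_slices=0), report


def roi_mean_mtr(mtr_map: ImageVolume, roi: MaskVolume) -> ROIStats:
    """Mean and SD of MTR over the defined (non-NaN) voxels of an ROI."""
    if mtr_map.data.shape != roi.data.shape:
        raise ValueError(
            f"shape mismatch: map {mtr_map.data.shape}, roi {roi.data.shape}"
        )
    if roi.count == 0:
        raise ValueError("ROI is empty")
    values = mtr_map.data[roi.data]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("ROI contains no defined MTR values")
    return ROIStats(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        count=int(values.size),
    )


def snr_difference(
    mt: ImageVolume,
    ref: ImageVolume,
    signal_roi: MaskVolume,
    noise_region: MaskVolume,
) -> float:
    """SNR of the difference image ``ref - mt``.

    Mean of the difference over the signal ROI divided by the standard
    deviation of the difference over a noise-only region (disjoint from the
    signal ROI).
    """
    if signal_roi.count == 0 or noise_region.count == 0:
        raise ValueError("signal ROI and noise region must be non-empty")
    if (signal_roi.data & noise_region.data).any():
        raise ValueError("noise region must be disjoint from the signal ROI")
    diff = ref.data - mt.data
    noise_sd = float(diff[noise_region.data].std(ddof=1))
    if noise_sd == 0:
        raise ValueError("noise region has zero variance")
    return float(diff[signal_roi.data].mean()) / noise_sd
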