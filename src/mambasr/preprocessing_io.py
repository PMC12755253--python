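"""Volume I/O, intensity normalization, degradation and slice selection.

The preprocessing pipeline mirrors a slice-wise MRI super-resolution study:
volumes are percentile-normalized to [0, 1], degraded in the image domain
by linear-interpolation downsampling (then linearly resampled back to the
original grid so LR and HR slices are co-registered), and background-heavy
or edge slices are dropped before pairing.

Conventions: the slicing axis is the volume's third axis; "background"
means exactly-zero voxels after masking/normalization; cell spacing is in
millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeMeta",
    "SliceSample",
    "DegenerateInputError",
    "VolumeFormatError",
    "DEGRADATION_PRESETS",
    "percentile_normalize",
    "resize_linear",
    "degrade_volume",
    "select_slices",
    "apply_mask",
    "read_volume",
    "write_volume",
]


class DegenerateInputError(ValueError):
    """Raised when an input has no usable dynamic range."""


class VolumeFormatError(ValueError):
    """Raised when a volume file cannot be read as NIfTI-1."""


# per-axis downsampling factors (row, col, slice)
DEGRADATION_PRESETS = {
    # isotropic factor 4: 0.8 mm -> 3.2 mm
    "brain4x": (4.0, 4.0, 4.0),
    # factor 9 in-plane read as 3x per in-plane axis (0.66 mm -> ~2 mm),
    # factor 2 through-plane (1.5 mm -> 3 mm)
    "prostate": (3.0, 3.0, 2.0),
    # mild in-plane-only degradation for desk-scale training experiments,
    # where full-scale factors would leave almost no recoverable structure
    # on small phantom slices
    "inplane2x": (2.0, 2.0, 1.0),
}


@dataclass
class VolumeMeta:
    shape: Tuple[int, int, int]
    voxel_spacing: Tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    source_id: str = ""

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive per axis")


@dataclass
class SliceSample:
    """A co-registered LR/HR slice pair on the HR grid, intensities in [0, 1]."""

    lr: np.ndarray
    hr: np.ndarray
    volume_id: str = ""
    slice_index: int = -1
    axis: int = 2

    def __post_init__(self) -> None:
        self.lr = np.asarray(self.lr, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        if self.lr.shape != self.hr.shape:
            raise ValueError("lr and hr slices must share the same grid")


def percentile_normalize(volume: np.ndarray, p_low: float = 1.0, p_high: float = 99.0,
                         mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Map [P_low, P_high] to [0, 1] with clipping.

    Percentiles use linear interpolation between order statistics and are
    computed over all voxels, or over foreground (nonzero-mask) voxels when
    ``mask`` is supplied.
    """
    volume = np.asarray(volume, dtype=float)
    sample = volume[np.asarray(mask) != 0] if mask is not None else volume
    lo, hi = np.percentile(sample, [p_low, p_high])
    if hi == lo:
        raise DegenerateInputError(
            f"percentiles P{p_low} and P{p_high} coincide ({lo}); "
            "volume has no usable dynamic range")
    return np.clip((volume - lo) / (hi - lo), 0.0, 1.0)


def resize_linear(volume: np.ndarray, new_shape: Sequence[int]) -> np.ndarray:
    """Linear-interpolation resampling to ``new_shape`` (endpoint-aligned grid)."""
    volume = np.asarray(volume, dtype=float)
    if len(new_shape) != volume.ndim:
        raise ValueError("new_shape rank must match volume rank")
    coords = np.meshgrid(
        *[np.linspace(0, n - 1, m) if m > 1 else np.array([(n - 1) / 2.0])
          for n, m in zip(volume.shape, new_shape)],
        indexing="ij")
    return ndimage.map_coordinates(volume, np.stack(coords), order=1, mode="nearest")


def degrade_volume(volume: np.ndarray,
                   factors: Sequence[float] | str) -> Tuple[np.ndarray, np.ndarray]:
    """Image-domain degradation by linear-interpolation downsampling.

    Returns ``(lr, lr_on_hr_grid)``: the coarse volume and its linear
    re-upsampling onto the original grid (the network input).  Constant
    volumes are preserved exactly — linear interpolation reproduces
    constants.
    """
    if isinstance(factors, str):
        factors = DEGRADATION_PRESETS[factors]
    volume = np.asarray(volume, dtype=float)
    if len(factors) != volume.ndim:
        raise ValueError("one downsampling factor per axis required")
    if any(f < 1 for f in factors):
        raise ValueError("downsampling factors must be >= 1")
    lr_shape = tuple(int(round(n / f)) for n, f in zip(volume.shape, factors))
    if any(s < 2 for s in lr_shape):
        raise ValueError(
            f"factors {tuple(factors)} leave fewer than 2 samples on some axis "
            f"(LR shape {lr_shape})")
    lr = resize_linear(volume, lr_shape)
    lr_up = resize_linear(lr, volume.shape)
    return lr, lr_up


def select_slices(volume: np.ndarray, background_threshold: float = 0.95,
                  trim: int = 5, axis: int = 2) -> List[int]:
    """Indices of usable slices: trim both ends, drop background-heavy slices.

    A slice is kept when its fraction of exactly-zero voxels is <= the
    threshold (strictly-greater fractions are excluded).  Order-preserving
    and deterministic.
    """
    volume = np.asarray(volume)
    n = volume.shape[axis]
    if n <= 2 * trim:
        raise ValueError(f"volume has {n} slices; needs more than {2 * trim}")
    kept = []
    for i in range(trim, n - trim):
        sl = np.take(volume, i, axis=axis)
        if np.mean(sl == 0) <= background_threshold:
            kept.append(i)
    return kept


def apply_mask(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Elementwise product with a binary mask (mask generation is external)."""
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask)
    if volume.shape != mask.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {volume.shape}")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    return volume * mask


def read_volume(path: str | Path) -> Tuple[np.ndarray, VolumeMeta]:
    """Read a NIfTI-1 volume; slice axis is the last (third) array axis."""
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
        zooms = img.header.get_zooms()[:3]
        affine = np.asarray(img.affine)
    except Exception as exc:  # malformed header/payload
        raise VolumeFormatError(f"cannot read {path} as NIfTI-1: {exc}") from exc
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    meta = VolumeMeta(shape=tuple(data.shape), voxel_spacing=tuple(float(z) for z in zooms),
                      affine=affine, source_id=path.stem)
    return data, meta


def write_volume(path: str | Path, array: np.ndarray, meta: VolumeMeta) -> None:
    import nibabel as nib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.asarray(meta.affine, dtype=float)
    if np.allclose(affine, np.eye(4)):
        # encode the spacing in the affine so it survives the round-trip
        affine = np.diag([*meta.voxel_spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float64), affine)
    nib.save(img, str(path))
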