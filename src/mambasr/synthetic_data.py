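"""Synthetic phantoms and reader tables for end-to-end desk-scale runs.

Phantoms are compositions of overlapping intensity ellipsoids (in the
Shepp-Logan tradition) plus an optional band-limited texture and Gaussian
noise: piecewise-smooth regions with sharp boundaries, the structure a
super-resolution model must restore.  They are a stand-in for anatomy, not
a claim of realism — intensity statistics, coil profiles and k-space
physics of real MRI are deliberately out of scope.

Reader tables are simulated with the simplest structure that gives the
preference statistics a known ground truth: a latent per-method quality,
a per-reader additive bias, and i.i.d. Gaussian noise, rounded and clipped
to the 1-5 Likert range.

Every generator is a pure function of its spec (bit-identical per seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocessing_io import (DegenerateInputError, SliceSample, VolumeMeta,
                               degrade_volume, percentile_normalize,
                               select_slices)

__all__ = [
    "PhantomSpec",
    "SyntheticReaderSpec",
    "generate_phantom_volume",
    "make_paired_dataset",
    "generate_likert_table",
]


@dataclass
class PhantomSpec:
    height: int = 64
    width: int = 64
    depth: int = 20
    n_ellipses: int = 8
    texture_amplitude: float = 0.05
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.height, self.width, self.depth) < 1:
            raise ValueError("phantom dimensions must be positive")
        if self.n_ellipses < 0:
            raise ValueError("n_ellipses must be non-negative")


@dataclass
class SyntheticReaderSpec:
    methods: List[str] = field(default_factory=lambda: ["bicubic", "proposed"])
    n_cases: int = 25
    n_readers: int = 3
    quality_means: List[float] = field(default_factory=lambda: [2.5, 4.2])
    noise_sd: float = 0.5
    reader_bias_sd: float = 0.25
    dataset: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("need at least one method")
        if len(self.quality_means) != len(self.methods):
            raise ValueError("one quality mean per method required")


def generate_phantom_volume(spec: PhantomSpec) -> Tuple[np.ndarray, VolumeMeta]:
    """Piecewise-smooth ellipsoid phantom, values in [0, ~1.2] pre-normalization."""
    rng = np.random.default_rng(spec.seed)
    H, W, Z = spec.height, spec.width, spec.depth
    vol = np.zeros((H, W, Z))
    yy, xx, zz = np.meshgrid(np.linspace(-1, 1, H), np.linspace(-1, 1, W),
                             np.linspace(-1, 1, Z), indexing="ij")
    for _ in range(spec.n_ellipses):
        cy, cx, cz = rng.uniform(-0.55, 0.55, 3)
        ay, ax = rng.uniform(0.15, 0.6, 2)
        az = rng.uniform(0.3, 0.9)
        theta = rng.uniform(0, np.pi)
        amp = rng.uniform(-0.35, 0.6)
        yr = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
        xr = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
        inside = (yr / ay) ** 2 + (xr / ax) ** 2 + ((zz - cz) / az) ** 2 <= 1.0
        vol += amp * inside
    vol = np.clip(vol, 0.0, None)
    if spec.n_ellipses > 0 and spec.texture_amplitude > 0:
        texture = ndimage.gaussian_filter(rng.standard_normal(vol.shape), sigma=1.5)
        vol += spec.texture_amplitude * texture * (vol > 0)
    if spec.noise_sd > 0:
        vol += spec.noise_sd * rng.standard_normal(vol.shape)
    vol = np.clip(vol, 0.0, 1.2)
    meta = VolumeMeta(shape=(H, W, Z), voxel_spacing=(0.8, 0.8, 0.8),
                      source_id=f"phantom-seed{spec.seed}")
    return vol, meta


def make_paired_dataset(spec: PhantomSpec, degradation_preset: str = "brain4x",
                        trim: int = 5, background_threshold: float = 0.95
                        ) -> List[SliceSample]:
    """Phantom -> normalize -> degrade -> slice-select -> paired LR/HR slices.

    The LR member of each pair is the degraded volume linearly resampled
    back onto the HR grid, so both slices are co-registered.
    """
    vol, meta = generate_phantom_volume(spec)
    try:
        hr = percentile_normalize(vol)
    except DegenerateInputError:
        raise DegenerateInputError(
            "phantom spec produced a constant volume; add ellipses or texture")
    _, lr_up = degrade_volume(hr, degradation_preset)
    indices = select_slices(hr, background_threshold=background_threshold, trim=trim)
    return [SliceSample(lr=lr_up[:, :, i], hr=hr[:, :, i],
                        volume_id=meta.source_id, slice_index=i, axis=2)
            for i in indices]


def generate_likert_table(spec: SyntheticReaderSpec) -> pd.DataFrame:
    """Long-format reader-score table with a planted preference structure.

    ``score(i, m) = round(clip(quality_means[m] + reader_bias + noise, 1, 5))``.
    """
    rng = np.random.default_rng(spec.seed)
    reader_bias = rng.normal(0.0, spec.reader_bias_sd, spec.n_readers)
    rows = []
    for reader in range(spec.n_readers):
        for case in range(spec.n_cases):
            for m, q in zip(spec.methods, spec.quality_means):
                noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
                score = int(round(np.clip(q + reader_bias[reader] + noise, 1.0, 5.0)))
                rows.append({"dataset": spec.dataset, "reader": f"R{reader + 1}",
                             "case": f"C{case + 1:03d}", "method": m, "score": score})
    return pd.DataFrame(rows)
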