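"""Core in-memory containers shared across the pipeline.

The central object is :class:`VoxelTimeSeries`: a flat ``voxels x timepoints``
matrix plus the sampling interval and per-voxel bookkeeping (grid coordinates,
tissue class, ROI and network labels).  Keeping the data flat (rather than 4-D)
makes every downstream operation a plain linear-algebra step; the 4-D volume
layout only exists at the NIfTI boundary (see :mod:`fastbold.preprocess`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

# integer codes used in segmentation volumes and per-voxel tissue labels
BACKGROUND, CSF, WM, GM = 0, 1, 2, 3
TISSUE_NAMES = {BACKGROUND: "background", CSF: "CSF", WM: "WM", GM: "GM"}


@dataclass
class VoxelTimeSeries:
    """BOLD data as a ``voxels x timepoints`` matrix with sampling metadata.

    Parameters
    ----------
    values : ndarray, shape (n_voxels, n_timepoints)
        Signal intensities.  No missing values are allowed.
    tr : float
        Sampling interval in seconds (> 0).
    voxel_index : ndarray, shape (n_voxels, 3), int
        Grid coordinate of each row.
    tissue : ndarray, shape (n_voxels,), int, optional
        Tissue code per row (``BACKGROUND``/``CSF``/``WM``/``GM``).
    roi : ndarray, shape (n_voxels,), int, optional
        1-based ROI label per row; 0 = not in any ROI.
    network : ndarray, shape (n_voxels,), int, optional
        1-based network label per row; 0 = none.
    grid_shape : tuple of 3 ints, optional
        Shape of the originating volume grid, if any.
    """

    values: np.ndarray
    tr: float
    voxel_index: np.ndarray
    tissue: Optional[np.ndarray] = None
    roi: Optional[np.ndarray] = None
    network: Optional[np.ndarray] = None
    grid_shape: Optional[tuple] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D voxels x timepoints matrix")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain non-finite entries")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        self.voxel_index = np.asarray(self.voxel_index)
        if self.voxel_index.shape != (self.values.shape[0], 3):
            raise ValueError("voxel_index must be (n_voxels, 3)")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist(self) -> float:
        """Highest representable frequency, 1/(2*tr), in Hz."""
        return 1.0 / (2.0 * self.tr)

    @property
    def duration(self) -> float:
        return self.n_timepoints * self.tr

    def with_values(self, values: np.ndarray, tr: Optional[float] = None) -> "VoxelTimeSeries":
        """Copy of this container with new data (labels carried over)."""
        out = replace(self, values=np.asarray(values, dtype=float))
        if tr is not None:
            out.tr = tr
        return out

    def tissue_mask(self, code: int) -> np.ndarray:
        if self.tissue is None:
            raise ValueError("series carries no tissue labels")
        return self.tissue == code


@dataclass
class PhysioRecording:
    """Simultaneously recorded cardiac and respiratory traces.

    Both traces share one sampling rate (Hz), typically far above the BOLD
    rate, so the fundamental cardiac frequency is directly observable.
    """

    cardiac: np.ndarray
    respiratory: np.ndarray
    rate: float

    def __post_init__(self):
        self.cardiac = np.asarray(self.cardiac, dtype=float)
        self.respiratory = np.asarray(self.respiratory, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.cardiac.ndim != 1 or self.respiratory.ndim != 1:
            raise ValueError("traces must be 1-D")

    @property
    def duration(self) -> float:
        return self.cardiac.size / self.rate

    def times(self) -> np.ndarray:
        return np.arange(self.cardiac.size) / self.rate


@dataclass
class FDSeries:
    """Per-volume framewise displacement (mm), first volume defined as 0."""

    fd: np.ndarray
    radius: float = 50.0

    def __post_init__(self):
        self.fd = np.asarray(self.fd, dtype=float)
        if (self.fd < 0).any():
            raise ValueError("framewise displacement cannot be negative")

    @property
    def mean_fd(self) -> float:
        return float(self.fd.mean())

    @property
    def max_fd(self) -> float:
        return float(self.fd.max())
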