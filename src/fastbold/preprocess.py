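"""Volume I/O and the minimal common preprocessing applied before denoising.

Covers: NIfTI round-trip for the flat voxel-by-time container, high-pass
filtering (> 0.01 Hz by default) realized as regression on a discrete-cosine
drift basis, volume-wise Gaussian smoothing, framewise displacement from
realignment parameters, and temporal SNR.  Motion correction itself,
slice-timing and distortion correction are out of scope.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

from .containers import FDSeries, VoxelTimeSeries

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# I/O


def save_bold(series: VoxelTimeSeries, path) -> str:
    """Write a 4-D NIfTI (TR in the header) plus a JSON provenance sidecar."""
    if series.grid_shape is None:
        raise ValueError("series has no spatial grid; cannot write a volume")
    vol = np.zeros(series.grid_shape + (series.n_timepoints,), dtype=np.float64)
    ijk = series.voxel_index
    vol[ijk[:, 0], ijk[:, 1], ijk[:, 2], :] = series.values
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, series.tr))
    nib.save(img, str(path))
    sidecar = Path(str(path)).with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {"op": "save_bold", "tr": series.tr, "n_voxels": series.n_voxels},
            fh,
        )
    return str(path)


def load_bold(
    path,
    tr: Optional[float] = None,
    segmentation: Optional[np.ndarray] = None,
) -> VoxelTimeSeries:
    """Load a 4-D volume into the flat voxels x timepoints container.

    Voxels are taken from ``segmentation != 0`` when a label volume is given
    (tissue labels are then attached); otherwise every voxel with a nonzero
    time course is kept.  The sampling interval comes from the NIfTI header
    unless ``tr`` overrides it; a missing/invalid header TR is an error.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got {data.ndim}-D")
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if not tr > 0:
            raise ValueError(
                "header carries no valid sampling interval; pass tr explicitly"
            )
    if segmentation is not None:
        mask = segmentation != 0
    else:
        mask = np.abs(data).sum(axis=3) > 0
    ijk = np.argwhere(mask)
    values = data[mask]
    tissue = segmentation[mask] if segmentation is not None else None
    return VoxelTimeSeries(
        values=values, tr=tr, voxel_index=ijk, tissue=tissue,
        grid_shape=data.shape[:3],
    )


# ---------------------------------------------------------------------------
# temporal filtering


def dct_drift_basis(n_timepoints: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine drift regressors spanning frequencies below ``cutoff``.

    Basis function k (k = 1..K) oscillates at k / (2 * n * tr) Hz; K is the
    largest k below the cutoff.  Returns an (n, K) matrix (no intercept).
    """
    duration = n_timepoints * tr
    n_basis = int(np.floor(2.0 * duration * cutoff))
    t = np.arange(n_timepoints) + 0.5
    k = np.arange(1, n_basis + 1)
    return np.cos(np.pi * np.outer(t, k) / n_timepoints)


def highpass(series: VoxelTimeSeries, cutoff: float = 0.01) -> VoxelTimeSeries:
    """Remove slow drifts by projecting out a discrete-cosine basis.

    Regression on the drift basis (rather than an IIR filter) avoids phase
    distortion and makes the operation exactly idempotent.  The per-voxel
    mean is removed along with the drift.
    """
    if cutoff >= series.nyquist:
        raise ValueError(
            f"cutoff {cutoff} Hz is at or above Nyquist {series.nyquist:.3f} Hz"
        )
    basis = dct_drift_basis(series.n_timepoints, series.tr, cutoff)
    design = np.column_stack([np.ones(series.n_timepoints), basis])
    # residual of values' rows against the design
    beta, *_ = np.linalg.lstsq(design, series.values.T, rcond=None)
    resid = series.values - (design @ beta).T
    return series.with_values(resid)


def smooth(
    series: VoxelTimeSeries, fwhm: float, voxel_size: float = 1.0
) -> VoxelTimeSeries:
    """Volume-wise Gaussian smoothing with the stated FWHM (mm).

    ``fwhm=0`` is the identity.  Series without a spatial grid (ROI-course
    mode) are returned unchanged with a logged notice.
    """
    from scipy.ndimage import gaussian_filter

    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return series.with_values(series.values.copy())
    if series.grid_shape is None:
        logger.info("smooth: series has no spatial grid; skipping")
        return series.with_values(series.values.copy())
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size
    ijk = series.voxel_index
    out = np.empty_like(series.values)
    vol = np.zeros(series.grid_shape)
    for tpt in range(series.n_timepoints):
        vol[:] = 0.0
        vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = series.values[:, tpt]
        sm = gaussian_filter(vol, sigma=sigma, mode="constant")
        out[:, tpt] = sm[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
    return series.with_values(out)


# ---------------------------------------------------------------------------
# quality metrics


def framewise_displacement(motion, radius: float = 50.0) -> FDSeries:
    """Framewise displacement from 6 realignment parameters.

    FD at volume t is the sum of absolute backward differences of the three
    translations (mm) and the three rotations converted to arc length on a
    sphere of the given radius (mm).  The first volume is defined as 0.
    """
    params = np.asarray(motion, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion table must have exactly 6 columns")
    diffs = np.abs(np.diff(params, axis=0))
    diffs[:, 3:] *= radius
    fd = np.concatenate([[0.0], diffs.sum(axis=1)])
    return FDSeries(fd=fd, radius=radius)


@dataclass
class TsnrMap:
    """Per-voxel temporal SNR with zero-variance voxels flagged, not infinite."""

    tsnr: np.ndarray
    valid: np.ndarray  # False where the voxel had zero temporal variance

    def region_mean(self, mask: np.ndarray) -> float:
        """Mean tSNR over ``mask``, excluding flagged voxels."""
        use = mask & self.valid
        if not use.any():
            return float("nan")
        return float(self.tsnr[use].mean())


def tsnr(series: VoxelTimeSeries) -> TsnrMap:
    """Temporal SNR: time-series mean divided by its standard deviation."""
    mean = series.values.mean(axis=1)
    sd = series.values.std(axis=1, ddof=1)
    valid = sd > 0
    out = np.zeros(series.n_voxels)
    out[valid] = mean[valid] / sd[valid]
    if not valid.all():
        logger.warning("tsnr: %d zero-variance voxels flagged", (~valid).sum())
    return TsnrMap(tsnr=out, valid=valid)
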