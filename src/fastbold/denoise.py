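"""Construction and removal of data-driven nuisance regressors.

Implements the five denoising families compared by the pipeline —
global-signal regression (GSR), mean WM/CSF regression, anatomical and
temporal CompCor, and an AROMA-like spatial-ICA classifier — plus the
"no correction" baseline.  Each method produces a :class:`NuisanceSet`;
:func:`regress_nuisance` removes it either aggressively (ordinary
least-squares residual) or non-aggressively (joint fit of all ICA component
courses, subtracting only the noise-classified contribution).

Head-motion parameters are deliberately *not* added as regressors to any
method; they only feed the ICA classifier's motion-correlation feature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import BACKGROUND, CSF, GM, WM, VoxelTimeSeries

logger = logging.getLogger(__name__)

METHODS = ("none", "GSR", "WM-CSF", "aCompCor", "tCompCor", "AROMA")


@dataclass
class NuisanceSet:
    """Named nuisance time courses produced by one denoising method.

    ``regressors`` is timepoints x k with zero-mean columns.  For the ICA
    method the set holds *all* component courses and ``noise_flags`` marks
    which of them are to be removed (supporting non-aggressive removal);
    for every other method all columns are noise.
    """

    method: str
    regressors: np.ndarray
    names: list
    mode: str = "aggressive"  # "aggressive" | "nonaggressive"
    noise_flags: Optional[np.ndarray] = None
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.size and self.regressors.shape[0] < self.regressors.shape[1]:
            pass  # caller's responsibility; checked at regression time
        if self.noise_flags is None:
            self.noise_flags = np.ones(self.k, dtype=bool)
        else:
            self.noise_flags = np.asarray(self.noise_flags, dtype=bool)

    @property
    def k(self) -> int:
        return 0 if self.regressors.size == 0 else self.regressors.shape[1]

    def to_confounds_frame(self) -> pd.DataFrame:
        """fMRIPrep-style confounds table (one named column per regressor)."""
        return pd.DataFrame(
            self.regressors.reshape(-1, self.k) if self.k else np.empty((0, 0)),
            columns=self.names,
        )


def no_correction(series: VoxelTimeSeries) -> NuisanceSet:
    """The empty nuisance set (reference condition)."""
    return NuisanceSet(
        method="none",
        regressors=np.empty((series.n_timepoints, 0)),
        names=[],
    )


# ---------------------------------------------------------------------------
# mask helpers


#: in-plane (x, y) cross structuring element; erosion does not eat along z,
#: where typical acquisitions (and the phantom) have far coarser resolution
_INPLANE_CROSS = np.zeros((3, 3, 3), dtype=bool)
_INPLANE_CROSS[1, 1, 1] = True
_INPLANE_CROSS[0, 1, 1] = _INPLANE_CROSS[2, 1, 1] = True
_INPLANE_CROSS[1, 0, 1] = _INPLANE_CROSS[1, 2, 1] = True


def erode_mask(
    mask_rows: np.ndarray, series: VoxelTimeSeries, iterations: int = 1
) -> np.ndarray:
    """Binary erosion of a voxel-row mask on the series' spatial grid."""
    if iterations == 0:
        return mask_rows.copy()
    if series.grid_shape is None:
        raise ValueError("series has no spatial grid; cannot erode")
    vol = np.zeros(series.grid_shape, dtype=bool)
    ijk = series.voxel_index
    vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = mask_rows
    vol = ndimage.binary_erosion(vol, structure=_INPLANE_CROSS, iterations=iterations)
    return vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]]


def _demeaned_mean(series: VoxelTimeSeries, mask: np.ndarray) -> np.ndarray:
    course = series.values[mask].mean(axis=0)
    return course - course.mean()


# ---------------------------------------------------------------------------
# mean-signal methods


def gsr_regressor(
    series: VoxelTimeSeries,
    brain_mask: Optional[np.ndarray] = None,
    csf_mask: Optional[np.ndarray] = None,
) -> NuisanceSet:
    """Global signal: mean time course over the brain mask excluding CSF."""
    if brain_mask is None:
        brain_mask = np.ones(series.n_voxels, dtype=bool)
    if csf_mask is None:
        csf_mask = series.tissue_mask(CSF) if series.tissue is not None else (
            np.zeros(series.n_voxels, dtype=bool)
        )
    use = brain_mask & ~csf_mask
    if not use.any():
        raise ValueError("brain mask is empty after excluding CSF")
    g = _demeaned_mean(series, use)
    if not g.any():
        warnings.warn("global signal is identically zero")
    return NuisanceSet(
        method="GSR", regressors=g[:, None], names=["global_signal"],
        metadata={"n_voxels": int(use.sum())},
    )


def wmcsf_regressors(
    series: VoxelTimeSeries,
    wm_mask: Optional[np.ndarray] = None,
    csf_mask: Optional[np.ndarray] = None,
    erosion_voxels: int = 1,
) -> NuisanceSet:
    """Mean eroded-WM and eroded-CSF time courses."""
    if wm_mask is None:
        wm_mask = series.tissue_mask(WM)
    if csf_mask is None:
        csf_mask = series.tissue_mask(CSF)
    courses, names = [], []
    for name, mask in (("white_matter", wm_mask), ("csf", csf_mask)):
        eroded = erode_mask(mask, series, erosion_voxels)
        if not eroded.any():
            raise ValueError(
                f"erosion by {erosion_voxels} voxel(s) emptied the {name} mask"
            )
        courses.append(_demeaned_mean(series, eroded))
        names.append(name)
    return NuisanceSet(
        method="WM-CSF", regressors=np.column_stack(courses), names=names,
        metadata={"erosion_voxels": erosion_voxels},
    )


# ---------------------------------------------------------------------------
# CompCor


def _compcor_pcs(values: np.ndarray):
    """Principal-component time courses of a voxels x time block.

    Rows are demeaned and variance-normalized (constant rows dropped with a
    log entry) before the SVD; returns (unit-norm component courses T x k,
    explained-variance fractions).
    """
    X = values - values.mean(axis=1, keepdims=True)
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.info("CompCor: dropping %d constant voxels", (~keep).sum())
    X = X[keep] / sd[keep, None]
    if X.shape[0] == 0:
        raise ValueError("no usable voxels for CompCor")
    _, svals, vt = np.linalg.svd(X, full_matrices=False)
    explained = svals**2 / np.sum(svals**2)
    courses = vt - vt.mean(axis=1, keepdims=True)
    return courses.T, explained


def acompcor_regressors(
    series: VoxelTimeSeries,
    wm_mask: Optional[np.ndarray] = None,
    csf_mask: Optional[np.ndarray] = None,
    n_components: int = 5,
    erosion_voxels: int = 1,
) -> NuisanceSet:
    """Anatomical CompCor: leading PCs of the combined eroded WM+CSF block.

    One combined mask with ``n_components`` total components (a per-tissue
    split is not applied here).
    """
    if wm_mask is None:
        wm_mask = series.tissue_mask(WM)
    if csf_mask is None:
        csf_mask = series.tissue_mask(CSF)
    noise_roi = erode_mask(wm_mask, series, erosion_voxels) | erode_mask(
        csf_mask, series, erosion_voxels
    )
    if noise_roi.sum() <= n_components:
        raise ValueError(
            f"eroded WM+CSF mask has {int(noise_roi.sum())} voxels; "
            f"need more than {n_components}"
        )
    courses, explained = _compcor_pcs(series.values[noise_roi])
    return NuisanceSet(
        method="aCompCor",
        regressors=courses[:, :n_components],
        names=[f"a_comp_cor_{i:02d}" for i in range(n_components)],
        metadata={
            "explained_variance": explained[:n_components].tolist(),
            "n_voxels": int(noise_roi.sum()),
        },
    )


def tcompcor_regressors(
    series: VoxelTimeSeries,
    brain_mask: Optional[np.ndarray] = None,
    std_percentile: float = 98.0,
    variance_target: float = 0.5,
) -> NuisanceSet:
    """Temporal CompCor: PCs of the highest-temporal-variance voxels.

    The noise ROI is selected purely temporally — voxels above the
    ``std_percentile`` of temporal standard deviation, irrespective of their
    tissue class.  Components are kept until their cumulative explained
    variance reaches ``variance_target``; all returned components are flagged
    for removal.
    """
    if brain_mask is None:
        brain_mask = np.ones(series.n_voxels, dtype=bool)
    stds = series.values[brain_mask].std(axis=1)
    thr = np.percentile(stds, std_percentile)
    sel = stds > thr
    if not sel.any():
        warnings.warn(
            "all voxels share the same temporal variance; "
            "falling back to a top-k selection"
        )
        k = max(2, int(np.ceil(stds.size * (100 - std_percentile) / 100.0)))
        sel = np.zeros(stds.size, dtype=bool)
        sel[np.argsort(stds)[-k:]] = True
    rows = np.flatnonzero(brain_mask)[sel]
    courses, explained = _compcor_pcs(series.values[rows])
    n_keep = int(np.searchsorted(np.cumsum(explained), variance_target) + 1)
    n_keep = min(n_keep, courses.shape[1])
    return NuisanceSet(
        method="tCompCor",
        regressors=courses[:, :n_keep],
        names=[f"t_comp_cor_{i:02d}" for i in range(n_keep)],
        metadata={
            "explained_variance": explained[:n_keep].tolist(),
            "n_voxels": int(sel.sum()),
            "std_threshold": float(thr),
        },
    )


# ---------------------------------------------------------------------------
# AROMA-like spatial ICA


@dataclass
class ICAComponentReport:
    """Spatial ICA decomposition with per-component features and labels.

    ``features`` has one row per component: ``max_rp_corr`` (maximum absolute
    correlation of the component course with the realignment parameters and
    their derivatives), ``hfc`` (high-frequency content: the fraction of the
    Nyquist range above which half the spectral power lies), ``edge_fract``
    and ``csf_fract`` (fraction of absolute spatial weight in the brain-edge
    rim / in CSF), and the resulting ``classification`` (noise or signal).
    """

    spatial_maps: np.ndarray  # voxels x k
    time_courses: np.ndarray  # timepoints x k
    features: pd.DataFrame
    thresholds: Dict

    @property
    def noise_flags(self) -> np.ndarray:
        return (self.features["classification"] == "noise").to_numpy()

    def to_nuisance_set(self, mode: str = "nonaggressive") -> NuisanceSet:
        courses = self.time_courses - self.time_courses.mean(axis=0)
        return NuisanceSet(
            method="AROMA",
            regressors=courses,
            names=[f"aroma_component_{i:02d}" for i in range(courses.shape[1])],
            mode=mode,
            noise_flags=self.noise_flags,
            metadata={"features": self.features.to_dict(orient="list")},
        )


def high_frequency_content(course: np.ndarray, tr: float, f_min: float = 0.01) -> float:
    """Fraction of the Nyquist range above which half the power lies.

    Computed on the raw periodogram of the course restricted to frequencies
    at or above ``f_min``; 0 means all power at the lowest frequencies, 1 at
    Nyquist.
    """
    from scipy.signal import periodogram

    freqs, pxx = periodogram(course, fs=1.0 / tr, detrend="constant")
    use = freqs >= f_min
    freqs, pxx = freqs[use], pxx[use]
    total = pxx.sum()
    if total == 0:
        return 0.0
    cum = np.cumsum(pxx) / total
    f_half = freqs[np.searchsorted(cum, 0.5)]
    return float(f_half / (1.0 / (2.0 * tr)))


def edge_rim_mask(series: VoxelTimeSeries) -> np.ndarray:
    """Brain voxels with at least one non-brain 6-neighbor (the edge rim)."""
    if series.grid_shape is None:
        raise ValueError("series has no spatial grid")
    vol = np.zeros(series.grid_shape, dtype=bool)
    ijk = series.voxel_index
    vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
    interior = ndimage.binary_erosion(vol)
    rim = vol & ~interior
    return rim[ijk[:, 0], ijk[:, 1], ijk[:, 2]]


def aroma_like_components(
    series: VoxelTimeSeries,
    motion,
    n_components: Optional[int] = None,
    theta_csf: float = 0.10,
    theta_hfc: float = 0.35,
    boundary: tuple = (1.0 / 0.6, 1.0 / 0.6, 1.0),
    seed: int = 0,
    max_retries: int = 6,
) -> ICAComponentReport:
    """Spatial ICA with automatic noise/signal classification.

    A component is noise if its CSF fraction exceeds ``theta_csf``, OR its
    high-frequency content exceeds ``theta_hfc``, OR the point
    (max motion correlation, edge fraction) falls on the noise side of the
    linear boundary ``a * rp + b * edge > c`` with ``boundary = (a, b, c)``.

    This is an AROMA-like classifier, not a bit-exact port: the decomposition
    is FastICA on the demeaned data, and the boundary is a package default
    rather than a trained hyperplane.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must have exactly 6 columns")
    X = series.values - series.values.mean(axis=1, keepdims=True)
    if n_components is None:
        # enough PCs to cover 90% of the variance, capped for tractability
        # and at T//8 so short (e.g. downsampled) series stay estimable
        svals = np.linalg.svd(X, compute_uv=False)
        frac = np.cumsum(svals**2) / np.sum(svals**2)
        cap = max(5, min(30, series.n_timepoints // 8))
        n_components = int(min(np.searchsorted(frac, 0.90) + 1, cap))
        n_components = max(n_components, 2)
    if series.n_timepoints <= n_components:
        raise ValueError("need more timepoints than components")

    # retries use a well-separated fresh seed and a progressively looser
    # stopping tolerance; only a failure at the loosest setting is an error
    tolerances = np.geomspace(5e-4, 3e-2, max_retries)
    last_err = None
    for attempt in range(max_retries):
        ica = FastICA(
            n_components=n_components,
            random_state=(seed + 7919 * attempt) % (2**31),
            max_iter=2000, tol=float(tolerances[attempt]),
            whiten="unit-variance",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                maps = ica.fit_transform(X)  # voxels x k spatial sources
                break
            except ConvergenceWarning as err:  # pragma: no cover - data dependent
                last_err = err
                logger.warning("FastICA did not converge (attempt %d)", attempt + 1)
    else:  # pragma: no cover - data dependent
        raise RuntimeError(f"ICA failed to converge after {max_retries} seeds") from last_err
    courses = ica.mixing_  # timepoints x k

    rp = np.column_stack([motion, np.gradient(motion, axis=0)])
    rp = rp - rp.mean(axis=0)
    rim = edge_rim_mask(series)
    csf = (
        series.tissue_mask(CSF)
        if series.tissue is not None
        else np.zeros(series.n_voxels, dtype=bool)
    )

    rows = []
    a, b, c = boundary
    for k in range(n_components):
        course = courses[:, k] - courses[:, k].mean()
        with np.errstate(invalid="ignore"):
            corrs = [
                abs(np.corrcoef(course, col)[0, 1]) if col.std() > 0 else 0.0
                for col in rp.T
            ]
        max_rp = float(np.nanmax(corrs))
        hfc = high_frequency_content(course, series.tr)
        w = np.abs(maps[:, k])
        # spatial fractions are computed on the suprathreshold part of the
        # map (|w| above 2 SD), approximating the mixture-model thresholding
        # of the canonical classifier; the diffuse noise floor of an ICA map
        # would otherwise dominate the mass fractions
        thr = 2.0 * w.std()
        supra = w > thr
        if supra.sum() >= 10:
            w = np.where(supra, w, 0.0)
        total = w.sum()
        edge_fract = float(w[rim].sum() / total) if total > 0 else 0.0
        csf_fract = float(w[csf].sum() / total) if total > 0 else 0.0
        is_noise = (
            csf_fract > theta_csf
            or hfc > theta_hfc
            or (a * max_rp + b * edge_fract > c)
        )
        rows.append(
            {
                "component": k,
                "max_rp_corr": max_rp,
                "hfc": hfc,
                "edge_fract": edge_fract,
                "csf_fract": csf_fract,
                "classification": "noise" if is_noise else "signal",
            }
        )
    features = pd.DataFrame(rows)
    return ICAComponentReport(
        spatial_maps=maps, time_courses=courses, features=features,
        thresholds={
            "theta_csf": theta_csf, "theta_hfc": theta_hfc, "boundary": boundary,
        },
    )


# ---------------------------------------------------------------------------
# removal


def _drop_collinear(design: np.ndarray, names=None):
    """Drop trailing collinear columns (pivoted-QR rank check)."""
    from scipy.linalg import qr

    if design.shape[1] == 0:
        return design, np.arange(0)
    rank = np.linalg.matrix_rank(design)
    if rank == design.shape[1]:
        return design, np.arange(design.shape[1])
    _, _, piv = qr(design, mode="economic", pivoting=True)
    keep = np.sort(piv[:rank])
    warnings.warn(
        f"rank-deficient design: dropping {design.shape[1] - rank} collinear column(s)"
    )
    return design[:, keep], keep


def regress_nuisance(series: VoxelTimeSeries, nuisance: NuisanceSet) -> VoxelTimeSeries:
    """Remove a nuisance set from every voxel.

    Aggressive mode: per-voxel ordinary-least-squares residual against
    [intercept, regressors]; residuals are exactly orthogonal to the removed
    regressors.  Non-aggressive mode (ICA only): fit *all* component courses
    jointly and subtract only the contribution of the noise-classified ones,
    retaining shared variance that the signal components explain.
    """
    T = series.n_timepoints
    if nuisance.k and nuisance.regressors.shape[0] != T:
        raise ValueError(
            f"regressors have {nuisance.regressors.shape[0]} rows, data has {T}"
        )
    if nuisance.k == 0:
        return series.with_values(series.values - series.values.mean(axis=1, keepdims=True))

    Y = series.values.T  # T x V
    if nuisance.mode == "nonaggressive":
        design = np.column_stack([np.ones(T), nuisance.regressors])
        design, keep = _drop_collinear(design)
        beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
        flags = np.concatenate([[False], nuisance.noise_flags])[keep]
        fitted_noise = design[:, flags] @ beta[flags]
        resid = Y - fitted_noise
        resid = resid - resid.mean(axis=0)
    else:
        design = np.column_stack(
            [np.ones(T), nuisance.regressors[:, nuisance.noise_flags]]
        )
        design, _ = _drop_collinear(design)
        beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
        resid = Y - design @ beta
    return series.with_values(resid.T)
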