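"""Synthetic fast-TR resting-state BOLD cohorts with ground-truth bookkeeping.

The generator emulates a two-group (young/old) cohort acquired with a
sub-second TR, so that the fundamental cardiac frequency (~1 Hz) sits below
the BOLD Nyquist frequency and is directly visible in the signal spectrum.
Each subject's BOLD matrix is an explicit mixture

    y_v(t) = baseline + amplitude * [ sum_c w_{v,c} x_c(t) + sd_v eps_v(t) ]

of standardized component time courses x_c — per-ROI neural signal
band-limited to 0.01-0.1 Hz, a cardiac oscillation with one harmonic and slow
amplitude modulation, a respiratory oscillation likewise, a global
low-frequency nuisance course shared by every brain voxel, and a slow scanner
drift — plus white noise.  Mixing weights are chosen so each component
contributes a stated *fraction of the voxel's variance*, and every course,
weight and fraction is stored in :class:`GroundTruth`, which makes
parameter-recovery testing possible without any real data.

Spatial layout is a small concentric head phantom: a CSF core and CSF edge
rim, a white-matter shell, and a grey-matter ribbon, so that mask erosion and
edge/CSF spatial features behave qualitatively like they do on real
segmentations.  Grey matter is divided into angular-sector networks, each
subdivided into equal-size ROIs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import BACKGROUND, CSF, GM, WM, PhysioRecording, VoxelTimeSeries


class ConfigError(ValueError):
    """A cohort configuration violates one of its invariants."""


class SamplingError(ValueError):
    """A requested sampling rate cannot represent the requested signal."""


#: default per-component variance fractions for a grey-matter voxel
DEFAULT_VARIANCE_FRACTIONS: Dict[str, float] = {
    "neural": 0.12,
    "cardiac": 0.10,
    "respiratory": 0.08,
    "global": 0.10,
    "drift": 0.05,
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the acquisition the pipeline is designed around:
    18 young + 18 old subjects, TR = 0.38 s, 1,950 volumes, 7 networks
    subdivided into ROIs, subject-specific cardiac (~1 Hz) and respiratory
    (~0.27 Hz) frequencies drawn from truncated normals, and weaker
    within-network neural coupling in the old group.
    """

    n_young: int = 18
    n_old: int = 18
    tr: float = 0.38
    n_volumes: int = 1950
    grid_shape: Tuple[int, int, int] = (16, 16, 10)
    n_networks: int = 7
    n_rois: int = 196
    cardiac_freq_mean: float = 1.0
    cardiac_freq_sd: float = 0.1
    cardiac_freq_range: Tuple[float, float] = (0.6, 1.5)
    resp_freq_mean: float = 0.27
    resp_freq_sd: float = 0.04
    resp_freq_range: Tuple[float, float] = (0.15, 0.4)
    within_net_corr_young: float = 0.5
    within_net_corr_old: float = 0.3
    variance_fractions: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VARIANCE_FRACTIONS)
    )
    physio_sampling_rate: float = 50.0
    seed: int = 0
    # amplitude boosts for the cardiac component near CSF and "vessel" GM voxels
    cardiac_csf_boost: float = 3.0
    cardiac_vessel_boost: float = 2.0
    vessel_fraction: float = 0.05
    resp_mod_depth: float = 0.3
    # per-group white-noise scale (old relative to young); mechanism knob only
    noise_scale_old: float = 1.0
    # motion is NOT injected into the BOLD signal by default; this flag adds a
    # motion-locked artifact confined to edge voxels for classifier testing
    inject_motion_artifact: bool = False
    baseline: float = 1000.0
    amplitude: float = 20.0
    allow_aliased_cardiac: bool = False

    def validate(self) -> None:
        if self.n_volumes < 2:
            raise ConfigError("n_volumes must be >= 2")
        if not self.tr > 0:
            raise ConfigError("tr must be > 0")
        if self.n_young < 0 or self.n_old < 0:
            raise ConfigError("group sizes must be non-negative")
        if self.n_networks < 1 or self.n_rois < self.n_networks:
            raise ConfigError("need n_rois >= n_networks >= 1")
        for name, frac in self.variance_fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"variance fraction {name!r}={frac} outside [0, 1]")
        if sum(self.variance_fractions.values()) > 1.0:
            raise ConfigError("variance fractions sum to more than 1")
        if self.within_net_corr_old > self.within_net_corr_young:
            raise ConfigError(
                "within_net_corr_old must not exceed within_net_corr_young"
            )
        for rho in (self.within_net_corr_young, self.within_net_corr_old):
            if not 0.0 <= rho <= 1.0:
                raise ConfigError("within-network correlations must lie in [0, 1]")
        nyquist = 1.0 / (2.0 * self.tr)
        if self.cardiac_freq_mean >= nyquist and not self.allow_aliased_cardiac:
            raise ConfigError(
                f"cardiac_freq_mean {self.cardiac_freq_mean} Hz is not below the "
                f"BOLD Nyquist {nyquist:.3f} Hz; this generator emulates a fast "
                "acquisition (set allow_aliased_cardiac=True to override)"
            )
        if self.physio_sampling_rate <= 2 * self.cardiac_freq_range[1]:
            raise ConfigError("physio_sampling_rate too low for the cardiac band")


@dataclass
class GroundTruth:
    """Everything injected into one subject's BOLD data.

    ``courses`` (components x timepoints, standardized) and ``weights``
    (voxels x components) reproduce the noise-free part of the BOLD matrix:
    ``bold = baseline + amplitude * (weights @ courses) + white noise``.
    ``component_names`` labels the rows of ``courses``; per-ROI neural courses
    are named ``neural_roi_<r>``.  ``fractions`` holds the per-voxel variance
    fraction of each named component family.
    """

    courses: np.ndarray
    component_names: List[str]
    weights: np.ndarray
    fractions: pd.DataFrame  # one row per voxel, one column per family
    network_courses: np.ndarray  # n_networks x T, standardized shared courses
    cardiac_freq: float
    resp_freq: float
    noise_sd: np.ndarray  # per-voxel white-noise weight (fraction^0.5)
    baseline: float
    amplitude: float

    def course(self, name: str) -> np.ndarray:
        return self.courses[self.component_names.index(name)]

    def reconstruct(self) -> np.ndarray:
        """Noise-free BOLD reconstruction from stored weights and courses."""
        return self.baseline + self.amplitude * (self.weights @ self.courses)


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str  # "young" | "old"
    bold: VoxelTimeSeries
    segmentation: np.ndarray  # 3-D tissue label volume
    parcellation: np.ndarray  # 3-D ROI label volume (1-based; 0 = background)
    roi_networks: np.ndarray  # network id (1-based) per ROI, length n_rois
    physio: PhysioRecording
    motion: pd.DataFrame  # n_volumes x 6: trans_{x,y,z} (mm), rot_{x,y,z} (rad)
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# geometry


def _phantom_geometry(grid_shape, n_networks, n_rois, rng, vessel_fraction=0.05):
    """Concentric tissue phantom + angular-sector parcellation.

    Returns (segmentation volume, parcellation volume, roi_networks,
    voxel_index, tissue, roi, network, vessel mask over voxels).
    """
    nx, ny, nz = grid_shape
    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    # normalized ellipsoidal radius: 1.0 at the brain surface
    r = np.sqrt(
        ((ix - cx) / (nx / 2.0)) ** 2
        + ((iy - cy) / (ny / 2.0)) ** 2
        + ((iz - cz) / (nz / 2.0)) ** 2
    )
    seg = np.full(grid_shape, BACKGROUND, dtype=np.int16)
    seg[r <= 0.95] = CSF          # thin CSF rim at the brain edge
    seg[r <= 0.88] = GM           # grey-matter ribbon
    seg[r <= 0.60] = WM           # white-matter shell
    seg[r <= 0.28] = CSF          # ventricle-like CSF core

    gm_mask = seg == GM
    theta = np.arctan2(iy - cy, ix - cx)[gm_mask]  # [-pi, pi)
    order = np.argsort(theta, kind="stable")
    gm_lin = np.flatnonzero(gm_mask.ravel())[order]
    n_gm = gm_lin.size
    if n_gm < n_rois:
        raise ConfigError(
            f"grid too small: {n_gm} GM voxels cannot host {n_rois} ROIs"
        )

    # split GM voxels (ordered by angle) into n_networks contiguous sectors,
    # then split each sector into its share of equal-size ROIs
    parc = np.zeros(grid_shape, dtype=np.int16).ravel()
    roi_networks = np.zeros(n_rois, dtype=np.int16)
    net_bounds = np.linspace(0, n_gm, n_networks + 1).astype(int)
    rois_per_net = np.full(n_networks, n_rois // n_networks)
    rois_per_net[: n_rois % n_networks] += 1
    roi_id = 1
    for k in range(n_networks):
        sector = gm_lin[net_bounds[k]: net_bounds[k + 1]]
        for chunk in np.array_split(sector, rois_per_net[k]):
            if chunk.size == 0:
                raise ConfigError("grid too small: an ROI received no voxels")
            parc[chunk] = roi_id
            roi_networks[roi_id - 1] = k + 1
            roi_id += 1
    parc = parc.reshape(grid_shape)

    brain = seg != BACKGROUND
    voxel_index = np.argwhere(brain)
    tissue = seg[brain]
    roi = parc[brain]
    network = np.zeros_like(roi)
    in_roi = roi > 0
    network[in_roi] = roi_networks[roi[in_roi] - 1]

    vessel = np.zeros(tissue.size, dtype=bool)
    gm_rows = np.flatnonzero(tissue == GM)
    n_vessel = int(round(vessel_fraction * gm_rows.size))
    if n_vessel:
        vessel[rng.choice(gm_rows, size=n_vessel, replace=False)] = True
    return seg, parc, roi_networks, voxel_index, tissue, roi, network, vessel


# ---------------------------------------------------------------------------
# component time courses


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant course")
    return x / sd


def _bandlimited_noise(rng, n, dt, lo, hi):
    """Gaussian noise restricted to [lo, hi] Hz, standardized."""
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=dt)
    keep = (freqs >= lo) & (freqs <= hi)
    if not keep.any():  # degenerate short series: keep the lowest nonzero bin
        keep[min(1, keep.size - 1)] = True
    spec[~keep] = 0.0
    return _standardize(np.fft.irfft(spec, n))


def _oscillation(rng, t, freq, mod_depth, harmonic=0.3):
    """Sinusoid + one harmonic with slow random amplitude modulation."""
    dt = t[1] - t[0]
    slow = _bandlimited_noise(rng, t.size, dt, 0.005, 0.05)
    envelope = 1.0 + mod_depth * slow / max(1.0, np.abs(slow).max())
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
    wave = np.sin(2 * np.pi * freq * t + phase1)
    wave = wave + harmonic * np.sin(4 * np.pi * freq * t + phase2)
    return _standardize(envelope * wave)


def _drift_course(rng, t):
    """Linear trend plus one very slow cosine, random polarity."""
    span = t[-1] - t[0]
    lin = (t - t.mean()) / span
    cos = np.cos(np.pi * t / span + rng.uniform(0, np.pi))
    return _standardize(rng.choice([-1.0, 1.0]) * lin + 0.5 * cos)


def _smooth_weight_field(rng, grid_shape, voxel_index, depth=0.4, sigma=2.0):
    """Smooth positive spatial modulation field, mean ~1, over voxel rows.

    Gives each physiological component its own spatial signature (as on real
    data, where cardiac/respiratory/global effects differ regionally), which
    keeps their spatial maps linearly independent and hence separable by
    spatial decompositions.
    """
    from scipy.ndimage import gaussian_filter

    field = gaussian_filter(rng.standard_normal(grid_shape), sigma=sigma)
    field = (field - field.mean()) / field.std()
    vals = 1.0 + depth * field[
        voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]
    ]
    return np.clip(vals, 0.1, None)


def _truncnorm(rng, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def generate_physio_recording(
    cardiac_freq: float,
    resp_freq: float,
    duration: float,
    rate: float,
    seed: int = 0,
    resp_mod_depth: float = 0.3,
) -> PhysioRecording:
    """Simulate pulse-oximeter and respiratory-belt traces.

    The spectral peak of each trace falls within one frequency bin
    (1/duration Hz) of the requested frequency.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rate <= 2 * cardiac_freq:
        raise SamplingError(
            f"physio rate {rate} Hz cannot represent a {cardiac_freq} Hz pulse"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    cardiac = _oscillation(rng, t, cardiac_freq, mod_depth=0.2, harmonic=0.4)
    cardiac = cardiac + 0.05 * rng.standard_normal(n)
    resp = _oscillation(rng, t, resp_freq, mod_depth=resp_mod_depth, harmonic=0.2)
    resp = resp + 0.05 * rng.standard_normal(n)
    return PhysioRecording(cardiac=cardiac, respiratory=resp, rate=rate)


# ---------------------------------------------------------------------------
# subjects


def _generate_motion(rng, n_volumes):
    step = np.array([0.01, 0.01, 0.01, 2e-4, 2e-4, 2e-4])
    walk = np.cumsum(rng.standard_normal((n_volumes, 6)) * step, axis=0)
    # occasional abrupt movements
    n_spikes = rng.poisson(3)
    for v in rng.integers(1, n_volumes, size=n_spikes):
        walk[v:] += rng.standard_normal(6) * np.array(
            [0.3, 0.3, 0.3, 4e-3, 4e-3, 4e-3]
        )
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    return pd.DataFrame(walk, columns=cols)


def generate_subject(
    config: CohortConfig, group: str, subject_id: str, rng: np.random.Generator
) -> SyntheticSubject:
    """Generate one subject; all randomness comes from ``rng``."""
    T, tr = config.n_volumes, config.tr
    t = np.arange(T) * tr
    seg, parc, roi_networks, voxel_index, tissue, roi, network, vessel = (
        _phantom_geometry(
            config.grid_shape, config.n_networks, config.n_rois, rng,
            vessel_fraction=config.vessel_fraction,
        )
    )
    n_vox = tissue.size
    n_rois = config.n_rois

    f_card = _truncnorm(
        rng, config.cardiac_freq_mean, config.cardiac_freq_sd,
        *config.cardiac_freq_range,
    )
    f_resp = _truncnorm(
        rng, config.resp_freq_mean, config.resp_freq_sd, *config.resp_freq_range
    )

    cardiac = _oscillation(rng, t, f_card, mod_depth=0.2)
    resp = _oscillation(rng, t, f_resp, mod_depth=config.resp_mod_depth, harmonic=0.2)
    glob = _bandlimited_noise(rng, T, tr, 0.005, 0.08)
    drift = _drift_course(rng, t)
    # orthogonalize the realized courses (cardiac kept pure, the rest
    # progressively residualized) so each component's variance contribution
    # is exactly additive — sample cross-covariances would otherwise smear
    # the per-voxel variance bookkeeping by up to ~15%
    basis, _ = np.linalg.qr(np.column_stack([cardiac, resp, glob, drift]))
    cardiac, resp, glob, drift = (_standardize(basis[:, i]) for i in range(4))

    rho = (
        config.within_net_corr_young if group == "young"
        else config.within_net_corr_old
    )
    net_courses = np.stack(
        [_bandlimited_noise(rng, T, tr, 0.01, 0.1) for _ in range(config.n_networks)]
    )
    roi_courses = np.empty((n_rois, T))
    for r in range(n_rois):
        shared = net_courses[roi_networks[r] - 1]
        innov = _bandlimited_noise(rng, T, tr, 0.01, 0.1)
        course = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * innov
        course = course - basis @ (basis.T @ course)  # keep nuisance-free
        roi_courses[r] = _standardize(course)

    vf = config.variance_fractions
    fractions = pd.DataFrame(
        0.0, index=np.arange(n_vox),
        columns=["neural", "cardiac", "respiratory", "global", "drift", "noise"],
    )
    gm_rows = tissue == GM
    fractions.loc[gm_rows, "neural"] = vf.get("neural", 0.0)
    card = np.full(n_vox, vf.get("cardiac", 0.0))
    card[tissue == CSF] *= config.cardiac_csf_boost
    card[vessel] *= config.cardiac_vessel_boost
    # distinct smooth spatial signatures per physiological component
    card *= _smooth_weight_field(rng, config.grid_shape, voxel_index)
    fractions["cardiac"] = card
    fractions["respiratory"] = vf.get("respiratory", 0.0) * _smooth_weight_field(
        rng, config.grid_shape, voxel_index
    )
    fractions["global"] = vf.get("global", 0.0) * _smooth_weight_field(
        rng, config.grid_shape, voxel_index
    )
    fractions["drift"] = vf.get("drift", 0.0)
    # keep each voxel's component variance total below 0.9 so white noise is
    # never squeezed out (boosted CSF voxels could otherwise exceed 1)
    comp_cols = ["neural", "cardiac", "respiratory", "global", "drift"]
    total = fractions[comp_cols].sum(axis=1).to_numpy()
    over = total > 0.9
    if over.any():
        fractions.loc[over, comp_cols] = fractions.loc[over, comp_cols].mul(
            0.9 / total[over], axis=0
        )
    fractions["noise"] = 1.0 - fractions[comp_cols].sum(axis=1)
    if group == "old":
        fractions["noise"] *= config.noise_scale_old ** 2

    names = ["cardiac", "respiratory", "global", "drift"] + [
        f"neural_roi_{r + 1}" for r in range(n_rois)
    ]
    courses = np.vstack([cardiac, resp, glob, drift, roi_courses])
    weights = np.zeros((n_vox, len(names)))
    weights[:, 0] = np.sqrt(fractions["cardiac"])
    weights[:, 1] = np.sqrt(fractions["respiratory"])
    weights[:, 2] = np.sqrt(fractions["global"])
    weights[:, 3] = np.sqrt(fractions["drift"])
    in_roi = roi > 0
    weights[in_roi, 3 + roi[in_roi]] = np.sqrt(
        fractions.loc[in_roi, "neural"].to_numpy()
    )

    noise_sd = np.sqrt(fractions["noise"].to_numpy())
    # make the white-noise realization exactly orthogonal to every stored
    # course and standardize it per voxel: the stated variance fractions
    # then hold exactly in the generated sample, not just in expectation
    eps = rng.standard_normal((n_vox, T))
    course_basis, _ = np.linalg.qr(
        np.column_stack([np.ones(T), courses.T])
    )
    eps -= (eps @ course_basis) @ course_basis.T
    eps /= eps.std(axis=1, keepdims=True)
    values = config.baseline + config.amplitude * (
        weights @ courses + noise_sd[:, None] * eps
    )

    motion = _generate_motion(rng, T)
    if config.inject_motion_artifact:
        # motion-locked artifact confined to the brain-edge rim (CSF rim + the
        # outermost GM), mimicking residual realignment error
        locked = _standardize(np.gradient(motion["trans_z"].to_numpy()))
        rim = tissue == CSF
        values[rim] += config.amplitude * 0.6 * locked

    physio = generate_physio_recording(
        f_card, f_resp, duration=T * tr, rate=config.physio_sampling_rate,
        seed=int(rng.integers(2**31)), resp_mod_depth=config.resp_mod_depth,
    )
    bold = VoxelTimeSeries(
        values=values, tr=tr, voxel_index=voxel_index, tissue=tissue,
        roi=roi, network=network, grid_shape=tuple(config.grid_shape),
    )
    truth = GroundTruth(
        courses=courses, component_names=names, weights=weights,
        fractions=fractions, network_courses=net_courses,
        cardiac_freq=f_card, resp_freq=f_resp, noise_sd=noise_sd,
        baseline=config.baseline, amplitude=config.amplitude,
    )
    return SyntheticSubject(
        subject_id=subject_id, group=group, bold=bold, segmentation=seg,
        parcellation=parc, roi_networks=roi_networks, physio=physio,
        motion=motion, ground_truth=truth,
    )


def iter_cohort(config: CohortConfig) -> Iterator[SyntheticSubject]:
    """Yield subjects one at a time (memory-friendly for large cohorts)."""
    config.validate()
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_young + config.n_old)
    i = 0
    for j in range(config.n_young):
        yield generate_subject(
            config, "young", f"sub-{i + 1:02d}", np.random.default_rng(seeds[i])
        )
        i += 1
    for j in range(config.n_old):
        yield generate_subject(
            config, "old", f"sub-{i + 1:02d}", np.random.default_rng(seeds[i])
        )
        i += 1


def generate_cohort(config: CohortConfig) -> List[SyntheticSubject]:
    """Generate the full cohort (young subjects first, then old).

    Deterministic given ``config.seed``: per-subject generators are spawned
    from one seed sequence, so the same config yields bitwise-identical data.
    """
    return list(iter_cohort(config))


# ---------------------------------------------------------------------------
# on-disk representation


def write_subject(subject: SyntheticSubject, out_dir) -> Dict[str, str]:
    """Write one subject in standard formats; returns the file manifest.

    BOLD as 4-D NIfTI (TR in the header), segmentation/parcellation as label
    NIfTIs, motion as an fMRIPrep-style TSV, physiological traces as
    two-column TSVs, and ground truth as JSON + TSV.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = subject.subject_id
    files = {}

    grid = subject.bold.grid_shape
    vol4d = np.zeros(grid + (subject.bold.n_timepoints,), dtype=np.float32)
    ijk = subject.bold.voxel_index
    vol4d[ijk[:, 0], ijk[:, 1], ijk[:, 2], :] = subject.bold.values
    img = nib.Nifti1Image(vol4d, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, subject.bold.tr))
    files["bold"] = str(out_dir / f"{sid}_bold.nii")
    nib.save(img, files["bold"])

    for name, vol in (("seg", subject.segmentation), ("parc", subject.parcellation)):
        files[name] = str(out_dir / f"{sid}_{name}.nii")
        nib.save(nib.Nifti1Image(vol.astype(np.int16), np.eye(4)), files[name])

    files["motion"] = str(out_dir / f"{sid}_motion.tsv")
    subject.motion.to_csv(files["motion"], sep="\t", index=False)

    tt = subject.physio.times()
    for trace in ("cardiac", "respiratory"):
        files[trace] = str(out_dir / f"{sid}_{trace}.tsv")
        pd.DataFrame(
            {"time": tt, "value": getattr(subject.physio, trace)}
        ).to_csv(files[trace], sep="\t", index=False)

    gt = subject.ground_truth
    files["truth_json"] = str(out_dir / f"{sid}_truth.json")
    with open(files["truth_json"], "w") as fh:
        json.dump(
            {
                "cardiac_freq": gt.cardiac_freq,
                "resp_freq": gt.resp_freq,
                "baseline": gt.baseline,
                "amplitude": gt.amplitude,
                "component_names": gt.component_names,
                "roi_networks": subject.roi_networks.tolist(),
                "group": subject.group,
            },
            fh,
            indent=1,
        )
    files["truth_courses"] = str(out_dir / f"{sid}_truth_courses.tsv")
    pd.DataFrame(gt.courses.T, columns=gt.component_names).to_csv(
        files["truth_courses"], sep="\t", index=False
    )
    return files


def write_cohort(subjects: List[SyntheticSubject], out_dir, config=None) -> str:
    """Write every subject plus a cohort manifest JSON; returns manifest path."""
    out_dir = Path(out_dir)
    manifest = {"subjects": [], "config": None}
    if config is not None:
        cfg = dataclasses.asdict(config)
        cfg["grid_shape"] = list(cfg["grid_shape"])
        manifest["config"] = cfg
    for sub in subjects:
        files = write_subject(sub, out_dir / sub.subject_id)
        manifest["subjects"].append(
            {"id": sub.subject_id, "group": sub.group, "files": files}
        )
    path = out_dir / "cohort.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return str(path)
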