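"""Functional-connectivity metrics and the young/old separability index.

Four layers: (1) template-based rotation (TBR) turns network templates into
per-subject voxelwise connectivity t-maps — templates are predicted as
linear sums of data volumes, and each voxel is then regressed on the
resulting time-weight course; (2) ROI-level Pearson correlation matrices
over a grey-matter parcellation grouped into networks; (3) the
functional-connectivity contrast (FCC), a Wilcoxon rank-sum z comparing
within-network against between-network correlation values; (4) a signed
partition-quality score Q on the subject-by-subject cosine-similarity graph,

    Q = 1/(4m) * sum_ij (A_ij - k_i k_j / (2m)) s_i s_j ,

with s_i = +1 for young and -1 for old subjects, measuring how strongly the
similarity graph splits along the age partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers


@dataclass
class TemplateSet:
    """Spatial network templates aligned to the data's voxel rows."""

    maps: np.ndarray  # voxels x k
    names: List[str]

    def __post_init__(self):
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if self.maps.shape[1] != len(self.names):
            raise ValueError("one name per template required")
        if not np.abs(self.maps).sum(axis=0).all():
            raise ValueError("templates must be nonzero")


@dataclass
class FcMap:
    """Per-network voxelwise connectivity-strength t-map for one subject."""

    tmap: np.ndarray
    network: str
    subject: str = ""
    method: str = ""

    def __post_init__(self):
        if not np.isfinite(self.tmap).all():
            raise ValueError("t-map contains non-finite values")


@dataclass
class ConnectivityMatrix:
    """ROI x ROI Pearson correlations with a network assignment per ROI."""

    matrix: np.ndarray
    networks: np.ndarray  # 1-based network id per ROI

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.networks = np.asarray(self.networks)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n) or self.networks.shape != (n,):
            raise ValueError("matrix must be square with one network id per ROI")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]

    def network_ids(self) -> np.ndarray:
        return np.unique(self.networks)


@dataclass
class ModularityInput:
    """Subject-similarity adjacency with the young/old sign assignment."""

    adjacency: np.ndarray  # subject x subject, symmetric, zero diagonal
    signs: np.ndarray  # +1 young, -1 old
    network: str = ""

    def __post_init__(self):
        A = np.asarray(self.adjacency, dtype=float)
        if not np.allclose(A, A.T, atol=1e-10):
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(A, 0.0)
        self.adjacency = A
        self.signs = np.asarray(self.signs)
        if not np.isin(self.signs, (-1, 1)).all():
            raise ValueError("signs must be +1 or -1")

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def connection_mass(self) -> float:
        return float(self.adjacency.sum() / 2.0)


@dataclass
class ModularityResult:
    q: float
    network: str = ""
    degenerate: bool = False


# ---------------------------------------------------------------------------
# TBR


def tbr_maps(
    series, templates: TemplateSet, subject: str = "", method: str = ""
) -> List[FcMap]:
    """Template-based rotation: one unthresholded t-map per template.

    Stage 1 solves ``template ~ volumes @ w`` by least squares over voxels
    (each acquired volume is a predictor), yielding a time-weight course per
    template.  Stage 2 regresses every voxel's time series on that course and
    reports the t-statistic of the slope.  Stage 1 goes through the volume
    Gram matrix (shared across templates); a rank-deficient volume set gets a
    tiny ridge penalty, logged, which approximates the minimum-norm solution.
    """
    from scipy.linalg import cho_factor, cho_solve, LinAlgError

    D = series.values - series.values.mean(axis=1, keepdims=True)  # V x T
    V, T = D.shape
    if T <= templates.maps.shape[1]:
        raise ValueError("need more timepoints than templates")
    G = D.T @ D  # T x T
    rhs = D.T @ templates.maps  # T x k
    try:
        W = cho_solve(cho_factor(G), rhs)
    except LinAlgError:
        lam = 1e-10 * np.trace(G) / T
        logger.info("tbr_maps: rank-deficient volume set; ridge penalty %.3g", lam)
        W = cho_solve(cho_factor(G + lam * np.eye(T)), rhs)
    out = []
    dof = T - 2
    for k, name in enumerate(templates.names):
        w = W[:, k] - W[:, k].mean()
        ww = w @ w
        if ww == 0:
            raise ValueError(f"template {name!r} produced a zero time course")
        beta = (D @ w) / ww
        resid = D - np.outer(beta, w)
        sigma2 = (resid**2).sum(axis=1) / dof
        se = np.sqrt(sigma2 / ww)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, 0.0)
        out.append(FcMap(tmap=t, network=name, subject=subject, method=method))
    return out


def network_templates(series) -> TemplateSet:
    """Binary network-membership templates from the series' own labels."""
    if series.network is None:
        raise ValueError("series carries no network labels")
    ids = np.unique(series.network[series.network > 0])
    maps = np.stack([(series.network == i).astype(float) for i in ids], axis=1)
    return TemplateSet(maps=maps, names=[f"network-{i}" for i in ids])


# ---------------------------------------------------------------------------
# ROI correlation structure


def roi_connectivity(series, roi_networks: Optional[np.ndarray] = None) -> ConnectivityMatrix:
    """Pearson correlation matrix of ROI-mean time courses.

    ROI labels come from the series (1-based; 0 = none); empty ROIs are
    excluded with a log entry.  ``roi_networks`` maps ROI id r to its network
    (index r-1); when omitted, it is derived from the series' network labels.
    """
    if series.roi is None:
        raise ValueError("series carries no ROI labels")
    roi_ids = np.unique(series.roi[series.roi > 0])
    courses, networks = [], []
    for r in roi_ids:
        rows = series.roi == r
        if not rows.any():  # pragma: no cover - ids come from the data
            logger.info("roi_connectivity: ROI %d empty; excluded", r)
            continue
        courses.append(series.values[rows].mean(axis=0))
        if roi_networks is not None:
            networks.append(roi_networks[r - 1])
        else:
            networks.append(int(series.network[rows][0]))
    C = np.corrcoef(np.vstack(courses))
    np.fill_diagonal(C, 1.0)
    return ConnectivityMatrix(matrix=C, networks=np.asarray(networks))


def _pair_values(cm: ConnectivityMatrix, net: int):
    """Within-network and between-network unique pair values for one network."""
    in_net = cm.networks == net
    iu = np.triu_indices(cm.n_rois, k=1)
    both = in_net[iu[0]] & in_net[iu[1]]
    one = in_net[iu[0]] ^ in_net[iu[1]]
    vals = cm.matrix[iu]
    return vals[both], vals[one]


def network_mean_correlation(cm: ConnectivityMatrix) -> Dict[int, float]:
    """Mean correlation over unique within-network ROI pairs, per network.

    Singleton networks have no pairs and yield NaN with a log entry.
    """
    out = {}
    for net in cm.network_ids():
        within, _ = _pair_values(cm, int(net))
        if within.size == 0:
            logger.warning("network %d has a single ROI; mean undefined", net)
            out[int(net)] = float("nan")
        else:
            out[int(net)] = float(within.mean())
    return out


def ranksum_z(x: np.ndarray, y: np.ndarray) -> float:
    """Wilcoxon rank-sum z for median(x) > median(y).

    Normal approximation with tie correction and no continuity correction:
    z = (U - n1 n2 / 2) / sigma with U the Mann-Whitney statistic of x.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1.0)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    if sigma2 <= 0:
        return 0.0
    return float((u - n1 * n2 / 2.0) / np.sqrt(sigma2))


def fcc(cm: ConnectivityMatrix) -> Dict:
    """Functional-connectivity contrast: per-network rank-sum z and average.

    For each network, within-network pair values are compared against pairs
    linking that network's ROIs to all others; the FCC is the mean z across
    networks.  Higher values mean stronger network segregation.
    """
    per_network = {}
    for net in cm.network_ids():
        within, between = _pair_values(cm, int(net))
        if within.size < 2 or between.size < 2:
            raise ValueError(f"network {net} has too few pairs for the rank-sum test")
        per_network[int(net)] = ranksum_z(within, between)
    values = list(per_network.values())
    return {"per_network": per_network, "fcc": float(np.mean(values))}


# ---------------------------------------------------------------------------
# age-partition modularity


def cosine_similarity_adjacency(
    maps: Sequence[FcMap],
    groups: Sequence[str],
    clip_negative: bool = False,
    center_maps: bool = False,
    network: str = "",
) -> ModularityInput:
    """Subject x subject cosine-similarity graph from per-subject maps.

    ``A_ij`` is the cosine similarity of subjects i and j's maps (diagonal
    zero); ``clip_negative`` zeroes negative similarities, for use with the
    nonnegative-weight null model.  Group labels become signs (+1 young,
    -1 old).

    With ``center_maps`` the grand-mean map is subtracted before computing
    similarities.  Raw connectivity-strength maps share the network geometry
    common to every subject, which pushes all cosines toward 1 and hides
    individual differences — the quantity the partition score is meant to
    detect; the pipeline therefore enables centering by default, while the
    bare operation keeps the literal definition.
    """
    M = np.vstack([m.tmap if isinstance(m, FcMap) else np.asarray(m) for m in maps])
    if center_maps:
        M = M - M.mean(axis=0)
    norms = np.linalg.norm(M, axis=1)
    if (norms == 0).any():
        raise ValueError("a subject map has zero norm")
    U = M / norms[:, None]
    A = U @ U.T
    np.fill_diagonal(A, 0.0)
    if clip_negative:
        A = np.clip(A, 0.0, None)
    signs = np.array([1 if g == "young" else -1 for g in groups])
    if len(signs) != A.shape[0]:
        raise ValueError("one group label per subject map required")
    return ModularityInput(adjacency=A, signs=signs, network=network)


def modularity(inp: ModularityInput) -> ModularityResult:
    """Signed partition quality Q of the similarity graph.

    Literal double sum over all ordered pairs (diagonal terms contribute
    only through the null model since A_ii = 0).  Degenerate graphs with
    non-positive connection mass are flagged rather than scored.
    """
    m = inp.connection_mass
    if m <= 0:
        logger.warning("modularity undefined: connection mass %.3g", m)
        return ModularityResult(q=float("nan"), network=inp.network, degenerate=True)
    k = inp.degrees
    s = inp.signs.astype(float)
    B = inp.adjacency - np.outer(k, k) / (2.0 * m)
    q = float(s @ B @ s / (4.0 * m))
    return ModularityResult(q=q, network=inp.network)


def modularity_permutation_null(
    inp: ModularityInput, n_permutations: int = 1000, seed: int = 0
) -> np.ndarray:
    """Null distribution of Q under random reassignment of the group signs."""
    rng = np.random.default_rng(seed)
    m = inp.connection_mass
    if m <= 0:
        raise ValueError("degenerate graph: no connection mass")
    k = inp.degrees
    B = inp.adjacency - np.outer(k, k) / (2.0 * m)
    out = np.empty(n_permutations)
    s = inp.signs.astype(float)
    for i in range(n_permutations):
        sp = rng.permutation(s)
        out[i] = sp @ B @ sp / (4.0 * m)
    return out


# ---------------------------------------------------------------------------
# group difference maps


def group_difference_tmap(maps_young: Sequence, maps_old: Sequence) -> Dict:
    """Voxelwise unpaired pooled-variance t-map, young minus old.

    Returns the map and its median (negative medians indicate lower
    connectivity strength in the old group).
    """
    Y = np.vstack([m.tmap if isinstance(m, FcMap) else np.asarray(m) for m in maps_young])
    O = np.vstack([m.tmap if isinstance(m, FcMap) else np.asarray(m) for m in maps_old])
    n1, n2 = Y.shape[0], O.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    d = Y.mean(axis=0) - O.mean(axis=0)
    sp2 = ((n1 - 1) * Y.var(axis=0, ddof=1) + (n2 - 1) * O.var(axis=0, ddof=1)) / (
        n1 + n2 - 2
    )
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, d / se, 0.0)
    return {"tmap": t, "median": float(np.median(t)), "df": n1 + n2 - 2}
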