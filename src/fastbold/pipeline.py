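"""End-to-end experiment: cohort -> denoising -> spectra -> connectivity -> stats.

One :class:`ExperimentConfig` drives the whole comparison: every requested
denoising condition (the five methods plus the "none" baseline) is applied to
every subject at the native sampling rate and, to probe generalizability to
conventional acquisitions, after decimating the data by ``downsample_factor``
(keeping every k-th volume with *no* anti-alias filter — aliasing of the
cardiac/respiratory tones into low frequencies is precisely the phenomenon
under study; the effective TR scales accordingly).  Band-power accounting is
computed at the native rate only (it is uninformative once the physiological
bands fold); connectivity metrics are computed at both rates with identical
table schemas so they can be compared as a paired analysis.

Ground truth from the synthetic generator is never consulted here; it is
reserved for the validation suite.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .containers import VoxelTimeSeries
from .connectivity import (
    cosine_similarity_adjacency,
    fcc,
    group_difference_tmap,
    modularity,
    network_mean_correlation,
    network_templates,
    roi_connectivity,
    tbr_maps,
)
from .denoise import (
    METHODS,
    acompcor_regressors,
    aroma_like_components,
    gsr_regressor,
    no_correction,
    regress_nuisance,
    tcompcor_regressors,
    wmcsf_regressors,
)
from .preprocess import highpass, smooth
from .spectra import band_power_table, subject_bands
from .stats import followup_tests, mixed_anova_metric, power_anova
from .synthetic import CohortConfig, iter_cohort

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one full run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    methods: List[str] = field(
        default_factory=lambda: ["none", "GSR", "WM-CSF", "aCompCor", "tCompCor", "AROMA"]
    )
    downsample_factor: int = 5
    downsample_phase: int = 0
    out_dir: str = "fastbold-out"
    seed: int = 0
    # preprocessing
    highpass_cutoff: float = 0.01
    fwhm: float = 5.0
    voxel_size_mm: float = 4.0
    # method flags
    erosion_voxels: int = 1
    acompcor_components: int = 5
    tcompcor_percentile: float = 98.0
    tcompcor_variance_target: float = 0.5
    aroma_n_components: Optional[int] = None
    aroma_theta_csf: float = 0.10
    aroma_theta_hfc: float = 0.35
    aroma_mode: str = "nonaggressive"
    # analysis flags
    spectrum_window: str = "boxcar"
    spectrum_mode: str = "mean-signal"
    # centered maps yield signed cosines, so the pipeline clips negatives by
    # default to keep the nonnegative-weight null model defined; the bare
    # operation still applies the literal signed formula
    clip_negative_modularity: bool = True
    center_modularity_maps: bool = True
    network_sources: bool = True  # include per-network band powers
    make_figures: bool = False

    def validate(self):
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        self.cohort.validate()

    @classmethod
    def from_dict(cls, raw: Dict) -> "ExperimentConfig":
        raw = dict(raw)
        cohort_raw = raw.pop("cohort", {})
        if "grid_shape" in cohort_raw:
            cohort_raw["grid_shape"] = tuple(cohort_raw["grid_shape"])
        if "variance_fractions" in cohort_raw:
            cohort_raw["variance_fractions"] = dict(cohort_raw["variance_fractions"])
        cfg = cls(cohort=CohortConfig(**cohort_raw), **raw)
        cfg.validate()
        return cfg


def downsample(series: VoxelTimeSeries, factor: int, phase: int = 0) -> VoxelTimeSeries:
    """Keep every ``factor``-th volume; no anti-alias filtering by design.

    The new sampling interval is ``factor * tr``; with the default factor 5
    and a 0.38 s native TR that is an effective TR of 1.9 s.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor >= series.n_timepoints:
        raise ValueError(
            f"factor {factor} >= {series.n_timepoints} timepoints"
        )
    if factor == 1:
        return series.with_values(series.values.copy())
    return series.with_values(
        series.values[:, phase::factor], tr=series.tr * factor
    )


def build_nuisance(series, method: str, motion, cfg: ExperimentConfig, seed: int = 0):
    """Dispatch a method name to its regressor constructor."""
    if method == "none":
        return no_correction(series)
    if method == "GSR":
        return gsr_regressor(series)
    if method == "WM-CSF":
        return wmcsf_regressors(series, erosion_voxels=cfg.erosion_voxels)
    if method == "aCompCor":
        return acompcor_regressors(
            series,
            n_components=cfg.acompcor_components,
            erosion_voxels=cfg.erosion_voxels,
        )
    if method == "tCompCor":
        return tcompcor_regressors(
            series,
            std_percentile=cfg.tcompcor_percentile,
            variance_target=cfg.tcompcor_variance_target,
        )
    if method == "AROMA":
        report = aroma_like_components(
            series,
            motion,
            n_components=cfg.aroma_n_components,
            theta_csf=cfg.aroma_theta_csf,
            theta_hfc=cfg.aroma_theta_hfc,
            seed=seed,
        )
        return report.to_nuisance_set(mode=cfg.aroma_mode)
    raise ValueError(f"unknown method {method!r}")


def _subject_metrics(sub, series, method: str, rate: str, rows: list, tmaps: dict):
    """Connectivity metrics for one denoised series; appends long-table rows."""
    templates = network_templates(series)
    maps = [
        m for m in tbr_maps(series, templates, subject=sub.subject_id, method=method)
    ]
    for m in maps:
        tmaps[(method, rate, m.network)] = tmaps.get((method, rate, m.network), [])
        tmaps[(method, rate, m.network)].append((sub.subject_id, sub.group, m.tmap))
    cm = roi_connectivity(series)
    netcorr = network_mean_correlation(cm)
    fcc_res = fcc(cm)
    for net, val in netcorr.items():
        rows.append(
            dict(subject=sub.subject_id, group=sub.group, method=method,
                 rate=rate, network=net, metric="netcorr", value=val)
        )
        rows.append(
            dict(subject=sub.subject_id, group=sub.group, method=method,
                 rate=rate, network=net, metric="fcc_z",
                 value=fcc_res["per_network"][net])
        )
    rows.append(
        dict(subject=sub.subject_id, group=sub.group, method=method,
             rate=rate, network=0, metric="fcc", value=fcc_res["fcc"])
    )


def run_experiment(config: ExperimentConfig) -> Dict:
    """Run the full comparison; writes TSV tables plus a JSON manifest.

    Returns the report bundle (tables as DataFrames plus the manifest dict).
    Failures of an individual method/stage are recorded in the manifest and
    the run continues across the remaining conditions.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "failures": [],
        "tables": {},
    }
    band_rows: List[pd.DataFrame] = []
    metric_rows: list = []
    tmaps: dict = {}
    sources = ["GM", "WM"]
    if config.network_sources:
        sources += [f"network-{k + 1}" for k in range(config.cohort.n_networks)]

    subjects_meta = []
    for sub in iter_cohort(config.cohort):
        subjects_meta.append({"id": sub.subject_id, "group": sub.group})
        pre = highpass(sub.bold, config.highpass_cutoff)
        if config.fwhm > 0:
            pre = smooth(pre, config.fwhm, config.voxel_size_mm)
        bands = subject_bands(sub.physio)
        motion = sub.motion.to_numpy()
        for rate in ("native", "downsampled"):
            if rate == "native":
                series, mot = pre, motion
            else:
                if config.downsample_factor == 1:
                    continue
                series = downsample(
                    pre, config.downsample_factor, config.downsample_phase
                )
                mot = motion[config.downsample_phase :: config.downsample_factor]
            denoised = {}
            for method in config.methods:
                try:
                    nuis = build_nuisance(
                        series, method, mot, config, seed=config.seed
                    )
                    denoised[(sub.subject_id, method)] = regress_nuisance(series, nuis)
                except Exception as err:  # keep going across methods
                    manifest["failures"].append(
                        {
                            "subject": sub.subject_id, "method": method,
                            "rate": rate, "error": repr(err),
                            "trace": traceback.format_exc(limit=3),
                        }
                    )
                    continue
            if rate == "native":
                sub_pre = _Preprocessed(sub, series)
                band_rows.append(
                    band_power_table(
                        [sub_pre], denoised, {sub.subject_id: bands},
                        sources=sources, window=config.spectrum_window,
                    )
                )
            for (sid, method), dser in denoised.items():
                try:
                    _subject_metrics(sub, dser, method, rate, metric_rows, tmaps)
                except Exception as err:
                    manifest["failures"].append(
                        {
                            "subject": sid, "method": method, "rate": rate,
                            "stage": "connectivity", "error": repr(err),
                        }
                    )

    tables: Dict[str, pd.DataFrame] = {}
    tables["band_power"] = (
        pd.concat(band_rows, ignore_index=True) if band_rows else pd.DataFrame()
    )
    tables["connectivity_metrics"] = pd.DataFrame(metric_rows)

    # subject-similarity modularity and group-difference maps per network
    mod_rows, diff_rows = [], []
    for (method, rate, network), entries in sorted(tmaps.items()):
        groups = [g for (_, g, _) in entries]
        maps = [m for (_, _, m) in entries]
        if len(set(groups)) == 2:
            inp = cosine_similarity_adjacency(
                maps, groups, clip_negative=config.clip_negative_modularity,
                center_maps=config.center_modularity_maps, network=network,
            )
            res = modularity(inp)
            mod_rows.append(
                dict(method=method, rate=rate, network=network, q=res.q,
                     degenerate=res.degenerate)
            )
            young = [m for m, g in zip(maps, groups) if g == "young"]
            old = [m for m, g in zip(maps, groups) if g == "old"]
            if len(young) >= 2 and len(old) >= 2:
                diff = group_difference_tmap(young, old)
                diff_rows.append(
                    dict(method=method, rate=rate, network=network,
                         median_t=diff["median"])
                )
    tables["modularity"] = pd.DataFrame(mod_rows)
    tables["diff_tmap_medians"] = pd.DataFrame(diff_rows)

    # group statistics
    stats_tables = {}
    bp = tables["band_power"]
    if not bp.empty and "none" in config.methods:
        anova_bp = bp[(bp["method"] != "none") & bp["tissue"].isin(["GM", "WM"])]
        for band in anova_bp["band"].unique():
            try:
                res = power_anova(anova_bp, band=band)
                stats_tables[f"anova_power_{band}"] = res.table
                sub_tab = anova_bp[anova_bp["band"] == band]
                for tissue in ("GM", "WM"):
                    fam = sub_tab[sub_tab["tissue"] == tissue].rename(
                        columns={"frac_change": "value"}
                    )
                    stats_tables[f"followup_power_{band}_{tissue}_method"] = (
                        followup_tests(fam, family="method")
                    )
            except Exception as err:
                manifest["failures"].append(
                    {"stage": f"power_anova:{band}", "error": repr(err)}
                )
    cmx = tables["connectivity_metrics"]
    if not cmx.empty:
        for rate in cmx["rate"].unique():
            for metric, agg in (("netcorr", True), ("fcc", False)):
                try:
                    sel = cmx[(cmx["rate"] == rate) & (cmx["metric"] == metric)]
                    if agg:  # average over networks per subject x method
                        sel = (
                            sel.groupby(
                                ["subject", "group", "method"], observed=True
                            )["value"].mean().reset_index()
                        )
                    if sel.empty:
                        continue
                    res = mixed_anova_metric(sel)
                    stats_tables[f"anova_{metric}_{rate}"] = res.table
                    stats_tables[f"followup_{metric}_{rate}_method"] = followup_tests(
                        sel, family="method"
                    )
                except Exception as err:
                    manifest["failures"].append(
                        {"stage": f"mixed_anova:{metric}:{rate}", "error": repr(err)}
                    )
    tables.update(stats_tables)

    for name, tab in tables.items():
        path = out_dir / f"{name}.tsv"
        tab.to_csv(path, sep="\t", index=False)
        manifest["tables"][name] = str(path)
    manifest["subjects"] = subjects_meta
    if config.make_figures:
        try:
            _make_figures(tables, out_dir)
        except Exception as err:  # plotting is best-effort
            manifest["failures"].append({"stage": "figures", "error": repr(err)})
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return {"tables": tables, "manifest": manifest}


class _Preprocessed:
    """Minimal subject view exposing the preprocessed series to the table op."""

    def __init__(self, sub, series):
        self.subject_id = sub.subject_id
        self.group = sub.group
        self.bold = series


def _config_dict(config: ExperimentConfig) -> Dict:
    raw = dataclasses.asdict(config)
    raw["cohort"]["grid_shape"] = list(raw["cohort"]["grid_shape"])
    return raw


def _make_figures(tables: Dict[str, pd.DataFrame], out_dir: Path):
    """Bar-with-SD summaries of the band-power and metric tables."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bp = tables.get("band_power")
    if bp is not None and not bp.empty:
        sub = bp[(bp["method"] != "none") & bp["tissue"].isin(["GM", "WM"])]
        bands = sub["band"].unique()
        fig, axes = plt.subplots(
            2, len(bands), figsize=(4 * len(bands), 6), squeeze=False
        )
        for col, band in enumerate(bands):
            for row, tissue in enumerate(("GM", "WM")):
                ax = axes[row][col]
                sel = sub[(sub["band"] == band) & (sub["tissue"] == tissue)]
                stats = sel.groupby(["method", "group"], observed=True)[
                    "frac_change"
                ].agg(["mean", "std"]).reset_index()
                for i, grp in enumerate(("young", "old")):
                    g = stats[stats["group"] == grp]
                    x = np.arange(len(g)) + (i - 0.5) * 0.35
                    ax.bar(
                        x, g["mean"], 0.35, yerr=g["std"],
                        label=grp, color=["0.7", "0.2"][i],
                    )
                ax.set_xticks(np.arange(stats["method"].nunique()))
                ax.set_xticklabels(sorted(sel["method"].unique()), rotation=45)
                ax.set_title(f"{tissue} {band}")
                ax.axhline(0, color="k", lw=0.5)
        axes[0][0].legend()
        fig.tight_layout()
        fig.savefig(out_dir / "band_power.png", dpi=100)
        plt.close(fig)
    cmx = tables.get("connectivity_metrics")
    if cmx is not None and not cmx.empty:
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        for ax, metric in zip(axes, ("netcorr", "fcc")):
            sel = cmx[(cmx["metric"] == metric) & (cmx["rate"] == "native")]
            stats = sel.groupby("method", observed=True)["value"].agg(
                ["mean", "std"]
            ).reset_index()
            ax.bar(stats["method"], stats["mean"], yerr=stats["std"], color="0.6")
            ax.set_title(metric)
            ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        fig.savefig(out_dir / "connectivity_metrics.png", dpi=100)
        plt.close(fig)
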