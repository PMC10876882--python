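"""Group-level statistics on long-format metric tables.

Two ANOVA entry points mirror the two analyses the pipeline runs:
``power_anova`` (fractional power change; age group between subjects, tissue
and method within subjects, plus the age x method interaction) and
``mixed_anova_metric`` (a connectivity metric; age between, method within).
Both are computed as classical balanced split-plot ANOVAs: each whole-plot
effect is tested against subjects-within-group, and each within-subject
effect against its own interaction-with-subjects stratum.  On a balanced
design this is the closed form of the Gaussian mixed model with a random
subject intercept (Wald F with containment denominator degrees of freedom),
evaluated without iterative fitting.  Unbalanced or incomplete designs are
rejected with an explicit list of the offending cells.

Follow-up comparisons are paired t-tests between methods and unpaired
t-tests between age groups, Benjamini-Hochberg corrected within each family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class AnovaResult:
    """Per-factor F statistics: one row per tested effect."""

    table: pd.DataFrame  # columns: effect, F, df1, df2, p

    def p(self, effect: str) -> float:
        return float(self.table.set_index("effect").loc[effect, "p"])

    def f(self, effect: str) -> float:
        return float(self.table.set_index("effect").loc[effect, "F"])


def _check_balanced(table: pd.DataFrame, subject: str, factors: Sequence[str]):
    counts = table.groupby([subject, *factors], observed=True).size()
    if (counts != 1).any():
        bad = counts[counts != 1].index.tolist()[:5]
        raise ValueError(f"duplicated cells in design: {bad}")
    expected = 1
    levels = {f: table[f].nunique() for f in factors}
    for f in factors:
        expected *= levels[f]
    per_subject = table.groupby(subject, observed=True).size()
    if (per_subject != expected).any():
        missing = per_subject[per_subject != expected].index.tolist()[:5]
        raise ValueError(
            f"incomplete design: subjects {missing} lack some of the "
            f"{expected} factor cells {levels}"
        )


def _f_row(effect, ss_eff, df_eff, ss_err, df_err):
    if df_eff <= 0 or df_err <= 0:  # e.g. a single group: no age contrast
        return None
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    if ms_err <= 0:
        F = 0.0 if ms_eff <= 0 else np.inf
    else:
        F = ms_eff / ms_err
    p = float(sps.f.sf(F, df_eff, df_err)) if np.isfinite(F) else 0.0
    return {"effect": effect, "F": float(F), "df1": df_eff, "df2": df_err, "p": p}


def power_anova(
    table: pd.DataFrame,
    band: Optional[str] = None,
    value: str = "frac_change",
) -> AnovaResult:
    """Split-plot ANOVA of fractional power change for one frequency band.

    Expects long-format rows with columns ``subject``, ``group`` (young/old),
    ``tissue``, ``method`` and the value column; ``band`` filters a
    multi-band table first (each band is analyzed separately).  Tests the
    age-group main effect (against subjects within group), the tissue and
    method main effects and the age x method interaction (each within effect
    against its interaction-with-subjects stratum).
    """
    df = table if band is None else table[table["band"] == band]
    if df.empty:
        raise ValueError(f"no rows for band {band!r}")
    _check_balanced(df, "subject", ["tissue", "method"])
    y = df[value].astype(float)
    mu = y.mean()

    g_of = df.groupby("subject", observed=True)["group"].first()
    n_subj = g_of.size
    n_grp = g_of.nunique()
    n_t = df["tissue"].nunique()
    n_m = df["method"].nunique()

    m_s = df.groupby("subject", observed=True)[value].mean()
    m_g = df.groupby("group", observed=True)[value].mean()
    m_t = df.groupby("tissue", observed=True)[value].mean()
    m_m = df.groupby("method", observed=True)[value].mean()
    m_gm = df.groupby(["group", "method"], observed=True)[value].mean()
    m_gt = df.groupby(["group", "tissue"], observed=True)[value].mean()
    m_sm = df.groupby(["subject", "method"], observed=True)[value].mean()
    m_st = df.groupby(["subject", "tissue"], observed=True)[value].mean()
    n_per_group = g_of.value_counts()

    ss_age = n_t * n_m * float((n_per_group * (m_g - mu) ** 2).sum())
    ss_subj = n_t * n_m * float(((m_s - m_g[g_of].to_numpy()) ** 2).sum())

    ss_tissue = n_subj * n_m * float(((m_t - mu) ** 2).sum())
    # tissue x subject(group) stratum
    dev_st = (
        m_st
        - m_s.reindex(m_st.index.get_level_values("subject")).to_numpy()
        - m_gt.reindex(
            pd.MultiIndex.from_arrays(
                [
                    g_of[m_st.index.get_level_values("subject")],
                    m_st.index.get_level_values("tissue"),
                ]
            )
        ).to_numpy()
        + m_g[g_of[m_st.index.get_level_values("subject")]].to_numpy()
    )
    ss_ts = n_m * float((dev_st**2).sum())

    ss_method = n_subj * n_t * float(((m_m - mu) ** 2).sum())
    gm_idx = pd.MultiIndex.from_arrays(
        [
            g_of[m_sm.index.get_level_values("subject")],
            m_sm.index.get_level_values("method"),
        ]
    )
    dev_sm = (
        m_sm
        - m_s.reindex(m_sm.index.get_level_values("subject")).to_numpy()
        - m_gm.reindex(gm_idx).to_numpy()
        + m_g[g_of[m_sm.index.get_level_values("subject")]].to_numpy()
    )
    ss_ms = n_t * float((dev_sm**2).sum())

    dev_gm = (
        m_gm
        - m_g.reindex(m_gm.index.get_level_values("group")).to_numpy()
        - m_m.reindex(m_gm.index.get_level_values("method")).to_numpy()
        + mu
    )
    weights = n_per_group[dev_gm.index.get_level_values("group")].to_numpy()
    ss_agemethod = n_t * float((weights * dev_gm**2).sum())

    rows = [
        _f_row("age", ss_age, n_grp - 1, ss_subj, n_subj - n_grp),
        _f_row("tissue", ss_tissue, n_t - 1, ss_ts, (n_t - 1) * (n_subj - n_grp)),
        _f_row("method", ss_method, n_m - 1, ss_ms, (n_m - 1) * (n_subj - n_grp)),
        _f_row(
            "age:method",
            ss_agemethod,
            (n_grp - 1) * (n_m - 1),
            ss_ms,
            (n_m - 1) * (n_subj - n_grp),
        ),
    ]
    return AnovaResult(table=pd.DataFrame([r for r in rows if r is not None]))


def mixed_anova_metric(table: pd.DataFrame, value: str = "value") -> AnovaResult:
    """Mixed ANOVA: age group between subjects, denoising method within.

    Split-plot decomposition — the age effect is tested against subjects
    within group; the method effect and the age x method interaction against
    the method x subjects-within-group stratum.
    """
    _check_balanced(table, "subject", ["method"])
    y = table[value].astype(float)
    mu = y.mean()
    g_of = table.groupby("subject", observed=True)["group"].first()
    n_subj, n_grp = g_of.size, g_of.nunique()
    n_m = table["method"].nunique()
    n_per_group = g_of.value_counts()

    m_s = table.groupby("subject", observed=True)[value].mean()
    m_g = table.groupby("group", observed=True)[value].mean()
    m_m = table.groupby("method", observed=True)[value].mean()
    m_gm = table.groupby(["group", "method"], observed=True)[value].mean()

    ss_age = n_m * float((n_per_group * (m_g - mu) ** 2).sum())
    ss_subj = n_m * float(((m_s - m_g[g_of].to_numpy()) ** 2).sum())
    ss_method = n_subj * float(((m_m - mu) ** 2).sum())
    dev_gm = (
        m_gm
        - m_g.reindex(m_gm.index.get_level_values("group")).to_numpy()
        - m_m.reindex(m_gm.index.get_level_values("method")).to_numpy()
        + mu
    )
    weights = n_per_group[dev_gm.index.get_level_values("group")].to_numpy()
    ss_gm = float((weights * dev_gm**2).sum())

    cell = table.set_index(["subject", "method"])[value].astype(float)
    pred = (
        m_s.reindex(cell.index.get_level_values("subject")).to_numpy()
        + m_gm.reindex(
            pd.MultiIndex.from_arrays(
                [
                    g_of[cell.index.get_level_values("subject")],
                    cell.index.get_level_values("method"),
                ]
            )
        ).to_numpy()
        - m_g[g_of[cell.index.get_level_values("subject")]].to_numpy()
    )
    ss_ms = float(((cell.to_numpy() - pred) ** 2).sum())
    df_ms = (n_m - 1) * (n_subj - n_grp)

    rows = [
        _f_row("age", ss_age, n_grp - 1, ss_subj, n_subj - n_grp),
        _f_row("method", ss_method, n_m - 1, ss_ms, df_ms),
        _f_row("age:method", ss_gm, (n_grp - 1) * (n_m - 1), ss_ms, df_ms),
    ]
    return AnovaResult(table=pd.DataFrame([r for r in rows if r is not None]))


# ---------------------------------------------------------------------------
# follow-up tests


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def followup_tests(
    table: pd.DataFrame, family: str, value: str = "value"
) -> pd.DataFrame:
    """All pairwise comparisons within one factor family, BH-corrected.

    ``family='method'``: paired t-tests between denoising methods (same
    subjects under each method).  ``family='group'``: unpaired t-test young
    vs old.  Each row carries the raw and adjusted p and a direction mark
    ('>' when the first level's mean exceeds the second's).  Zero within-pair
    variance makes the paired t undefined; such comparisons are flagged NaN
    with a warning.
    """
    if family not in ("method", "group"):
        raise ValueError("family must be 'method' or 'group'")
    levels = sorted(table[family].unique())
    if len(levels) < 2:
        raise ValueError(f"need at least 2 levels of {family!r}")
    rows = []
    for a, b in combinations(levels, 2):
        if family == "method":
            wide = table.pivot_table(
                index="subject", columns="method", values=value, observed=True
            )
            xa, xb = wide[a].to_numpy(), wide[b].to_numpy()
            diff = xa - xb
            if np.allclose(diff.std(ddof=1), 0):
                if np.allclose(diff, 0):
                    warnings.warn(f"paired t undefined for identical {a} and {b}")
                    t, p = float("nan"), float("nan")
                else:
                    t = float(np.inf * np.sign(diff.mean()))
                    p = 0.0
            else:
                t, p = sps.ttest_rel(xa, xb)
        else:
            xa = table.loc[table[family] == a, value].to_numpy()
            xb = table.loc[table[family] == b, value].to_numpy()
            t, p = sps.ttest_ind(xa, xb)
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "t": float(t),
                "p_raw": float(p),
                "direction": ">" if np.nanmean(xa) > np.nanmean(xb) else "<",
            }
        )
    out = pd.DataFrame(rows)
    finite = out["p_raw"].notna()
    out["p_adj"] = np.nan
    out.loc[finite, "p_adj"] = bh_adjust(out.loc[finite, "p_raw"].to_numpy())
    return out
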