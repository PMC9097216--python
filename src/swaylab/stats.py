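"""Inference layer: transforms, mixed ANOVA, effect sizes, BH post-hocs,
ICC(1,1) reliability with an exclusion gate, BCa bootstrap CIs, summary
t-tests and pediatric weight-status classification.

The study design is 2 (group, between) × 2 (condition, within) × 2 (visit,
within) with one observation per cell.  All factors have two levels, so no
sphericity correction is needed; each within effect is tested against its
own effect × subjects-within-groups mean square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from swaylab.io_config import logger

ANOVA_EFFECTS = [
    "group",
    "condition",
    "visit",
    "group x condition",
    "group x visit",
    "condition x visit",
    "group x condition x visit",
]

ICC_BANDS = ((0.40, "poor"), (0.60, "fair"), (0.75, "good"), (1.00, "excellent"))


def log1_transform(values: np.ndarray) -> np.ndarray:
    """ln(x + 1) normalising transform."""
    values = np.asarray(values, dtype=float)
    if np.any(values <= -1):
        raise ValueError("log1 transform requires values > -1")
    return np.log1p(values)


def antilog1(values: np.ndarray) -> np.ndarray:
    """Inverse of :func:`log1_transform` for reporting on the original scale."""
    return np.expm1(np.asarray(values, dtype=float))


def cohens_f_from_eta(partial_eta_sq: float) -> float:
    """Cohen's f = sqrt(eta² / (1 − eta²))."""
    if not (0 <= partial_eta_sq < 1):
        raise ValueError(f"partial eta² must lie in [0, 1), got {partial_eta_sq}")
    return float(np.sqrt(partial_eta_sq / (1 - partial_eta_sq)))


def cohens_f_from_t(t: float, df: int) -> float:
    """Cohen's f for a two-group comparison via eta² = t² / (t² + df)."""
    if df <= 0:
        raise ValueError(f"df must be positive, got {df}")
    return cohens_f_from_eta(t**2 / (t**2 + df))


def independent_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test from summary statistics.

    Returns (t, df, two-sided p).  With equal group sizes the pooled t is
    identical to the unpooled one.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    if se == 0:
        return (0.0, df, 1.0) if mean1 == mean2 else (np.inf, df, 0.0)
    t = (mean1 - mean2) / se
    p = 2 * sstats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


# ---------------------------------------------------------------------------
# three-way mixed ANOVA (2 between-levels, 2×2 within)


@dataclass
class AnovaRow:
    effect: str
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    f: float


def _cell_pivot(table: pd.DataFrame) -> pd.DataFrame:
    """Validate the balanced complete 2×2×2 design and pivot to wide cells."""
    required = {"subject", "group", "condition", "visit", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns {sorted(missing)}")
    if table["value"].isna().any():
        bad = table.loc[table["value"].isna(), ["subject", "condition", "visit"]]
        raise ValueError(f"missing values in cells:\n{bad.to_string(index=False)}")
    wide = table.pivot_table(
        index=["group", "subject"],
        columns=["condition", "visit"],
        values="value",
        aggfunc="first",
    )
    counts = table.groupby(["subject", "condition", "visit"]).size()
    if (counts > 1).any():
        raise ValueError(f"duplicated cells:\n{counts[counts > 1].to_string()}")
    if wide.isna().any().any():
        holes = wide.stack(list(range(wide.columns.nlevels)), future_stack=True)
        holes = holes[holes.isna()]
        raise ValueError(f"incomplete design; empty cells:\n{holes.index.tolist()}")
    if wide.shape[1] != 4:
        raise ValueError(f"expected 2 conditions × 2 visits, found columns {wide.columns.tolist()}")
    n_per_group = wide.groupby(level="group").size()
    if len(n_per_group) != 2:
        raise ValueError(f"expected exactly 2 groups, found {n_per_group.index.tolist()}")
    if n_per_group.nunique() != 1:
        raise ValueError(f"unbalanced group sizes: {n_per_group.to_dict()}")
    if n_per_group.iloc[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    return wide


def mixed_anova_2x2x2(table: pd.DataFrame) -> pd.DataFrame:
    """Univariate mixed-model ANOVA for the 2×2×2 design.

    ``table`` is long-format with columns subject, group, condition, visit,
    value (one row per cell).  The between effect is tested against the
    subjects-within-groups mean square; each within effect against its own
    interaction with subjects-within-groups.  Returns one row per effect
    with F, df, p, partial eta² and Cohen's f.
    """
    wide = _cell_pivot(table)
    n = wide.groupby(level="group").size().iloc[0]  # subjects per group
    y = wide.to_numpy()  # (2n, 4) rows: subjects ordered by group
    # reshape to (group, subject, condition, visit)
    conds = sorted({c for c, _ in wide.columns})
    visits = sorted({v for _, v in wide.columns})
    order = [(c, v) for c in conds for v in visits]
    y = y[:, [wide.columns.get_loc(cv) for cv in order]].reshape(2, n, 2, 2)

    grand = y.mean()
    m_g = y.mean(axis=(1, 2, 3))  # (2,)
    m_gs = y.mean(axis=(2, 3))  # (2, n)
    m_c = y.mean(axis=(0, 1, 3))  # (2,)
    m_v = y.mean(axis=(0, 1, 2))  # (2,)
    m_gc = y.mean(axis=(1, 3))  # (2, 2)
    m_gv = y.mean(axis=(1, 2))  # (2, 2)
    m_cv = y.mean(axis=(0, 1))  # (2, 2)
    m_gcv = y.mean(axis=1)  # (2, 2, 2)
    m_gsc = y.mean(axis=3)  # (2, n, 2)
    m_gsv = y.mean(axis=2)  # (2, n, 2)

    ss_g = 4 * n * np.sum((m_g - grand) ** 2)
    ss_s = 4 * np.sum((m_gs - m_g[:, None]) ** 2)
    ss_c = 4 * n * np.sum((m_c - grand) ** 2)
    ss_v = 4 * n * np.sum((m_v - grand) ** 2)
    ss_gc = 2 * n * np.sum((m_gc - m_g[:, None] - m_c[None, :] + grand) ** 2)
    ss_gv = 2 * n * np.sum((m_gv - m_g[:, None] - m_v[None, :] + grand) ** 2)
    ss_cv = 2 * n * np.sum((m_cv - m_c[:, None] - m_v[None, :] + grand) ** 2)
    ss_gcv = n * np.sum(
        (
            m_gcv
            - m_gc[:, :, None]
            - m_gv[:, None, :]
            - m_cv[None, :, :]
            + m_g[:, None, None]
            + m_c[None, :, None]
            + m_v[None, None, :]
            - grand
        )
        ** 2
    )
    ss_cs = 2 * np.sum(
        (m_gsc - m_gs[:, :, None] - m_gc[:, None, :] + m_g[:, None, None]) ** 2
    )
    ss_vs = 2 * np.sum(
        (m_gsv - m_gs[:, :, None] - m_gv[:, None, :] + m_g[:, None, None]) ** 2
    )
    ss_total = np.sum((y - grand) ** 2)
    ss_cvs = ss_total - (
        ss_g + ss_s + ss_c + ss_v + ss_gc + ss_gv + ss_cv + ss_gcv + ss_cs + ss_vs
    )

    df_err = 2 * (n - 1)
    rows = []
    for effect, ss_eff, ss_err in [
        ("group", ss_g, ss_s),
        ("condition", ss_c, ss_cs),
        ("visit", ss_v, ss_vs),
        ("group x condition", ss_gc, ss_cs),
        ("group x visit", ss_gv, ss_vs),
        ("condition x visit", ss_cv, ss_cvs),
        ("group x condition x visit", ss_gcv, ss_cvs),
    ]:
        ms_eff = ss_eff / 1
        ms_err = ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else np.inf
        p = float(sstats.f.sf(F, 1, df_err)) if np.isfinite(F) else 0.0
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        rows.append(
            AnovaRow(
                effect=effect,
                F=float(F),
                df1=1,
                df2=df_err,
                p=p,
                partial_eta_sq=float(eta),
                f=cohens_f_from_eta(min(eta, 1 - 1e-15)),
            )
        )
    return pd.DataFrame([vars(r) for r in rows])


# ---------------------------------------------------------------------------
# post-hoc comparisons


def bh_adjust(pvals: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def posthoc_pairwise_bh(
    table: pd.DataFrame, anova: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Follow-up pairwise comparisons with BH control, after visit pooling.

    ``table`` is the long-format cell table of one measure × axis (already
    transformed).  When every visit-involving ANOVA term is negligible
    (p > alpha), cell values are pooled (averaged) across visit first.  The
    family comprises the group contrast within each condition (independent
    t) and the condition contrast within each group (paired t); BH step-up
    runs over that family.
    """
    visit_terms = anova[anova["effect"].str.contains("visit")]
    pool_visits = bool((visit_terms["p"] > alpha).all())
    data = table.copy()
    if pool_visits:
        data = (
            data.groupby(["group", "subject", "condition"], as_index=False)["value"].mean()
        )
        data["visit"] = 0
    comparisons = []
    for cond, sub in data.groupby("condition"):
        cell = sub.pivot_table(index="subject", columns="group", values="value", aggfunc="mean")
        groups = cell.columns.tolist()
        t, p = sstats.ttest_ind(cell[groups[0]].dropna(), cell[groups[1]].dropna())
        comparisons.append(
            {"comparison": f"{groups[0]} vs {groups[1]} @ {cond}", "t": float(t), "p_raw": float(p)}
        )
    for grp, sub in data.groupby("group"):
        cell = sub.pivot_table(index=["subject", "visit"], columns="condition", values="value")
        conds = cell.columns.tolist()
        t, p = sstats.ttest_rel(cell[conds[0]], cell[conds[1]])
        comparisons.append(
            {"comparison": f"{conds[0]} vs {conds[1]} @ {grp}", "t": float(t), "p_raw": float(p)}
        )
    out = pd.DataFrame(comparisons)
    reject, p_adj = bh_adjust(out["p_raw"].to_numpy(), alpha)
    out["p_bh"] = p_adj
    out["significant"] = reject
    out["visits_pooled"] = pool_visits
    return out


# ---------------------------------------------------------------------------
# reliability


def icc_band(icc: float) -> str:
    """Qualitative band: poor ≤ 0.40 < fair ≤ 0.60 < good ≤ 0.75 < excellent."""
    for upper, name in ICC_BANDS:
        if icc <= upper:
            return name
    return "excellent"


def icc_1_1(visit1: np.ndarray, visit2: np.ndarray) -> tuple[float, str]:
    """One-way random, single-measure intraclass correlation ICC(1,1).

    With k = 2 repeated measurements per subject:
    ICC = (MSB − MSW) / (MSB + MSW), from the one-way ANOVA mean squares
    between and within subjects.
    """
    v1 = np.asarray(visit1, dtype=float)
    v2 = np.asarray(visit2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise ValueError("visit vectors must be paired 1-D arrays of equal length")
    n = v1.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    data = np.column_stack([v1, v2])
    subj_means = data.mean(axis=1)
    grand = data.mean()
    msb = 2 * np.sum((subj_means - grand) ** 2) / (n - 1)
    msw = np.sum((data - subj_means[:, None]) ** 2) / n
    if msb + msw == 0:
        return 1.0, "excellent"
    icc = float((msb - msw) / (msb + msw))
    return icc, icc_band(icc)


def reliability_gate(icc_rows: pd.DataFrame, threshold: float = 0.40) -> list[tuple[str, str]]:
    """Measures excluded from inference: any group×condition cell ICC ≤ threshold."""
    required = {"measure", "axis", "group", "condition", "icc"}
    missing = required - set(icc_rows.columns)
    if missing:
        raise ValueError(f"ICC grid lacks columns {sorted(missing)}")
    excluded = []
    for (measure, axis), sub in icc_rows.groupby(["measure", "axis"]):
        if (sub["icc"] <= threshold).any():
            excluded.append((measure, axis))
            logger.info(
                "measure %s/%s excluded from inference (min ICC %.2f <= %.2f)",
                measure,
                axis,
                sub["icc"].min(),
                threshold,
            )
    return excluded


# ---------------------------------------------------------------------------
# bootstrap and classification


def bca_ci(
    sample1: np.ndarray,
    sample2: np.ndarray,
    B: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """BCa bootstrap CI for the mean difference of two independent samples.

    Bias correction comes from the fraction of bootstrap statistics below
    the observed difference, acceleration from jackknife skewness, both as
    implemented in scipy's BCa percentile correction.
    """
    s1 = np.asarray(sample1, dtype=float)
    s2 = np.asarray(sample2, dtype=float)
    if s1.size < 2 or s2.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    diff = float(s1.mean() - s2.mean())
    if np.ptp(s1) == 0 and np.ptp(s2) == 0:
        return diff, diff
    res = sstats.bootstrap(
        (s1, s2),
        lambda a, b, axis: np.mean(a, axis=axis) - np.mean(b, axis=axis),
        n_resamples=B,
        confidence_level=1 - alpha,
        method="BCa",
        rng=np.random.default_rng(seed),
    )
    return float(res.confidence_interval.low), float(res.confidence_interval.high)


def classify_weight(bmi_percentile: float) -> str:
    """CDC pediatric weight status from the age/sex-specific BMI percentile.

    underweight < 5th ≤ normal < 85th ≤ overweight < 95th ≤ obese.
    """
    p = float(bmi_percentile)
    if not (0 <= p <= 100):
        raise ValueError(f"BMI percentile must lie in [0, 100], got {p}")
    if p < 5:
        return "underweight"
    if p < 85:
        return "normal"
    if p < 95:
        return "overweight"
    return "obese"
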