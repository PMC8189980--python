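"""Statistical battery for preferential-looking eye-movement metrics.

Implements the analysis applied to the per-participant metrics table:

* group ANCOVA (metric ~ group + age + gender, no interactions) with
  Cohen's d and partial eta-squared for the group term,
* Wilcoxon signed-rank tests against the 50% chance level and paired
  signed-rank tests for first-fixation latencies,
* Spearman partial correlations (rank residualization) between metrics and
  symptom-subscale scores with age, gender and IQ as covariates,
* Benjamini-Hochberg adjustment over the five primary group tests,
* symptom-severity tertiles and IQ strata,
* ``run_full_battery`` assembling the complete structured report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SYMPTOM_SUBSCALES",
    "SUBSCALE_COLUMNS",
    "METRIC_COLUMNS",
    "StatsConfig",
    "StatResult",
    "DegenerateModelError",
    "ancova_group_effect",
    "wilcoxon_vs_chance",
    "wilcoxon_paired",
    "spearman_partial",
    "bh_adjust",
    "severity_tertiles",
    "iq_strata",
    "run_full_battery",
]

# The 29 symptom subscales: caregiver-reported behavior rating scales plus
# the diagnostic observation schedule.  Scores are treated as opaque numbers.
SYMPTOM_SUBSCALES: dict[str, tuple[str, ...]] = {
    "abi": (
        "core_asd_symptoms",
        "challenging_behavior",
        "mental_health",
        "restrictive_repetitive_behaviors",
        "self_regulation",
        "social_communication",
    ),
    "ados2": (
        "restricted_repetitive_behavior",
        "social_affect",
        "total",
    ),
    "abc": (
        "hyperactivity_noncompliance",
        "inappropriate_speech",
        "irritability",
        "lethargy_social_withdrawal",
        "stereotypic_behavior",
    ),
    "casi_anx": ("total",),
    "rbsr": (
        "compulsive_behavior",
        "ritualistic_behavior",
        "restricted_behavior",
        "sameness_behavior",
        "self_injurious_behavior",
        "stereotyped_behavior",
        "total",
    ),
    "srs2": (
        "social_awareness",
        "social_cognition",
        "social_communication",
        "social_motivation",
        "restricted_interests_repetitive_behavior",
        "social_communication_interaction",
        "total",
    ),
}

SUBSCALE_COLUMNS: tuple[str, ...] = tuple(
    f"{scale}_{sub}" for scale, subs in SYMPTOM_SUBSCALES.items() for sub in subs
)
assert len(SUBSCALE_COLUMNS) == 29

METRIC_COLUMNS: tuple[str, ...] = (
    "total_valid_pct",
    "preference_bio_pct",
    "first_fix_bio_pct",
    "latency_bio_ms",
    "latency_nonbio_ms",
)


class DegenerateModelError(ValueError):
    """The linear model cannot be fit (e.g. constant response)."""


@dataclass
class StatsConfig:
    covariates: tuple[str, ...] = ("age", "gender")
    fdr_level: float = 0.05
    n_primary_tests: int = 5
    chance_level_pct: float = 50.0
    iq_strata: dict = field(
        default_factory=lambda: {
            "low": (60.0, 84.0),
            "normal": (85.0, 115.0),
            "high": (116.0, 136.0),
        }
    )
    severity_levels: tuple[str, ...] = ("mild", "moderate", "severe")

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must lie in (0, 1)")
        bounds = [self.iq_strata[k] for k in ("low", "normal", "high")]
        for (lo1, hi1), (lo2, _) in zip(bounds, bounds[1:]):
            if not lo1 <= hi1 < lo2:
                raise ValueError("iq strata must be ordered and non-overlapping")


@dataclass
class StatResult:
    """One test's outcome: estimate, statistic, p-values and effect sizes."""

    test_name: str
    estimate: float | dict | None
    statistic: float | None
    p_raw: float | None
    n_used: int
    p_adjusted: float | None = None
    effect_cohens_d: float | None = None
    effect_partial_eta_sq: float | None = None
    note: str | None = None

    def to_dict(self) -> dict:
        out = {
            "test_name": self.test_name,
            "estimate": self.estimate,
            "statistic": self.statistic,
            "p_raw": self.p_raw,
            "n": self.n_used,
        }
        if self.p_adjusted is not None:
            out["p_adjusted"] = self.p_adjusted
        if self.effect_cohens_d is not None:
            out["cohens_d"] = self.effect_cohens_d
        if self.effect_partial_eta_sq is not None:
            out["partial_eta_sq"] = self.effect_partial_eta_sq
        if self.note is not None:
            out["note"] = self.note
        return out


# ---------------------------------------------------------------------------
# group comparison

def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference (b - a) with pooled SD."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if sp == 0:
        return 0.0
    return float((b.mean() - a.mean()) / sp)


def ancova_group_effect(
    metrics_table: pd.DataFrame, metric_name: str, config: StatsConfig | None = None
) -> StatResult:
    """ANCOVA of one metric on group with age and gender as covariates.

    Fits ``metric ~ C(group) + age + C(gender)`` by least squares (no
    interactions) and partitions sums of squares (type II) to obtain the
    group F test.  Partial eta-squared is SS_group / (SS_group + SS_resid);
    Cohen's d is computed from the raw group means with pooled SD.
    """
    config = config or StatsConfig()
    cols = ["group", "age", "gender", metric_name]
    df = metrics_table[cols].dropna()
    n_excluded = len(metrics_table) - len(df)
    groups = sorted(df["group"].unique())
    if len(groups) != 2 or df.groupby("group").size().min() < 2:
        raise DegenerateModelError("need two groups with at least 2 rows each")
    if df[metric_name].nunique() < 2:
        raise DegenerateModelError(f"{metric_name} is constant")

    df = df.rename(columns={metric_name: "_y"})
    # covariates that are constant in this subset carry no information and
    # would make the design singular
    terms = ["C(group)"]
    if df["age"].nunique() > 1:
        terms.append("age")
    if df["gender"].nunique() > 1:
        terms.append("C(gender)")
    fit = smf.ols("_y ~ " + " + ".join(terms), data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    ss_group = float(anova.loc["C(group)", "sum_sq"])
    ss_resid = float(anova.loc["Residual", "sum_sq"])
    f_stat = float(anova.loc["C(group)", "F"])
    p = float(anova.loc["C(group)", "PR(>F)"])

    a = df.loc[df["group"] == groups[0], "_y"].to_numpy()
    b = df.loc[df["group"] == groups[1], "_y"].to_numpy()
    means = {groups[0]: float(a.mean()), groups[1]: float(b.mean())}
    note = f"{n_excluded} rows excluded (missing values)" if n_excluded else None
    return StatResult(
        test_name=f"ancova_group:{metric_name}",
        estimate=means,
        statistic=f_stat,
        p_raw=p,
        n_used=len(df),
        effect_cohens_d=cohens_d(a, b),
        effect_partial_eta_sq=ss_group / (ss_group + ss_resid),
        note=note,
    )


# ---------------------------------------------------------------------------
# signed-rank tests

def _signed_rank(diffs: np.ndarray, test_name: str, n_total: int) -> StatResult:
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        return StatResult(test_name, 0.0, None, 1.0, n_total, note="degenerate: all values at chance")
    stat, p = sps.wilcoxon(
        nonzero,
        zero_method="wilcox",
        correction=True,
        alternative="two-sided",
        method="approx",
    )
    return StatResult(
        test_name,
        float(np.median(diffs)),
        float(stat),
        float(p),
        n_total,
    )


def wilcoxon_vs_chance(values: Sequence[float], chance_level_pct: float = 50.0) -> StatResult:
    """Two-sided signed-rank test of a percentage metric against chance.

    Zero differences are dropped; ties get mid-ranks; p comes from the
    normal approximation with continuity and tie corrections.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if len(v) < 6:
        raise ValueError("need at least 6 non-missing values")
    res = _signed_rank(v - chance_level_pct, "wilcoxon_vs_chance", len(v))
    res.estimate = float(np.mean(v))
    return res


def wilcoxon_paired(lat_bio: Sequence[float], lat_nonbio: Sequence[float]) -> StatResult:
    """Paired signed-rank test of within-participant latency differences."""
    a = np.asarray(lat_bio, float)
    b = np.asarray(lat_nonbio, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have the same length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 6:
        raise ValueError("need at least 6 complete pairs")
    res = _signed_rank(a[ok] - b[ok], "wilcoxon_paired", int(ok.sum()))
    res.estimate = float(np.mean(a[ok] - b[ok]))
    return res


# ---------------------------------------------------------------------------
# partial rank correlation

def spearman_partial(
    x: Sequence[float],
    y: Sequence[float],
    covariate_table: pd.DataFrame | None = None,
) -> StatResult:
    """Spearman partial correlation by rank residualization.

    Ranks x, y and each numeric covariate (mid-ranks on ties), residualizes
    the x and y ranks on the covariate ranks by least squares, and returns
    the Pearson correlation of the residuals with a t-based p on
    ``n - 2 - k`` degrees of freedom.  With no covariates this reduces to
    the ordinary Spearman correlation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if covariate_table is None or covariate_table.shape[1] == 0:
        cov = np.empty((len(x), 0))
    else:
        cov = np.asarray(covariate_table, float)
    ok = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(cov), axis=1)
    k = cov.shape[1]
    n = int(ok.sum())
    if n < k + 3:
        raise ValueError("not enough complete cases")
    x, y, cov = x[ok], y[ok], cov[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatResult("spearman_partial", None, None, None, n, note="constant input")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    design = np.column_stack([np.ones(n)] + [sps.rankdata(cov[:, j]) for j in range(k)])
    rx_res = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    ry_res = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    denom = np.sqrt(np.dot(rx_res, rx_res) * np.dot(ry_res, ry_res))
    if denom == 0:
        return StatResult("spearman_partial", None, None, None, n, note="degenerate ranks")
    r = float(np.dot(rx_res, ry_res) / denom)
    dof = n - 2 - k
    r_c = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_c * np.sqrt(dof / (1 - r_c**2))
    p = float(2 * sps.t.sf(abs(t), dof))
    return StatResult("spearman_partial", r, float(t), p, n)


# ---------------------------------------------------------------------------
# multiplicity, tertiles, strata

def bh_adjust(p_values: Sequence[float], fdr_level: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, alpha=fdr_level, method="fdr_bh")[1]


def severity_tertiles(scores: Sequence[float]) -> np.ndarray:
    """Split scores into mild / moderate / severe thirds by rank.

    Stable sort (ties broken by input order, i.e. participant order), split
    at ranks n/3 and 2n/3 with remainders allocated to the later groups:
    n = 121 yields sizes (40, 40, 41).
    """
    s = np.asarray(scores, float)
    n = len(s)
    if n < 3:
        raise ValueError("need at least 3 scores")
    if np.any(~np.isfinite(s)):
        raise ValueError("scores must be non-missing")
    order = np.argsort(s, kind="stable")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i >= 3 - rem else 0) for i in range(3)]
    labels = np.empty(n, dtype=object)
    start = 0
    for size, name in zip(sizes, ("mild", "moderate", "severe")):
        labels[order[start : start + size]] = name
        start += size
    return labels


def iq_strata(iq_values: Sequence[float], config: StatsConfig | None = None) -> np.ndarray:
    """Bin IQ composite scores into low / normal / high strata."""
    config = config or StatsConfig()
    iq = np.asarray(iq_values, float)
    lo_lo = config.iq_strata["low"][0]
    hi_hi = config.iq_strata["high"][1]
    if len(iq) and (np.any(iq < lo_lo) | np.any(iq > hi_hi)):
        raise ValueError(f"IQ values must lie within [{lo_lo}, {hi_hi}]")
    normal_lo = config.iq_strata["normal"][0]
    high_lo = config.iq_strata["high"][0]
    labels = np.where(iq < normal_lo, "low", np.where(iq < high_lo, "normal", "high"))
    return labels.astype(object)


# ---------------------------------------------------------------------------
# full battery

def _chance_section(df: pd.DataFrame, config: StatsConfig) -> dict:
    out = {}
    for group, sub in df.groupby("group"):
        out[group] = {}
        for metric in ("preference_bio_pct", "first_fix_bio_pct"):
            try:
                res = wilcoxon_vs_chance(sub[metric], config.chance_level_pct)
                out[group][metric] = res.to_dict()
            except ValueError as exc:
                out[group][metric] = {"note": str(exc)}
    return out


def run_full_battery(
    metrics_table: pd.DataFrame,
    participant_table: pd.DataFrame,
    config: StatsConfig | None = None,
) -> dict:
    """Run the complete statistical battery and return a structured report.

    Sections: ``group_effects`` (five ANCOVAs, BH-adjusted over the five
    primary tests), ``chance_tests``, ``paired_latency``, ``severity_grid``
    (29 symptoms x 3 tertiles of chance tests on preference),
    ``iq_strata`` (stratified group ANCOVAs), and ``correlation_grid``
    (5 metrics x 29 symptoms partial Spearman with age/gender/IQ covariates).
    """
    config = config or StatsConfig()
    missing = set(metrics_table["participant_id"]) ^ set(participant_table["participant_id"])
    df = metrics_table.merge(participant_table, on="participant_id", how="inner")
    report: dict = {
        "meta": {
            "n_joined": len(df),
            "n_unmatched": len(missing),
            "groups": {g: int(n) for g, n in df.groupby("group").size().items()},
        }
    }

    # --- five primary group ANCOVAs + BH over exactly those five
    group_effects = {}
    for metric in METRIC_COLUMNS:
        group_effects[metric] = ancova_group_effect(df, metric, config)
    p_raw = [group_effects[m].p_raw for m in METRIC_COLUMNS]
    p_adj = bh_adjust(p_raw, config.fdr_level)
    for metric, padj in zip(METRIC_COLUMNS, p_adj):
        group_effects[metric].p_adjusted = float(padj)
    report["group_effects"] = {m: r.to_dict() for m, r in group_effects.items()}

    # --- chance-level tests per group
    report["chance_tests"] = _chance_section(df, config)

    # --- paired latency tests per group
    paired = {}
    for group, sub in df.groupby("group"):
        try:
            paired[group] = wilcoxon_paired(sub["latency_bio_ms"], sub["latency_nonbio_ms"]).to_dict()
        except ValueError as exc:
            paired[group] = {"note": str(exc)}
    report["paired_latency"] = paired

    asd = df[df["group"] == "asd"].reset_index(drop=True)

    # --- severity grid: 29 symptoms x 3 tertiles, chance test on preference
    grid = {}
    for col in SUBSCALE_COLUMNS:
        if col not in asd.columns:
            continue
        sub = asd.dropna(subset=[col, "preference_bio_pct"]).reset_index(drop=True)
        if len(sub) < 3:
            continue
        labels = severity_tertiles(sub[col].to_numpy())
        grid[col] = {}
        for level in config.severity_levels:
            vals = sub.loc[labels == level, "preference_bio_pct"]
            cell = {"n": int(len(vals)), "mean": float(vals.mean()) if len(vals) else None}
            try:
                cell.update(
                    {
                        k: v
                        for k, v in wilcoxon_vs_chance(vals, config.chance_level_pct).to_dict().items()
                        if k in ("statistic", "p_raw")
                    }
                )
            except ValueError as exc:
                cell["note"] = str(exc)
            grid[col][level] = cell
    report["severity_grid"] = grid

    # --- IQ strata: stratified ASD-vs-TD ANCOVAs
    strata_section: dict = {}
    if asd["iq"].notna().any():
        iq_ok = asd.dropna(subset=["iq"]).reset_index(drop=True)
        labels = iq_strata(iq_ok["iq"].to_numpy(), config)
        strata_section["sizes"] = {
            level: int((labels == level).sum()) for level in ("low", "normal", "high")
        }
        td = df[df["group"] != "asd"]
        strata_section["group_effects"] = {}
        for level in ("low", "normal", "high"):
            subset = pd.concat([iq_ok[labels == level], td], ignore_index=True)
            strata_section["group_effects"][level] = {}
            for metric in METRIC_COLUMNS:
                try:
                    strata_section["group_effects"][level][metric] = ancova_group_effect(
                        subset, metric, config
                    ).to_dict()
                except DegenerateModelError as exc:
                    strata_section["group_effects"][level][metric] = {"note": str(exc)}
    report["iq_strata"] = strata_section

    # --- correlation grid: 5 metrics x 29 symptoms, partial Spearman
    cov_cols = ["age", "gender", "iq"]
    corr_grid = {}
    gender_num = (asd["gender"] == "male").astype(float) if len(asd) else None
    for metric in METRIC_COLUMNS:
        corr_grid[metric] = {}
        for col in SUBSCALE_COLUMNS:
            if col not in asd.columns:
                continue
            cov = pd.DataFrame(
                {"age": asd["age"], "gender": gender_num, "iq": asd["iq"]}
            )
            try:
                corr_grid[metric][col] = spearman_partial(
                    asd[metric], asd[col], cov
                ).to_dict()
            except ValueError as exc:
                corr_grid[metric][col] = {"note": str(exc)}
    report["correlation_grid"] = corr_grid
    return report
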