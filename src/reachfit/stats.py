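"""Study-level tables: per-trial metrics, cell means, correlations, ANOVA.

The per-trial metric record is the analysis surface of the package; the
aggregation, correlation and ANOVA layers reproduce the structure of a
group x condition kinematic study: cell means with standard errors,
within-group correlation matrices between reach/grasp and transport
metrics and between rotation and transport metrics, and two-way ANOVAs
with Scheffé-style follow-ups.  Significance conventions are configurable
and default to the strict levels customary for large correlation families
(individual tests at p < .005; post hoc at .01).
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass
class TrialMetrics:
    """Flat record of all per-trial kinematic parameters."""

    trial_id: str
    group: str
    condition: str
    hand: str
    latency_ms: float
    reach_duration_ms: float
    reach_wrist_mus: int
    reach_index_mus: int
    reach_wrist_peak_v: float
    reach_wrist_peak_time_ms: float
    reach_wrist_ppv_pct: float
    reach_wrist_decel_pct: float
    reach_wrist_avg_v: float
    reach_wrist_dist_mm: float
    reach_index_peak_v: float
    reach_index_peak_time_ms: float
    reach_index_avg_v: float
    reach_index_dist_mm: float
    peak_time_diff_ms: float
    grasp_duration_ms: float
    transport_duration_ms: float
    transport_wrist_mus: int
    transport_index_mus: int
    transport_peg_mus: int
    transport_wrist_avg_v: float
    transport_index_avg_v: float
    transport_wrist_dist_mm: float
    transport_index_dist_mm: float
    fitting_mu_fraction: float
    rota1_ms: float
    rota2_ms: float
    total_rotation_ms: float
    residual_angle_deg: float
    arrival_frame: int
    wrist_index_gap_mm: float
    flags: str = ""


METRIC_COLUMNS = [
    f.name for f in TrialMetrics.__dataclass_fields__.values()
    if f.name not in ("trial_id", "group", "condition", "hand", "flags",
                      "arrival_frame")
]


def metrics_table(metrics: list[TrialMetrics]) -> pd.DataFrame:
    """One row per analysed trial."""
    return pd.DataFrame([asdict(m) for m in metrics])


@dataclass
class SummaryTables:
    cells: pd.DataFrame        # group x condition mean/SE/n per metric
    group_means: pd.DataFrame  # marginal group mean/SE/n per metric


def aggregate(
    table: pd.DataFrame, metrics: list[str] | None = None
) -> SummaryTables:
    """Cell and marginal means with standard errors.

    Single-trial cells report the trial value with a missing (NaN) SE;
    empty cells are absent rather than zero-filled.
    """
    if metrics is None:
        metrics = [m for m in METRIC_COLUMNS if m in table.columns]
    if table.empty:
        raise ValueError("no trials to aggregate")
    agg = {m: ["mean", "sem", "count"] for m in metrics}
    cells = table.groupby(["group", "condition"], observed=True).agg(agg)
    groups = table.groupby("group", observed=True).agg(agg)
    return SummaryTables(cells=cells, group_means=groups)


def correlate(
    table: pd.DataFrame,
    row_vars: list[str],
    col_vars: list[str],
    partial_on: list[str] | None = None,
    alpha: float = 0.005,
    by: str | None = "group",
) -> pd.DataFrame:
    """Pearson (optionally partial) correlations per group.

    Returns a tidy frame with columns group, row_var, col_var, r, p, n and
    a significance flag at ``alpha`` (the Bonferroni-style per-test level).
    Zero-variance variables yield an undefined r, flagged in ``note``.
    """
    rows = []
    groups = [(g, d) for g, d in table.groupby(by, observed=True)] \
        if by else [("all", table)]
    for gname, gdf in groups:
        if len(gdf) < 4:
            raise ValueError(f"group {gname}: need at least 4 trials")
        for rv in row_vars:
            for cv in col_vars:
                sub = gdf[[rv, cv] + (partial_on or [])].dropna()
                note = ""
                if sub[rv].nunique() < 2 or sub[cv].nunique() < 2:
                    r, p = np.nan, np.nan
                    note = "zero variance"
                elif partial_on:
                    res = pg.partial_corr(sub, x=rv, y=cv, covar=partial_on)
                    r = float(res["r"].iloc[0])
                    p = float(res["p_val"].iloc[0])
                else:
                    r, p = sps.pearsonr(sub[rv], sub[cv])
                rows.append({
                    "group": gname, "row_var": rv, "col_var": cv,
                    "r": r, "p": p, "n": len(sub),
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                    "note": note,
                })
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    metric: str
    effects: pd.DataFrame      # effect, F, p, partial eta squared
    posthoc: pd.DataFrame      # Scheffé-style group pairs
    warnings: list[str] = field(default_factory=list)


def anova_summary(
    table: pd.DataFrame,
    metric: str,
    posthoc_alpha: float = 0.01,
) -> AnovaResult:
    """Two-way (group x condition) ANOVA with Scheffé follow-ups.

    F, p and partial eta squared for the group effect, the task-condition
    effect and their interaction; pairwise group contrasts use Scheffé's
    criterion, which is valid for any set of contrasts.
    """
    notes = []
    if table[metric].nunique() < 2:
        raise ValueError(f"{metric} is constant: degenerate model")
    counts = table.groupby(["group", "condition"], observed=True).size()
    if counts.min() * 3 < counts.max():
        notes.append("strongly unbalanced design")
        warnings.warn("unbalanced group x condition design", stacklevel=2)
    df = table.rename(columns={metric: "_y"})[["_y", "group", "condition"]]
    model = smf.ols("_y ~ C(group) * C(condition)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    ss_res = tab.loc["Residual", "sum_sq"]
    effects = []
    for key, name in [("C(group)", "group"), ("C(condition)", "task"),
                      ("C(group):C(condition)", "interaction")]:
        ss = tab.loc[key, "sum_sq"]
        effects.append({
            "effect": name,
            "F": tab.loc[key, "F"],
            "p": tab.loc[key, "PR(>F)"],
            "eta2_partial": ss / (ss + ss_res),
        })
    # Scheffé pairwise group contrasts
    k = df["group"].nunique()
    dfe = model.df_resid
    mse = ss_res / dfe
    means = df.groupby("group", observed=True)["_y"].agg(["mean", "count"])
    pairs = []
    names = list(means.index)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            diff = means.loc[a, "mean"] - means.loc[b, "mean"]
            se2 = mse * (1 / means.loc[a, "count"] + 1 / means.loc[b, "count"])
            f_s = diff**2 / se2 / (k - 1)
            p = sps.f.sf(f_s, k - 1, dfe)
            pairs.append({
                "group_a": a, "group_b": b, "diff": diff,
                "F_scheffe": f_s, "p": p,
                "significant": p < posthoc_alpha,
            })
    return AnovaResult(
        metric=metric,
        effects=pd.DataFrame(effects),
        posthoc=pd.DataFrame(pairs),
        warnings=notes,
    )


# correlation variable families used for the study-style tables
REACH_VARS = [
    "latency_ms", "reach_duration_ms", "reach_wrist_mus",
    "reach_wrist_peak_v", "reach_wrist_peak_time_ms",
    "reach_wrist_decel_pct", "reach_wrist_avg_v", "reach_wrist_dist_mm",
    "grasp_duration_ms",
]
TRANSPORT_VARS = [
    "transport_duration_ms", "transport_wrist_mus",
    "transport_wrist_avg_v", "transport_wrist_dist_mm",
]
ROTATION_VARS = ["rota1_ms", "rota2_ms"]
ROTATION_TRANSPORT_VARS = TRANSPORT_VARS + [
    "transport_peg_mus", "residual_angle_deg",
]
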