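"""Between-cluster comparisons and survival contrasts.

Continuous variables are compared pairwise with the Mann-Whitney U rank-sum
test (medians with IQR reported), binary variables with Fisher's exact 2x2
test.  Survival from the time of CMR to the composite outcome (death or
heart transplantation/listing) is contrasted with Kaplan-Meier product-limit
curves, pairwise log-rank tests, and multivariable Cox proportional-hazards
models (Efron tie handling, Wald confidence intervals) adjusting for
ventricular morphology or for indexed end-diastolic volume per 10 mL/m^2.
Controls are excluded from all survival analyses by the pipeline.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats

from .errors import CoxFitError, ZeroEventsError

DURATION_COL = "followup_y"
EVENT_COL = "event"


@dataclass
class GroupComparison:
    """One pairwise group contrast for one variable."""

    variable: str
    group_a: str
    group_b: str
    summary_a: str
    summary_b: str
    test: str
    p_value: float
    warning: str = ""


def _median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.3g} ({q1:.3g}, {q3:.3g})"


def _count_pct(x: np.ndarray) -> str:
    n = int(np.sum(x))
    return f"{n} ({100.0 * n / len(x):.0f}%)"


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> Tuple[float, str]:
    """Two-sided Mann-Whitney U p-value; all-tied data gives p=1 with a flag."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0, "all values tied"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.pvalue), ""


def exact_2x2_test(success_a: int, n_a: int, success_b: int, n_b: int) -> float:
    """Fisher's exact two-sided p for a 2x2 table of counts."""
    table = [[success_a, n_a - success_a], [success_b, n_b - success_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def compare_clusters(
    data: pd.DataFrame,
    group_col: str = "cluster",
    continuous: Sequence[str] = (),
    binary: Sequence[str] = (),
) -> List[GroupComparison]:
    """All pairwise cluster contrasts for the given variables.

    ``binary`` columns must be 0/1 (or boolean) encoded.  Rows with missing
    values for a variable are dropped for that variable only.
    """
    groups = sorted(data[group_col].dropna().unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 clusters to compare")
    for g in groups:
        if (data[group_col] == g).sum() == 0:
            raise ValueError(f"empty cluster {g}")
    out: List[GroupComparison] = []
    for var in continuous:
        for ga, gb in itertools.combinations(groups, 2):
            a = data.loc[data[group_col] == ga, var].dropna().to_numpy(dtype=float)
            b = data.loc[data[group_col] == gb, var].dropna().to_numpy(dtype=float)
            if len(a) == 0 or len(b) == 0:
                raise ValueError(f"empty cluster for variable {var!r}")
            p, warn = rank_sum_test(a, b)
            out.append(GroupComparison(var, str(ga), str(gb), _median_iqr(a),
                                       _median_iqr(b), "mann-whitney", p, warn))
    for var in binary:
        for ga, gb in itertools.combinations(groups, 2):
            a = data.loc[data[group_col] == ga, var].dropna().to_numpy(dtype=float)
            b = data.loc[data[group_col] == gb, var].dropna().to_numpy(dtype=float)
            p = exact_2x2_test(int(a.sum()), len(a), int(b.sum()), len(b))
            out.append(GroupComparison(var, str(ga), str(gb), _count_pct(a),
                                       _count_pct(b), "fisher-exact", p))
    return out


def comparisons_frame(comparisons: List[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])


@dataclass
class KMCurve:
    """Product-limit survival estimate for one cluster."""

    group: str
    times: np.ndarray
    survival: np.ndarray  # starts at 1, non-increasing
    at_risk: np.ndarray
    n: int
    n_events: int


@dataclass
class SurvivalContrast:
    """KM curves, pairwise log-rank results, and optional Cox tables."""

    km_curves: Dict[str, KMCurve]
    pairwise_logrank: pd.DataFrame
    cox_tables: Dict[str, pd.DataFrame] = field(default_factory=dict)


def km_logrank(
    data: pd.DataFrame,
    group_col: str = "cluster",
    duration_col: str = DURATION_COL,
    event_col: str = EVENT_COL,
    bonferroni: bool = False,
) -> SurvivalContrast:
    """Kaplan-Meier curves per cluster plus pairwise log-rank tests.

    Raises :class:`ZeroEventsError` when no events are observed at all.  With
    ``bonferroni=True`` the pairwise p-values are multiplied by the number of
    pairs (capped at 1).
    """
    if int(data[event_col].sum()) == 0:
        raise ZeroEventsError("no events observed; log-rank is undefined")
    groups = sorted(data[group_col].dropna().unique())
    curves: Dict[str, KMCurve] = {}
    for g in groups:
        sub = data[data[group_col] == g]
        if int(sub[event_col].sum()) == 0:
            warnings.warn(f"cluster {g} has zero events", stacklevel=2)
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], event_observed=sub[event_col])
        table = kmf.event_table
        curves[str(g)] = KMCurve(
            group=str(g),
            times=kmf.survival_function_.index.to_numpy(dtype=float),
            survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
            at_risk=table["at_risk"].to_numpy(dtype=float),
            n=len(sub),
            n_events=int(sub[event_col].sum()),
        )
    pairs = list(itertools.combinations(groups, 2))
    rows = []
    for ga, gb in pairs:
        a = data[data[group_col] == ga]
        b = data[data[group_col] == gb]
        res = logrank_test(a[duration_col], b[duration_col],
                           event_observed_A=a[event_col], event_observed_B=b[event_col])
        p = float(res.p_value)
        if bonferroni:
            p = min(1.0, p * len(pairs))
        rows.append({"group_a": str(ga), "group_b": str(gb),
                     "chi_sq": float(res.test_statistic), "p_value": p})
    return SurvivalContrast(km_curves=curves, pairwise_logrank=pd.DataFrame(rows))


def _cox_design(
    data: pd.DataFrame,
    adjustment: str,
    reference_cluster: int,
    group_col: str,
) -> Tuple[pd.DataFrame, List[str]]:
    clusters = sorted(data[group_col].unique())
    if reference_cluster not in clusters:
        raise ValueError(f"reference cluster {reference_cluster} not present")
    design = pd.DataFrame(index=data.index)
    cluster_cols = []
    for c in clusters:
        if c == reference_cluster:
            continue
        col = f"cluster_{c}"
        design[col] = (data[group_col] == c).astype(float)
        cluster_cols.append(col)
    if adjustment == "morphology":
        for m in ("RV", "mixed"):  # LV is the reference morphology
            design[f"morphology_{m}"] = (data["morphology"] == m).astype(float)
    elif adjustment == "edvi":
        design["edvi_per10"] = data["edvi_ml_m2"].astype(float) / 10.0
    elif adjustment not in (None, "none"):
        raise ValueError("adjustment must be 'morphology', 'edvi' or None")
    return design, cluster_cols


def cox_fit(
    data: pd.DataFrame,
    adjustment: str = "morphology",
    reference_cluster: int = 1,
    group_col: str = "cluster",
    duration_col: str = DURATION_COL,
    event_col: str = EVENT_COL,
) -> pd.DataFrame:
    """Multivariable Cox model of the composite outcome on cluster indicators.

    The reference cluster is absorbed; indexed EDV enters per 10 mL/m^2.
    Returns a table with one row per covariate: coef, hazard ratio, Wald 95%
    CI and p.  A warning is issued when events < 5 x covariates; exact
    collinearity raises :class:`CoxFitError`.
    """
    design, _ = _cox_design(data, adjustment, reference_cluster, group_col)
    n_events = int(data[event_col].sum())
    if n_events == 0:
        raise ZeroEventsError("no events observed; Cox model is undefined")
    if n_events < 5 * design.shape[1]:
        warnings.warn(
            f"only {n_events} events for {design.shape[1]} covariates "
            "(< 5 events per covariate)",
            stacklevel=2,
        )
    fit_df = design.copy()
    fit_df[duration_col] = data[duration_col].to_numpy(dtype=float)
    fit_df[event_col] = data[event_col].to_numpy(dtype=int)
    cph = CoxPHFitter()
    # the full Newton step can oscillate on heavy-tailed follow-up data;
    # retry with damped steps before giving up
    last_exc: Exception | None = None
    for step_size in (None, 0.5, 0.25):
        options = {} if step_size is None else {"fit_options": {"step_size": step_size}}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cph.fit(fit_df, duration_col=duration_col, event_col=event_col,
                        **options)
            last_exc = None
            break
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            last_exc = exc
    if last_exc is not None:
        raise CoxFitError(
            f"Cox fit failed (collinear design or separation): {last_exc}"
        ) from last_exc
    summary = cph.summary
    out = pd.DataFrame(
        {
            "covariate": summary.index,
            "coef": summary["coef"].to_numpy(),
            "hr": summary["exp(coef)"].to_numpy(),
            "hr_ci_lower": summary["exp(coef) lower 95%"].to_numpy(),
            "hr_ci_upper": summary["exp(coef) upper 95%"].to_numpy(),
            "p_value": summary["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def cluster_contrasts(
    data: pd.DataFrame,
    target_cluster: int,
    adjustment: str = "morphology",
    group_col: str = "cluster",
) -> pd.DataFrame:
    """HR of ``target_cluster`` vs each other cluster as reference in turn."""
    rows = []
    for ref in sorted(data[group_col].unique()):
        if ref == target_cluster:
            continue
        table = cox_fit(data, adjustment=adjustment, reference_cluster=ref,
                        group_col=group_col)
        row = table[table["covariate"] == f"cluster_{target_cluster}"].iloc[0]
        rows.append({"reference_cluster": ref, "target_cluster": target_cluster,
                     "adjustment": adjustment, "hr": row["hr"],
                     "hr_ci_lower": row["hr_ci_lower"],
                     "hr_ci_upper": row["hr_ci_upper"], "p_value": row["p_value"]})
    return pd.DataFrame(rows)
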