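"""Kaplan-Meier estimation and log-rank comparison for median-split groups.

Samples are dichotomized at the median of a covariate (gene expression or
CpG beta value) computed over the entire cohort, ties to the low group.
The two groups are compared with the standard two-group log-rank test
(1 df); the hazard ratio is reported in the log-rank O/E form
(O_high/E_high)/(O_low/E_low), optionally inverted when below 1 so the
adverse direction is highlighted, as Kaplan-Meier-plotter-style analyses
do. A per-feature scan applies the same split and test to every row of a
covariate matrix (e.g. a CpG beta-value matrix).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

logger = logging.getLogger(__name__)

GROUP_HIGH = "high"
GROUP_LOW = "low"

SCAN_COLUMNS = ["feature_id", "chi2", "p_value", "hr", "n_high", "n_low", "inverted"]


@dataclass
class KMCurve:
    """Product-limit survival curve evaluated at the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    p_value: float
    hr: float
    n_high: int
    n_low: int
    inverted: bool = False


def median_split(records: pd.DataFrame) -> pd.Series:
    """Label samples high/low at the whole-cohort covariate median.

    Values strictly above the median are 'high'; ties at the median go to
    'low'. All-identical covariates are a degenerate split and an error.
    """
    if len(records) < 4:
        raise ValueError("median_split needs at least 4 records")
    cov = records["covariate"].to_numpy(dtype=float)
    if np.all(cov == cov[0]):
        raise ValueError("degenerate split: all covariate values identical")
    med = float(np.median(cov))
    labels = np.where(cov > med, GROUP_HIGH, GROUP_LOW)
    return pd.Series(labels, index=records.index, name="group")


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit curve over the distinct event times.

    Samples censored exactly at an event time are counted at risk at that
    time (the standard convention). With zero events the curve is flat at
    1 and a warning is logged.
    """
    t = records["time"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=int)
    if not (t > 0).all():
        raise ValueError("times must be positive")
    if e.sum() == 0:
        logger.warning("km_estimate: no events; flat curve at 1")
        return KMCurve(np.array([]), np.array([]), np.array([]))
    kmf = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(t, e)
    event_times = np.sort(np.unique(t[e == 1]))
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    table = kmf.event_table
    at_risk = table.loc[event_times, "at_risk"].to_numpy(dtype=float)
    return KMCurve(event_times, surv, at_risk)


def _logrank_table(t, e, in_high):
    """O, E and hypergeometric variance over the distinct event times."""
    death_times = np.sort(np.unique(t[e == 1]))
    t_high = np.sort(t[in_high])
    t_all = np.sort(t)
    n_at = len(t_all) - np.searchsorted(t_all, death_times, side="left")
    n1_at = len(t_high) - np.searchsorted(t_high, death_times, side="left")
    d_at = np.array([int(((t == s) & (e == 1)).sum()) for s in death_times])
    d1_at = np.array([int(((t == s) & (e == 1) & in_high).sum()) for s in death_times])
    O1 = float(d1_at.sum())
    E1 = float((d_at * n1_at / n_at).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        v = d_at * (n1_at / n_at) * (1 - n1_at / n_at) * (n_at - d_at) / (n_at - 1)
    V = float(np.nansum(np.where(n_at > 1, v, 0.0)))
    D = float(d_at.sum())
    return O1, E1, V, D


def log_rank(
    records: pd.DataFrame, groups: pd.Series, invert_hr: bool = True
) -> LogRankResult:
    """Two-group log-rank chi-square (1 df) with O/E hazard ratio.

    hr = (O_high/E_high)/(O_low/E_low). With ``invert_hr`` the reciprocal
    is reported when hr < 1 and the result flagged ``inverted`` so the
    adverse association always reads as hr > 1.
    """
    groups = pd.Series(groups).reindex(records.index)
    in_high = (groups == GROUP_HIGH).to_numpy()
    in_low = (groups == GROUP_LOW).to_numpy()
    if not (in_high | in_low).all():
        raise ValueError("groups must label every record high or low")
    n_high, n_low = int(in_high.sum()), int(in_low.sum())
    if n_high == 0 or n_low == 0:
        raise ValueError("both groups must contain at least one subject")
    t = records["time"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=int)
    O1, E1, V, D = _logrank_table(t, e, in_high)
    O2, E2 = D - O1, D - E1
    chi2 = (O1 - E1) ** 2 / V if V > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1)) if V > 0 else 1.0
    if E1 > 0 and E2 > 0 and O2 > 0:
        hr = (O1 / E1) / (O2 / E2)
    elif O1 == 0 and O2 == 0:
        hr = 1.0
    else:
        hr = np.inf if O2 == 0 or E2 == 0 else 0.0
    inverted = False
    if invert_hr and hr < 1:
        hr = 1.0 / hr if hr > 0 else np.inf
        inverted = True
    return LogRankResult(
        chi2=float(chi2), p_value=p, hr=float(hr),
        n_high=n_high, n_low=n_low, inverted=inverted,
    )


def covariate_scan(
    matrix: pd.DataFrame, survival: pd.DataFrame, invert_hr: bool = True
) -> pd.DataFrame:
    """Median-split + log-rank for every row of a covariate matrix.

    ``matrix`` is features x samples with columns matching the survival
    table's sample ids; degenerate (constant) features are skipped with a
    log entry. Rows are sorted by ascending p-value.
    """
    missing = [s for s in survival["sample"] if s not in matrix.columns]
    if missing:
        raise ValueError(f"survival samples missing from the matrix: {missing[:10]}")
    aligned = matrix[list(survival["sample"])]
    rows = []
    for feature_id, cov in aligned.iterrows():
        rec = survival.copy()
        rec["covariate"] = cov.to_numpy(dtype=float)
        try:
            groups = median_split(rec)
        except ValueError:
            logger.info("covariate_scan: skipping degenerate feature %s", feature_id)
            continue
        res = log_rank(rec, groups, invert_hr=invert_hr)
        rows.append(
            {
                "feature_id": feature_id,
                "chi2": res.chi2,
                "p_value": res.p_value,
                "hr": res.hr,
                "n_high": res.n_high,
                "n_low": res.n_low,
                "inverted": res.inverted,
            }
        )
    out = pd.DataFrame(rows, columns=SCAN_COLUMNS)
    return out.sort_values(["p_value", "feature_id"], ignore_index=True)


def methylation_heatmap_table(
    matrix: pd.DataFrame, order: str = "by_mean", survival: pd.DataFrame | None = None
):
    """Reorder methylation rows for heat-map display.

    ``by_mean`` sorts by row mean descending; ``by_p`` by the covariate
    scan's p-value ascending (skipped features last). Values are untouched.
    Returns the reordered matrix and per-row annotations.
    """
    if order == "by_mean":
        means = matrix.mean(axis=1)
        idx = means.sort_values(ascending=False, kind="stable").index
        annotations = pd.DataFrame({"mean_beta": means.loc[idx]})
    elif order == "by_p":
        if survival is None:
            raise ValueError("by_p ordering requires a survival table")
        scan = covariate_scan(matrix, survival).set_index("feature_id")
        ordered = [f for f in scan.index if f in matrix.index]
        ordered += [f for f in matrix.index if f not in scan.index]
        idx = pd.Index(ordered)
        annotations = pd.DataFrame(
            {"p_value": scan["p_value"].reindex(idx), "mean_beta": matrix.mean(axis=1).loc[idx]}
        )
    else:
        raise ValueError(f"unknown order key {order!r}")
    return matrix.loc[idx], annotations
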