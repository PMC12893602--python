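"""Two-group differential-expression screening on log2 expression matrices.

Identifies differentially expressed genes (DEGs) and miRNAs (DEMs) from a
case/control log2 expression matrix with a per-feature t-test and a
fold-change rule, and produces volcano- and top-k-table outputs.

The default fold-change rule is a *band*: a feature is called DE only when
0.5 <= |log2 fold change| <= 1.0 (together with p < 0.05). A conventional
one-sided ``min`` rule (|log2FC| >= lo) is available as an alternative.
Fold change is always oriented case minus control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GROUP_CASE = "case"
GROUP_CONTROL = "control"

DE_COLUMNS = ["feature_id", "log2_fc", "t_stat", "p_value", "adj_p", "is_de", "direction"]


@dataclass
class ExpressionMatrix:
    """A features x samples matrix of log2 expression with group labels.

    ``values`` is indexed by feature id (duplicates allowed until
    :func:`collapse_duplicates`) with sample ids as columns; ``groups`` maps
    each sample id to ``"case"`` or ``"control"``.
    """

    values: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.values.columns[self.groups.isna()])
            raise ValueError(f"samples without a group label: {missing}")
        bad = set(self.groups.unique()) - {GROUP_CASE, GROUP_CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must all be finite")
        for g in (GROUP_CASE, GROUP_CONTROL):
            if (self.groups == g).sum() == 0:
                raise ValueError(f"group {g!r} has no samples")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def case_samples(self) -> pd.Index:
        return self.values.columns[self.groups.to_numpy() == GROUP_CASE]

    @property
    def control_samples(self) -> pd.Index:
        return self.values.columns[self.groups.to_numpy() == GROUP_CONTROL]


@dataclass(frozen=True)
class FoldChangeRule:
    """DE fold-change rule on |log2FC|: band(lo, hi) or min(lo)."""

    kind: str = "band"
    lo: float = 0.5
    hi: float | None = 1.0

    def __post_init__(self) -> None:
        if self.kind not in {"band", "min"}:
            raise ValueError(f"unknown fold-change rule kind {self.kind!r}")
        if self.kind == "band":
            if self.hi is None or self.lo > self.hi:
                raise ValueError("band rule requires lo <= hi")
        if self.lo < 0:
            raise ValueError("fold-change threshold must be nonnegative")

    @classmethod
    def parse(cls, text: str) -> "FoldChangeRule":
        """Parse ``"band:0.5,1.0"`` or ``"min:0.5"``."""
        kind, _, rest = text.partition(":")
        kind = kind.strip()
        parts = [float(x) for x in rest.split(",") if x.strip()]
        if kind == "band":
            if len(parts) != 2:
                raise ValueError(f"band rule needs two thresholds, got {text!r}")
            return cls("band", parts[0], parts[1])
        if kind == "min":
            if len(parts) != 1:
                raise ValueError(f"min rule needs one threshold, got {text!r}")
            return cls("min", parts[0], None)
        raise ValueError(f"unknown fold-change rule {text!r}")

    def passes(self, abs_log2_fc: np.ndarray) -> np.ndarray:
        abs_log2_fc = np.asarray(abs_log2_fc, dtype=float)
        if self.kind == "band":
            return (abs_log2_fc >= self.lo) & (abs_log2_fc <= self.hi)
        return abs_log2_fc >= self.lo


def collapse_duplicates(matrix: ExpressionMatrix, policy: str = "max_mean") -> ExpressionMatrix:
    """Collapse rows sharing a feature id.

    ``max_mean`` keeps, per id, the row with the highest mean expression
    (the usual probe-to-feature collapse); ``mean`` averages rows per id.
    """
    if policy not in {"max_mean", "mean"}:
        raise ValueError(f"unknown collapse policy {policy!r}")
    values = matrix.values
    if not values.index.has_duplicates:
        return ExpressionMatrix(values.copy(), matrix.groups.copy())
    if policy == "mean":
        collapsed = values.groupby(level=0, sort=False).mean()
    else:
        # among ties keep the first occurrence (idxmax on positional index)
        ranking = pd.DataFrame(
            {"id": values.index, "mean": values.mean(axis=1).to_numpy()}
        ).reset_index(drop=True)
        keep = ranking.groupby("id", sort=False)["mean"].idxmax().to_numpy()
        collapsed = values.iloc[np.sort(keep)]
    logger.info("collapse_duplicates(%s): %d -> %d rows", policy, len(values), len(collapsed))
    return ExpressionMatrix(collapsed, matrix.groups.copy())


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common (mean) quantile distribution.

    Ties within a column receive the mean of the reference values at the
    positions they span (average-rank interpolation).
    """
    x = matrix.values.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("quantile_normalize requires a complete matrix")
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    positions = np.arange(n, dtype=float)
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, positions, reference)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.groups.copy())


def _welch_pooled_t(case: np.ndarray, control: np.ndarray, variant: str):
    """Row-wise two-sample t on 2-D arrays (features x samples)."""
    if variant not in {"welch", "pooled"}:
        raise ValueError(f"unknown t-test variant {variant!r}")
    n1, n2 = case.shape[1], control.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    m1, m2 = case.mean(axis=1), control.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = control.var(axis=1, ddof=1)
    fc = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        if variant == "welch":
            se2 = v1 / n1 + v2 / n2
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        else:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se2 = sp2 * (1 / n1 + 1 / n2)
            df = np.full_like(se2, float(n1 + n2 - 2))
        t = fc / np.sqrt(se2)
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), np.where(np.isfinite(df), df, 1.0)), np.nan)
    # zero-variance rows: equal means -> (t=0, p=1); unequal -> infinite t, p=0
    degenerate = se2 == 0
    equal = degenerate & (fc == 0)
    unequal = degenerate & (fc != 0)
    t = np.where(equal, 0.0, t)
    p = np.where(equal, 1.0, p)
    t = np.where(unequal, np.sign(fc) * np.inf, t)
    p = np.where(unequal, 0.0, p)
    return fc, t, p


def test_feature(case_values, control_values, variant: str = "welch"):
    """Two-sided t-test for a single feature.

    Returns ``(log2_fc, t_stat, p_value)`` with log2_fc = mean(case) -
    mean(control). When both groups are constant and equal the convention
    is t = 0, p = 1.
    """
    case = np.asarray(case_values, dtype=float).reshape(1, -1)
    control = np.asarray(control_values, dtype=float).reshape(1, -1)
    fc, t, p = _welch_pooled_t(case, control, variant)
    return float(fc[0]), float(t[0]), float(p[0])


def run_de(
    matrix: ExpressionMatrix,
    p_thresh: float = 0.05,
    fc_rule: FoldChangeRule | str = FoldChangeRule(),
    adjust: str = "none",
    variant: str = "welch",
) -> pd.DataFrame:
    """Screen every feature for differential expression.

    A feature is DE when its (raw or BH-adjusted, per ``adjust``) p-value is
    below ``p_thresh`` and |log2FC| satisfies ``fc_rule``. Returns one row
    per input feature with columns ``feature_id, log2_fc, t_stat, p_value,
    adj_p, is_de, direction``.
    """
    if isinstance(fc_rule, str):
        fc_rule = FoldChangeRule.parse(fc_rule)
    if adjust not in {"none", "bh"}:
        raise ValueError(f"unknown adjustment {adjust!r}")
    if not 0 < p_thresh <= 1:
        raise ValueError("p_thresh must be in (0, 1]")
    case = matrix.values[matrix.case_samples].to_numpy(dtype=float)
    control = matrix.values[matrix.control_samples].to_numpy(dtype=float)
    fc, t, p = _welch_pooled_t(case, control, variant)
    if adjust == "bh":
        adj_p = multipletests(p, method="fdr_bh")[1]
        p_for_call = adj_p
    else:
        adj_p = p.copy()
        p_for_call = p
    is_de = (p_for_call < p_thresh) & fc_rule.passes(np.abs(fc))
    direction = np.where(~is_de, "none", np.where(fc > 0, "up", "down"))
    out = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids.to_numpy(),
            "log2_fc": fc,
            "t_stat": t,
            "p_value": p,
            "adj_p": adj_p,
            "is_de": is_de,
            "direction": direction,
        }
    )
    logger.info(
        "run_de: %d features, %d up, %d down (p<%g, fc=%s, adjust=%s)",
        len(out), int((direction == "up").sum()), int((direction == "down").sum()),
        p_thresh, fc_rule, adjust,
    )
    return out


def de_summary(results: pd.DataFrame) -> dict:
    """Up/down/total bookkeeping for a DE result table."""
    up = int((results["direction"] == "up").sum())
    down = int((results["direction"] == "down").sum())
    return {"n_features": int(len(results)), "up": up, "down": down, "de_total": up + down}


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot table: log2FC vs -log10 p, with the DE flag."""
    if results.empty:
        raise ValueError("volcano_table needs a non-empty result table")
    p = results["p_value"].to_numpy(dtype=float).copy()
    zero = p <= 0
    if zero.any():
        tiny = np.finfo(float).tiny
        logger.warning("volcano_table: %d zero p-values clamped to %g", int(zero.sum()), tiny)
        p[zero] = tiny
    return pd.DataFrame(
        {
            "feature_id": results["feature_id"].to_numpy(),
            "log2_fc": results["log2_fc"].to_numpy(),
            "neg_log10_p": -np.log10(p),
            "significant": results["is_de"].to_numpy(),
        }
    )


def top_k_table(results: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """The k most up- and k most down-regulated DE features.

    Ordered by |log2FC| descending within each direction; ties broken by
    smaller p-value then feature id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    de = results[results["is_de"]]
    up = de[de["direction"] == "up"].sort_values(
        ["log2_fc", "p_value", "feature_id"], ascending=[False, True, True]
    )
    down = de[de["direction"] == "down"].sort_values(
        ["log2_fc", "p_value", "feature_id"], ascending=[True, True, True]
    )
    for name, frame in (("up", up), ("down", down)):
        if len(frame) < k:
            logger.warning("top_k_table: only %d %s-regulated DE features (k=%d)", len(frame), name, k)
    return pd.concat([up.head(k), down.head(k)], ignore_index=True)
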