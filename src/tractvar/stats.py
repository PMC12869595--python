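"""Three-sources-of-variability statistics with FDR control.

Primitive tests
---------------
* :func:`wilcoxon_signed_rank` -- paired left/right asymmetry test. Zero
  differences are dropped; the two-sided p-value is exact (dynamic
  programming over all sign assignments of the ranks) when at most 25
  non-zero pairs remain, and a normal approximation with continuity and
  tie corrections otherwise.
* :func:`two_sample_t` -- pooled-variance Student t (Welch by flag) for
  equality of means between two lifespan epochs.
* :func:`two_sample_f` -- variance-ratio F test, two-sided.
* :func:`bh_fdr` -- Benjamini-Hochberg step-up adjusted p-values.

Summaries: :func:`percent_change` of the epoch means and the natural-log
variance ratio (:func:`log_variance_ratio`; a halving of variance maps to
-0.69, a doubling to +0.69).

Scans
-----
Scan estimators run one primitive test per pathway (or per epoch pair)
over a long feature table and control the false discovery rate at q
within each (feature, analysis, epoch-pair) family. They follow the
sklearn estimator protocol: configure in ``__init__``, ``fit`` a table,
read ``results_``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

try:  # sklearn is optional at runtime; the scans only need get/set_params
    from sklearn.base import BaseEstimator
except Exception:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass

from .registry import (
    CATEGORIES,
    DEFAULT_EPOCHS,
    PathwayRecord,
    bilateral_pairs,
    load_pathway_registry,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "ComparisonSchedule",
    "DEFAULT_SCHEDULE",
    "wilcoxon_signed_rank",
    "two_sample_t",
    "two_sample_f",
    "bh_fdr",
    "percent_change",
    "log_variance_ratio",
    "AsymmetryScan",
    "LifespanScan",
    "VarianceAsymmetryScan",
    "asymmetry_scan",
    "lifespan_scan",
    "variance_asymmetry_scan",
    "population_sd_profile",
]

_EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    significant: bool | None = None
    n: tuple[int, ...] = ()
    degenerate: bool = False


@dataclass(frozen=True)
class ComparisonSchedule:
    """Ordered (earlier epoch, later epoch) pairs within one protocol."""

    pairs: tuple[tuple[str, str], ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        cohort_of = {e.name: e.cohort for e in DEFAULT_EPOCHS}
        for early, late in self.pairs:
            if cohort_of.get(early) != cohort_of.get(late):
                raise ValueError(
                    f"schedule pair ({early}, {late}) crosses acquisition protocols"
                )


# Comparisons are restricted to same-protocol cohorts: infancy and late
# adulthood pairs within one dataset each, development within another.
DEFAULT_SCHEDULE = ComparisonSchedule(
    pairs=(
        ("early_infancy", "late_infancy"),
        ("childhood", "adolescence"),
        ("middle_adulthood", "older_adulthood"),
        ("older_adulthood", "late_life"),
    ),
    labels=("infancy", "development", "middle_adulthood", "late_adulthood"),
)


def _signed_rank_statistic(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = sps.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    return w_plus, ranks


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p by DP over the 2^n equally likely sign patterns.

    Ranks are doubled so tied (half-integer) average ranks become integers;
    the DP array counts sign patterns reaching each possible doubled
    positive-rank sum.
    """
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w_plus * 2))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _approx_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    n = len(ranks)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    # continuity correction toward the mean
    delta = abs(w_plus - mean) - 0.5
    z = max(delta, 0.0) / math.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def wilcoxon_signed_rank(left: Sequence[float], right: Sequence[float]) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test of left vs right.

    Pairs with zero difference are dropped before ranking. If every pair
    is tied the result is statistic 0, p = 1 (no evidence of asymmetry).
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape or left.ndim != 1 or len(left) < 1:
        raise ValueError("wilcoxon_signed_rank needs two equal-length 1D samples")
    diffs = left - right
    diffs = diffs[diffs != 0]
    n_pairs = len(left)
    if len(diffs) == 0:
        return TestResult(0.0, 1.0, n=(n_pairs,), degenerate=True)
    w_plus, ranks = _signed_rank_statistic(diffs)
    if len(diffs) <= _EXACT_WILCOXON_MAX_N:
        p = _exact_signed_rank_p(w_plus, ranks)
    else:
        p = _approx_signed_rank_p(w_plus, ranks)
    return TestResult(w_plus, p, n=(n_pairs,))


def two_sample_t(
    a: Sequence[float], b: Sequence[float], *, welch: bool = False
) -> TestResult:
    """Two-sided two-sample t-test for equal means (pooled by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("two_sample_t needs at least two observations per sample")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, n=(len(a), len(b)), degenerate=True)
        return TestResult(math.inf, 0.0, n=(len(a), len(b)), degenerate=True)
    stat, p = sps.ttest_ind(a, b, equal_var=not welch)
    return TestResult(float(stat), float(p), n=(len(a), len(b)))


def two_sample_f(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided variance-ratio F test: F = var(a)/var(b), df (na-1, nb-1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("two_sample_f needs at least two observations per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        p = 1.0 if va == vb else 0.0
        return TestResult(math.inf if vb == 0 and va > 0 else 0.0, p,
                          n=(len(a), len(b)), degenerate=True)
    f = va / vb
    dist = sps.f(len(a) - 1, len(b) - 1)
    p = min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f)))
    return TestResult(float(f), float(p), n=(len(a), len(b)))


def bh_fdr(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and rejection flags.

    adjusted p_(i) = min over j >= i of m * p_(j) / j, clipped at 1;
    rejections are adjusted p <= q (equivalent to the classic step-up rule
    p_(i) <= i q / m).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj, adj <= q


def percent_change(mean_early: float, mean_late: float) -> float:
    """100 * (late - early) / early; the lifespan mean-change summary."""
    if mean_early == 0:
        raise ValueError("percent change undefined for a zero early mean")
    return 100.0 * (mean_late - mean_early) / mean_early


def log_variance_ratio(var_early: float, var_late: float) -> float:
    """ln(var_late / var_early): -0.69 for a halving, +0.69 for a doubling."""
    if var_early <= 0 or var_late <= 0:
        raise ValueError("variances must be positive")
    return float(np.log(var_late / var_early))


def _check_feature(table: pd.DataFrame, feature: str) -> pd.DataFrame:
    sub = table[table["feature"] == feature]
    if sub.empty:
        raise ValueError(f"feature {feature!r} absent from table")
    return sub


def _paired_lr(
    sub: pd.DataFrame, pairs: Sequence[tuple[PathwayRecord, PathwayRecord]]
) -> dict[str, tuple[np.ndarray, np.ndarray, int]]:
    """Subject-matched (left, right) value arrays per bilateral bundle."""
    wide = sub.pivot_table(index="subject_id", columns="pathway", values="value")
    out = {}
    for lrec, rrec in pairs:
        if lrec.name not in wide.columns or rrec.name not in wide.columns:
            continue
        both = wide[[lrec.name, rrec.name]].dropna()
        dropped = len(wide) - len(both)
        if dropped:
            logger.info(
                "asymmetry: dropped %d subject(s) with missing %s data",
                dropped, lrec.name,
            )
        out[lrec.name] = (
            both[lrec.name].to_numpy(),
            both[rrec.name].to_numpy(),
            dropped,
        )
    return out


class AsymmetryScan(BaseEstimator):
    """Paired Wilcoxon left-vs-right tests for one feature, BH-FDR across pathways.

    Parameters
    ----------
    feature : which structural feature to test.
    q : FDR level across the bilateral-pathway family (default 0.05).
    registry : pathway records; the default 64-bundle registry if None.

    After ``fit``, ``results_`` holds one row per bilateral bundle with the
    signed-rank statistic, raw and adjusted p, and the rejection flag.
    Midline bundles are skipped.
    """

    def __init__(self, feature: str = "FA", q: float = 0.05, registry=None):
        self.feature = feature
        self.q = q
        self.registry = registry

    def fit(self, table: pd.DataFrame, y=None):
        registry = self.registry if self.registry is not None else load_pathway_registry()
        sub = _check_feature(table, self.feature)
        paired = _paired_lr(sub, bilateral_pairs(registry))
        rows = []
        for left_name, (lv, rv, dropped) in paired.items():
            res = wilcoxon_signed_rank(lv, rv)
            rows.append(
                {
                    "pathway": left_name.removesuffix("_left"),
                    "feature": self.feature,
                    "statistic": res.statistic,
                    "p_raw": res.p_raw,
                    "n_pairs": len(lv),
                    "n_dropped": dropped,
                    "mean_diff": float((lv - rv).mean()),
                }
            )
        df = pd.DataFrame(rows)
        if not df.empty:
            adj, rej = bh_fdr(df["p_raw"].to_numpy(), self.q)
            df["p_adjusted"] = adj
            df["significant"] = rej
        self.results_ = df
        return self


class LifespanScan(BaseEstimator):
    """Epoch-pair mean and variance change for one feature, per pathway.

    For every (pathway, schedule pair): a two-sample t-test on the means, a
    two-sample F-test on the variances, the percent change of the mean and
    the log variance ratio. BH-FDR is applied across pathways within each
    (pair, test-type) family; non-significant cells carry
    ``significant_* = False`` (the figure-style backslash).
    """

    def __init__(
        self,
        feature: str = "FA",
        schedule: ComparisonSchedule = DEFAULT_SCHEDULE,
        q: float = 0.05,
        welch: bool = False,
    ):
        self.feature = feature
        self.schedule = schedule
        self.q = q
        self.welch = welch

    def fit(self, table: pd.DataFrame, y=None):
        sub = _check_feature(table, self.feature)
        rows = []
        for label, (early, late) in zip(self.schedule.labels, self.schedule.pairs):
            for pathway, grp in sub.groupby("pathway", sort=True):
                a = grp.loc[grp["epoch"] == early, "value"].to_numpy()
                b = grp.loc[grp["epoch"] == late, "value"].to_numpy()
                if len(a) < 2 or len(b) < 2:
                    logger.warning(
                        "lifespan: pair %s skipped for %s (unpopulated epoch)",
                        label, pathway,
                    )
                    continue
                t_res = two_sample_t(a, b, welch=self.welch)
                f_res = two_sample_f(a, b)
                rows.append(
                    {
                        "pathway": pathway,
                        "feature": self.feature,
                        "pair": label,
                        "epoch_early": early,
                        "epoch_late": late,
                        "n_early": len(a),
                        "n_late": len(b),
                        "t_statistic": t_res.statistic,
                        "p_mean_raw": t_res.p_raw,
                        "f_statistic": (
                            f_res.statistic if not np.isinf(f_res.statistic) else np.nan
                        ),
                        "p_var_raw": f_res.p_raw,
                        "percent_change": (
                            percent_change(a.mean(), b.mean()) if a.mean() != 0 else np.nan
                        ),
                        "log_variance_ratio": (
                            log_variance_ratio(a.var(ddof=1), b.var(ddof=1))
                            if a.var(ddof=1) > 0 and b.var(ddof=1) > 0
                            else np.nan
                        ),
                    }
                )
        df = pd.DataFrame(rows)
        if not df.empty:
            for col, adj_col, sig_col in (
                ("p_mean_raw", "p_mean_adjusted", "significant_mean"),
                ("p_var_raw", "p_var_adjusted", "significant_var"),
            ):
                df[adj_col] = np.nan
                df[sig_col] = False
                for _, idx in df.groupby("pair").groups.items():
                    adj, rej = bh_fdr(df.loc[idx, col].to_numpy(), self.q)
                    df.loc[idx, adj_col] = adj
                    df.loc[idx, sig_col] = rej
        self.results_ = df
        return self


class VarianceAsymmetryScan(BaseEstimator):
    """Left-vs-right variance F tests for one feature within one epoch."""

    def __init__(self, feature: str = "volume", epoch: str = "young_adulthood",
                 q: float = 0.05, registry=None):
        self.feature = feature
        self.epoch = epoch
        self.q = q
        self.registry = registry

    def fit(self, table: pd.DataFrame, y=None):
        registry = self.registry if self.registry is not None else load_pathway_registry()
        sub = _check_feature(table, self.feature)
        sub = sub[sub["epoch"] == self.epoch]
        if sub.empty:
            raise ValueError(f"epoch {self.epoch!r} absent from table")
        rows = []
        for lrec, rrec in bilateral_pairs(registry):
            lv = sub.loc[sub["pathway"] == lrec.name, "value"].to_numpy()
            rv = sub.loc[sub["pathway"] == rrec.name, "value"].to_numpy()
            if len(lv) < 2 or len(rv) < 2:
                continue
            res = two_sample_f(lv, rv)
            rows.append(
                {
                    "pathway": lrec.name.removesuffix("_left"),
                    "feature": self.feature,
                    "epoch": self.epoch,
                    "statistic": res.statistic,
                    "p_raw": res.p_raw,
                    "n_left": len(lv),
                    "n_right": len(rv),
                    "var_ratio_lr": (
                        lv.var(ddof=1) / rv.var(ddof=1) if rv.var(ddof=1) > 0 else np.nan
                    ),
                }
            )
        df = pd.DataFrame(rows)
        if not df.empty:
            adj, rej = bh_fdr(df["p_raw"].to_numpy(), self.q)
            df["p_adjusted"] = adj
            df["significant"] = rej
        self.results_ = df
        return self


def population_sd_profile(
    table: pd.DataFrame,
    feature: str,
    epoch: str,
    registry: Sequence[PathwayRecord] | None = None,
) -> pd.DataFrame:
    """Across-population SD (n-1) per pathway, ordered category then ap_rank."""
    registry = registry if registry is not None else load_pathway_registry()
    sub = _check_feature(table, feature)
    sub = sub[sub["epoch"] == epoch]
    cat_order = {c: i for i, c in enumerate(CATEGORIES)}
    recs = sorted(registry, key=lambda r: (cat_order.get(r.category, 99), r.ap_rank, r.name))
    rows = []
    for r in recs:
        vals = sub.loc[sub["pathway"] == r.name, "value"].to_numpy()
        if len(vals) < 2:
            raise ValueError(
                f"fewer than 2 subjects for {r.name} in epoch {epoch!r}; SD undefined"
            )
        rows.append(
            {
                "pathway": r.name,
                "category": r.category,
                "ap_rank": r.ap_rank,
                "feature": feature,
                "epoch": epoch,
                "sd": float(vals.std(ddof=1)),
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows)


def asymmetry_scan(table, feature, registry=None, q=0.05) -> pd.DataFrame:
    return AsymmetryScan(feature=feature, q=q, registry=registry).fit(table).results_


def lifespan_scan(table, feature, schedule=DEFAULT_SCHEDULE, q=0.05) -> pd.DataFrame:
    return LifespanScan(feature=feature, schedule=schedule, q=q).fit(table).results_


def variance_asymmetry_scan(table, feature, epoch, registry=None, q=0.05) -> pd.DataFrame:
    return (
        VarianceAsymmetryScan(feature=feature, epoch=epoch, q=q, registry=registry)
        .fit(table)
        .results_
    )
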