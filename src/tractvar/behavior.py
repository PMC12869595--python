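"""Structure-function analysis: normalisation, outlier trimming, and the
per-(pathway, feature, behaviour) interaction regression.

The model for one cell of the grid is ordinary least squares on

    behaviour ~ b0 + b1 * feature + b2 * dataset + b3 * feature x dataset
                + b4 * age + b5 * sex + error

with the dataset (acquisition cohort, a proxy for lifespan stage) coded
as treatment dummies against the Development reference, age centred
within dataset in raw years, and sex as a 0/1 indicator. b1 is the
feature slope in the reference dataset; the joint partial F-test on the
feature x dataset dummies asks whether the structure-function slope
differs across datasets. With 64 pathways and 9 features the scan fits
576 models per behavioural measure and calls significance at the
Bonferroni threshold alpha / 576.

Features and behaviour scores are z-scored within each dataset first and
values beyond 4 SD are removed, both per (dataset, column) -- scanner and
protocol differences make raw cross-dataset values incommensurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .registry import FEATURE_NAMES, load_pathway_registry
from .simulate import BEHAVIORS

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionResult",
    "WithinDatasetScaler",
    "OutlierTrimmer",
    "zscore_within_dataset",
    "remove_outliers",
    "fit_behavior_model",
    "bonferroni_threshold",
    "BehaviorScan",
    "behavior_scan",
]

BEHAVIOR_DATASETS = ("Development", "YoungAdult", "Aging")


@dataclass(frozen=True)
class RegressionResult:
    """One fitted structure-function model."""

    beta: np.ndarray
    se: np.ndarray
    names: tuple[str, ...]
    p_feature: float
    p_interaction: float
    f_interaction: float
    n_used: int
    sigma2: float

    @property
    def beta_feature(self) -> float:
        return float(self.beta[self.names.index("feature")])

    @property
    def se_feature(self) -> float:
        return float(self.se[self.names.index("feature")])

    def simple_slope(self, dataset: str, reference: str = "Development") -> float:
        """Feature slope within one dataset (b1 plus its interaction dummy)."""
        slope = self.beta_feature
        key = f"feature:{dataset}"
        if dataset != reference and key in self.names:
            slope += float(self.beta[self.names.index(key)])
        return slope


class WithinDatasetScaler(BaseEstimator, TransformerMixin):
    """Z-score columns within each dataset (group) independently.

    Works on a wide DataFrame; ``group_col`` names the dataset column and
    every other numeric column is standardised per group. Columns that are
    constant within any group are excluded (recorded in ``dropped_``) --
    a zero-variance column cannot be standardised.
    """

    def __init__(self, group_col: str = "cohort", columns=None):
        self.group_col = group_col
        self.columns = columns

    def fit(self, X: pd.DataFrame, y=None):
        cols = self.columns
        if cols is None:
            cols = [
                c
                for c in X.columns
                if c != self.group_col and pd.api.types.is_numeric_dtype(X[c])
            ]
        cols = list(cols)
        grouped = X.groupby(self.group_col)[cols]
        self.means_ = grouped.mean()
        self.sds_ = grouped.std(ddof=1)
        constant = (self.sds_.fillna(0.0) == 0.0).any(axis=0)
        self.dropped_ = [c for c in cols if constant[c]]
        for c in self.dropped_:
            logger.warning("excluding constant column %r from z-scoring", c)
        self.columns_ = [c for c in cols if c not in self.dropped_]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        groups = out[self.group_col].to_numpy()
        mu = self.means_.loc[groups, self.columns_].to_numpy()
        sd = self.sds_.loc[groups, self.columns_].to_numpy()
        out[self.columns_] = (out[self.columns_].to_numpy() - mu) / sd
        out = out.drop(columns=[c for c in self.dropped_ if c in out.columns])
        return out


class OutlierTrimmer(BaseEstimator, TransformerMixin):
    """Remove values more than k SD from their (dataset, column) mean.

    Removal is per (group, column) independently: an offending cell is set
    to missing so the subject's other measurements survive. With the
    default k = 4 and roughly Gaussian data essentially nothing is removed
    (tail mass ~6e-5). Counts per column live in ``removed_``. Re-running
    without re-standardising is a fixed point: surviving values already
    lie within k SD.
    """

    def __init__(self, k: float = 4.0, group_col: str = "cohort", columns=None):
        self.k = k
        self.group_col = group_col
        self.columns = columns

    def fit(self, X: pd.DataFrame, y=None):
        cols = self.columns
        if cols is None:
            cols = [
                c
                for c in X.columns
                if c != self.group_col and pd.api.types.is_numeric_dtype(X[c])
            ]
        self.columns_ = list(cols)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        cols = self.columns_
        grouped = out.groupby(self.group_col)[cols]
        mu = grouped.transform("mean").to_numpy()
        sd = grouped.transform("std").to_numpy()
        vals = out[cols].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            bad = np.abs(vals - mu) > self.k * sd
        self.removed_ = {c: int(n) for c, n in zip(cols, bad.sum(axis=0))}
        vals[bad] = np.nan
        out[cols] = vals
        if any(self.removed_.values()):
            logger.info("outlier removal: %s", self.removed_)
        return out


def zscore_within_dataset(
    table: pd.DataFrame, group_col: str = "cohort", columns=None
) -> pd.DataFrame:
    """Standardise columns within each dataset; thin wrapper over the scaler."""
    return WithinDatasetScaler(group_col=group_col, columns=columns).fit_transform(table)


def remove_outliers(
    table: pd.DataFrame, k: float = 4.0, group_col: str = "cohort", columns=None
) -> tuple[pd.DataFrame, dict]:
    """Drop |z| > k rows per (dataset, column); returns (table, removal log)."""
    trimmer = OutlierTrimmer(k=k, group_col=group_col, columns=columns)
    out = trimmer.fit_transform(table)
    return out, trimmer.removed_


def _ols(y: np.ndarray, X: np.ndarray):
    """Classical OLS: coefficients, SEs, residual SS, df. Raises on rank loss."""
    n, p = X.shape
    beta, lstsq_rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError(f"design matrix rank {rank} < {p} columns")
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    return beta, se, rss, df, sigma2


def fit_behavior_model(
    feature_values,
    behavior_values,
    dataset_labels,
    age,
    sex,
    reference: str = "Development",
) -> RegressionResult:
    """OLS fit of the behaviour model for one (pathway, feature, behaviour).

    ``sex`` may be 'F'/'M' strings or 0/1 indicators; age is centred
    within dataset. The interaction p-value comes from the nested-model
    partial F-test jointly on all feature x dataset dummies.

    Raises a ``LinAlgError`` naming the offending columns when the design
    is rank deficient (e.g. a duplicated covariate).
    """
    f = np.asarray(feature_values, dtype=float)
    yv = np.asarray(behavior_values, dtype=float)
    ds = np.asarray(dataset_labels)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    if sex.dtype.kind in "UO":
        sex = (sex == "M").astype(float)
    sex = sex.astype(float)
    ok = np.isfinite(f) & np.isfinite(yv) & np.isfinite(age) & np.isfinite(sex)
    f, yv, ds, age, sex = f[ok], yv[ok], ds[ok], age[ok], sex[ok]

    levels = [d for d in BEHAVIOR_DATASETS if d in set(ds)]
    if reference in levels:
        levels = [reference] + [d for d in levels if d != reference]
    else:
        levels = sorted(set(ds))
    age_c = age.copy()
    for d in levels:
        m = ds == d
        age_c[m] = age[m] - age[m].mean()

    names = ["intercept", "feature"]
    cols = [np.ones_like(f), f]
    inter_idx = []
    for d in levels[1:]:
        dummy = (ds == d).astype(float)
        names.append(f"dataset:{d}")
        cols.append(dummy)
    for d in levels[1:]:
        dummy = (ds == d).astype(float)
        names.append(f"feature:{d}")
        inter_idx.append(len(cols))
        cols.append(f * dummy)
    names += ["age", "sex"]
    cols += [age_c, sex]
    X = np.column_stack(cols)
    if len(yv) <= X.shape[1]:
        raise ValueError(f"n = {len(yv)} too small for {X.shape[1]} parameters")

    try:
        beta, se, rss_full, df_full, sigma2 = _ols(yv, X)
    except np.linalg.LinAlgError as exc:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X[:, 1:], rowvar=False)
        corr = np.nan_to_num(corr, nan=1.0)  # constant columns: flag as collinear
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise np.linalg.LinAlgError(
            f"rank-deficient design ({exc}); most collinear columns: "
            f"{names[1 + i]!r} and {names[1 + j]!r}"
        ) from exc

    t_feat = beta[1] / se[1]
    p_feature = float(2.0 * sps.t.sf(abs(t_feat), df_full))
    if inter_idx:
        keep = [k for k in range(X.shape[1]) if k not in inter_idx]
        _, _, rss_red, _, _ = _ols(yv, X[:, keep])
        q = len(inter_idx)
        f_stat = ((rss_red - rss_full) / q) / (rss_full / df_full)
        p_interaction = float(sps.f.sf(f_stat, q, df_full))
    else:  # single-dataset degradation: no interaction to test
        f_stat, p_interaction = np.nan, np.nan
    return RegressionResult(
        beta=beta,
        se=se,
        names=tuple(names),
        p_feature=p_feature,
        p_interaction=p_interaction,
        f_interaction=float(f_stat),
        n_used=len(yv),
        sigma2=sigma2,
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """alpha / n_tests; the family-wise threshold for the behaviour grid."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


class BehaviorScan(BaseEstimator):
    """The full structure-function grid: one OLS model per cell.

    ``fit(feature_table, behavior_table)`` z-scores features and behaviour
    scores within dataset, removes |z| > 4 outliers, restricts to the
    Development / YoungAdult / Aging datasets (infants have no behaviour
    battery), fits one interaction model per (pathway, feature, behaviour)
    and calls significance at alpha / (n_pathways * n_features) per
    behavioural measure.

    Attributes: ``results_`` (long DataFrame), ``n_tests_`` (models per
    behaviour), ``threshold_``.
    """

    def __init__(
        self,
        behaviors=BEHAVIORS,
        features=FEATURE_NAMES,
        alpha: float = 0.05,
        outlier_k: float = 4.0,
        registry=None,
        reference: str = "Development",
    ):
        self.behaviors = behaviors
        self.features = features
        self.alpha = alpha
        self.outlier_k = outlier_k
        self.registry = registry
        self.reference = reference

    def fit(self, feature_table: pd.DataFrame, behavior_table: pd.DataFrame):
        registry = self.registry if self.registry is not None else load_pathway_registry()
        missing = [b for b in self.behaviors if b not in behavior_table.columns]
        if missing:
            raise ValueError(f"behaviour column(s) missing from table: {missing}")
        pathways = [r.name for r in registry]
        features = [f for f in self.features if f in set(feature_table["feature"])]

        demo = (
            feature_table[["subject_id", "age", "sex", "cohort"]]
            .drop_duplicates("subject_id")
            .set_index("subject_id")
        )
        wide = feature_table.pivot_table(
            index="subject_id", columns=["pathway", "feature"], values="value"
        )
        wide.columns = [f"{p}|{f}" for p, f in wide.columns]
        wide = wide.join(demo)
        wide = wide[wide["cohort"].isin(BEHAVIOR_DATASETS)]

        beh = behavior_table.set_index("subject_id")[list(self.behaviors)]
        beh = beh.join(demo["cohort"])
        beh = beh[beh["cohort"].isin(BEHAVIOR_DATASETS)]

        feat_cols = [c for c in wide.columns if "|" in c]
        wide = zscore_within_dataset(wide, group_col="cohort", columns=feat_cols)
        wide, _ = remove_outliers(
            wide, k=self.outlier_k, group_col="cohort", columns=feat_cols
        )
        beh = zscore_within_dataset(
            beh, group_col="cohort", columns=list(self.behaviors)
        )
        beh, _ = remove_outliers(
            beh, k=self.outlier_k, group_col="cohort", columns=list(self.behaviors)
        )

        self.n_tests_ = len(pathways) * len(features)
        self.threshold_ = bonferroni_threshold(self.alpha, self.n_tests_)
        common = wide.index.intersection(beh.index)
        wide = wide.loc[common]
        beh = beh.loc[common]
        ds_arr = wide["cohort"].to_numpy()
        age_arr = wide["age"].to_numpy(dtype=float)
        sex_arr = (wide["sex"] == "M").to_numpy(dtype=float)
        rows = []
        for b in self.behaviors:
            y_arr = beh[b].to_numpy(dtype=float)
            for p in pathways:
                for f in features:
                    col = f"{p}|{f}"
                    if col not in wide.columns:
                        continue
                    try:
                        res = fit_behavior_model(
                            wide[col].to_numpy(dtype=float),
                            y_arr,
                            ds_arr,
                            age_arr,
                            sex_arr,
                            reference=self.reference,
                        )
                    except (ValueError, np.linalg.LinAlgError) as exc:
                        logger.warning("cell (%s, %s, %s) failed: %s", b, p, f, exc)
                        continue
                    rows.append(
                        {
                            "behavior": b,
                            "pathway": p,
                            "feature": f,
                            "beta1": res.beta_feature,
                            "se": res.se_feature,
                            "p_feature": res.p_feature,
                            "p_interaction": res.p_interaction,
                            "n_used": res.n_used,
                            "significant": res.p_feature < self.threshold_,
                            "significant_interaction": (
                                res.p_interaction < self.threshold_
                                if np.isfinite(res.p_interaction)
                                else False
                            ),
                        }
                    )
        self.results_ = pd.DataFrame(rows)
        return self

    def grid(self, behavior: str) -> pd.DataFrame:
        """Figure-style grid for one behaviour: rows features, columns pathways."""
        sub = self.results_[self.results_["behavior"] == behavior]
        return sub.pivot_table(index="feature", columns="pathway", values="beta1")


def behavior_scan(
    feature_table: pd.DataFrame,
    behavior_table: pd.DataFrame,
    registry=None,
    alpha: float = 0.05,
    **kwargs,
) -> pd.DataFrame:
    scan = BehaviorScan(registry=registry, alpha=alpha, **kwargs)
    return scan.fit(feature_table, behavior_table).results_
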