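"""Joint modeling of evolutionary rate by gradient-boosted regression
trees, the feature-importance spectrum across a (n_trees, depth) grid,
out-of-sample adjusted R^2, and TWAS statistical power.

Tree induction is delegated to xgboost with a squared-error loss,
``max_depth`` playing the interaction-depth role, learning rate equal to
the shrinkage, and no subsampling, so fits are deterministic given the
seed. Feature importance is the total squared-error gain attributed to
each feature, normalized to sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold, ShuffleSplit
import xgboost as xgb

from .datatypes import ValidationError

__all__ = [
    "BoostConfig",
    "BoostedRateModel",
    "fit_boosted",
    "importance_spectrum",
    "ImportanceSpectrum",
    "cv_r2",
    "out_of_sample_r2",
    "twas_power",
    "PowerResult",
    "DEFAULT_GRID",
]

#: the (n_trees, interaction_depth) grid explored for the spectrum
DEFAULT_GRID = [(nt, di) for nt in (100, 500, 1000, 10000) for di in (1, 4, 5)]


@dataclass(frozen=True)
class BoostConfig:
    n_trees: int = 1000
    interaction_depth: int = 4
    shrinkage: float = 0.01
    cv_folds: int = 10
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.shrinkage <= 1):
            raise ValidationError("shrinkage must lie in (0, 1]")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if not (0 < self.train_fraction < 1):
            raise ValidationError("train_fraction must lie in (0, 1)")
        if self.n_trees < 1 or self.interaction_depth < 1:
            raise ValidationError("n_trees and interaction_depth must be >= 1")


def _encode_features(X: pd.DataFrame) -> pd.DataFrame:
    """Ordinal-encode non-numeric columns; keep NaN as missing."""
    out = {}
    for col in X.columns:
        s = X[col]
        if s.dtype == bool:
            out[col] = s.astype(float)
        elif pd.api.types.is_numeric_dtype(s):
            out[col] = pd.to_numeric(s, errors="coerce").astype(float)
        else:
            codes = pd.Categorical(s).codes.astype(float)
            codes[codes < 0] = np.nan
            out[col] = pd.Series(codes, index=s.index)
    return pd.DataFrame(out, index=X.index)


class BoostedRateModel(BaseEstimator, RegressorMixin):
    """Gradient-boosted regression trees for evolutionary rate.

    Stagewise additive model minimizing squared error with learning rate
    ``shrinkage`` and trees of depth ``interaction_depth`` (allowing up to
    that many-way interactions). ``feature_importances_`` holds per-feature
    total gain normalized to sum to 100.
    """

    def __init__(
        self, n_trees: int = 1000, interaction_depth: int = 4,
        shrinkage: float = 0.01, seed: int = 0,
    ):
        self.n_trees = n_trees
        self.interaction_depth = interaction_depth
        self.shrinkage = shrinkage
        self.seed = seed

    def _validate(self, X: pd.DataFrame, y: np.ndarray) -> None:
        if X.shape[1] < 1:
            raise ValidationError("need at least one feature")
        if np.nanstd(y) == 0:
            raise ValidationError("constant target")
        all_missing = [c for c in X.columns if X[c].isna().all()]
        if all_missing:
            raise ValidationError(f"feature {all_missing[0]!r} is entirely missing")

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, float)
        self._validate(X, y)
        Xe = _encode_features(X)
        self.feature_names_ = list(Xe.columns)
        self.model_ = xgb.XGBRegressor(
            objective="reg:squarederror",
            n_estimators=self.n_trees,
            max_depth=self.interaction_depth,
            learning_rate=self.shrinkage,
            subsample=1.0,
            colsample_bytree=1.0,
            reg_lambda=0.0,
            min_child_weight=1.0,
            tree_method="hist",
            n_jobs=1,
            random_state=self.seed,
            base_score=float(np.mean(y)),
        )
        self.model_.fit(Xe.to_numpy(), y)
        booster = self.model_.get_booster()
        gain = booster.get_score(importance_type="total_gain")
        raw = np.array(
            [gain.get(f"f{i}", 0.0) for i in range(len(self.feature_names_))]
        )
        total = raw.sum()
        if total == 0:  # no split ever made; spread importance uniformly
            raw = np.ones_like(raw)
            total = raw.sum()
        self.feature_importances_ = pd.Series(
            100.0 * raw / total, index=self.feature_names_, name="importance"
        )
        return self

    def predict(self, X):
        Xe = _encode_features(pd.DataFrame(X))
        return self.model_.predict(Xe[self.feature_names_].to_numpy())


def fit_boosted(X, y, config: BoostConfig = BoostConfig()) -> BoostedRateModel:
    """Fit the boosted model; returns the estimator with importances."""
    X = pd.DataFrame(X)
    if X.dropna(how="any").shape[0] < 50:
        complete = X.notna().all(axis=1).sum()
        raise ValidationError(f"need >= 50 complete genes, got {complete}")
    return BoostedRateModel(
        n_trees=config.n_trees,
        interaction_depth=config.interaction_depth,
        shrinkage=config.shrinkage,
        seed=config.seed,
    ).fit(X, y)


@dataclass
class ImportanceSpectrum:
    """Importance scores per feature (rows) and grid cell (columns).

    Every column sums to 100. ``top_rank_counts`` counts how often each
    feature is top-ranked across the grid.
    """

    scores: pd.DataFrame
    top_rank_counts: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        sums = self.scores.sum(axis=0).to_numpy(float)
        if not np.allclose(sums, 100.0, atol=1e-6):
            raise ValidationError("importance columns must each sum to 100")
        top = self.scores.idxmax(axis=0)
        self.top_rank_counts = top.value_counts().reindex(
            self.scores.index, fill_value=0
        )


def importance_spectrum(
    X, y, grid=None, shrinkage: float = 0.01, seed: int = 0
) -> ImportanceSpectrum:
    """One boosted fit per (n_trees, depth) grid cell; importance matrix."""
    grid = list(grid) if grid is not None else list(DEFAULT_GRID)
    cols = {}
    for nt, di in grid:
        try:
            model = fit_boosted(
                X, y, BoostConfig(n_trees=nt, interaction_depth=di,
                                  shrinkage=shrinkage, seed=seed)
            )
        except Exception as exc:
            raise RuntimeError(f"boosted fit failed at grid cell ({nt}, {di})") from exc
        cols[f"Nt={nt},Di={di}"] = model.feature_importances_
    return ImportanceSpectrum(scores=pd.DataFrame(cols))


def cv_r2(X, y, config: BoostConfig = BoostConfig()) -> float:
    """Mean k-fold cross-validated R^2 of the boosted model."""
    X = pd.DataFrame(X)
    y = np.asarray(y, float)
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    scores = []
    for train, test in kf.split(X):
        model = fit_boosted(X.iloc[train], y[train], config)
        scores.append(r2_score(y[test], model.predict(X.iloc[test])))
    return float(np.mean(scores))


def out_of_sample_r2(
    X, y, config: BoostConfig = BoostConfig(), n_splits: int = 100
) -> np.ndarray:
    """Distribution of out-of-sample adjusted R^2 over random 70/30 splits.

    Per split the model is trained on ``train_fraction`` of the genes and
    scored on the complement; adjusted R^2 = 1 - (1 - R^2)(m - 1)/(m - k - 1)
    with m test genes and k features.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, float)
    k = X.shape[1]
    splitter = ShuffleSplit(
        n_splits=n_splits, train_size=config.train_fraction, random_state=config.seed
    )
    out = np.empty(n_splits)
    for i, (train, test) in enumerate(splitter.split(X)):
        m = len(test)
        if m - k - 1 <= 0:
            raise ValidationError("test set too small for adjusted R^2")
        model = fit_boosted(X.iloc[train], y[train], config)
        r2 = r2_score(y[test], model.predict(X.iloc[test]))
        out[i] = 1.0 - (1.0 - r2) * (m - 1) / (m - k - 1)
    return out


@dataclass
class PowerResult:
    """Per-gene TWAS power and the conserved vs fast-evolving comparison."""

    power: pd.Series
    median_power: dict
    prop_powered: dict  # fraction with power >= 0.8 per group
    u_statistic: float | None
    pvalue: float | None
    alpha: float
    gwas_n: int
    phi2: float


def twas_power(
    imputation_r2,
    gwas_n: int = 1000,
    alpha: float = 0.05,
    phi2: float = 0.01,
    omega=None,
    conserved_below: float = 0.01,
    fast_above: float = 1.0,
    power_threshold: float = 0.8,
) -> PowerResult:
    """Statistical power of a TWAS association test per gene.

    The association chi-square(1) statistic has non-centrality
    lambda = N x R^2 x phi^2, where R^2 is the expression imputation
    quality and phi^2 the fraction of trait variance mediated by total
    expression; power is the probability that the non-central
    chi-square(1, lambda) exceeds the central critical value at ``alpha``
    (r2 = 0 gives power = alpha exactly).

    With ``omega`` supplied, conserved (omega < 0.01 by default) and
    fast-evolving (omega > 1) genes are compared by a two-sided
    Mann-Whitney U on their power values.
    """
    r2 = pd.Series(imputation_r2, dtype=float)
    if ((r2 < 0) | (r2 > 1)).any():
        raise ValidationError("imputation R^2 must lie in [0, 1]")
    if gwas_n < 2:
        raise ValidationError("gwas_n must be >= 2")
    if not (0 < phi2 <= 1):
        raise ValidationError("phi2 must lie in (0, 1]")
    crit = stats.chi2.ppf(1.0 - alpha, df=1)
    lam = gwas_n * r2.to_numpy() * phi2
    power = pd.Series(stats.ncx2.sf(crit, df=1, nc=lam), index=r2.index, name="power")
    median_power = {"all": float(power.median())}
    prop_powered = {"all": float((power >= power_threshold).mean())}
    u = p = None
    if omega is not None:
        om = pd.Series(omega).reindex(r2.index)
        conserved = power[om < conserved_below]
        fast = power[om > fast_above]
        for name, grp in (("conserved", conserved), ("fast", fast)):
            median_power[name] = float(grp.median()) if len(grp) else float("nan")
            prop_powered[name] = (
                float((grp >= power_threshold).mean()) if len(grp) else float("nan")
            )
        if len(conserved) and len(fast):
            res = stats.mannwhitneyu(conserved, fast, alternative="two-sided")
            u, p = float(res.statistic), float(res.pvalue)
    return PowerResult(
        power=power,
        median_power=median_power,
        prop_powered=prop_powered,
        u_statistic=u,
        pvalue=p,
        alpha=alpha,
        gwas_n=gwas_n,
        phi2=phi2,
    )
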