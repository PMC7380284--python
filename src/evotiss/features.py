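"""Per-tissue expression features.

Per-tissue moments (mean, median, variance, variance-to-mean), the tau
expression-breadth statistic, the MaxTissue/MaxVariance pair (the tissue
in which a gene attains its maximum inter-individual expression variance),
and latent-factor residualization of hidden confounders.

Moments are computed on raw values by default; ``scale="log2p1"``
switches to log2(x+1). tau is always computed from raw-scale per-tissue
mean expression (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import (
    EvolRates,
    ExpressionDataset,
    GeneFeatureTable,
    GeneNetwork,
    ValidationError,
)

__all__ = [
    "MomentScale",
    "per_tissue_moments",
    "compute_tau",
    "tau_profile",
    "identify_max_tissue",
    "max_tissue_table",
    "FactorResidualizer",
    "residualize",
    "build_feature_table",
]


class MomentScale(str, Enum):
    raw = "raw"
    log2p1 = "log2p1"


def _apply_scale(values: np.ndarray, scale: MomentScale | str) -> np.ndarray:
    scale = MomentScale(scale)
    if scale is MomentScale.raw:
        return values
    return np.log2(values + 1.0)


def per_tissue_moments(
    ds: ExpressionDataset, scale: MomentScale | str = MomentScale.raw
) -> pd.DataFrame:
    """Per-gene, per-tissue mean/median/variance/variance-to-mean.

    Returns a DataFrame with a (stat, tissue) column MultiIndex. Sample
    variance uses the n-1 denominator; tissues with a single sample get
    missing variance (with a warning); variance-to-mean is missing where
    the mean is 0.
    """
    tissues = ds.tissues
    blocks: dict[tuple[str, str], np.ndarray] = {}
    for tissue in tissues:
        cols = ds.samples_in(tissue)
        x = _apply_scale(ds.values.loc[:, cols].to_numpy(float), scale)
        mean = x.mean(axis=1)
        median = np.median(x, axis=1)
        if x.shape[1] >= 2:
            var = x.var(axis=1, ddof=1)
        else:
            warnings.warn(
                f"tissue {tissue!r} has < 2 samples; variance is missing",
                stacklevel=2,
            )
            var = np.full(x.shape[0], np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            vtm = np.where(mean != 0, var / mean, np.nan)
        blocks[("mean", tissue)] = mean
        blocks[("median", tissue)] = median
        blocks[("variance", tissue)] = var
        blocks[("var_to_mean", tissue)] = vtm
    out = pd.DataFrame(blocks, index=ds.gene_ids)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["stat", "tissue"])
    return out.sort_index(axis=1)


def compute_tau(x, exclude=None, labels=None) -> float:
    """Tissue-specificity statistic tau for one gene.

    tau = sum_i (1 - x_i/max_j x_j) / (n - 1), a score in [0, 1]: 0 means
    identical expression in every tissue, 1 single-tissue expression.

    ``x`` is the per-tissue summary (e.g. mean) expression, nonnegative.
    ``exclude`` drops tissues by label (requires ``labels``) before the
    computation. Missing when max(x) = 0; error for fewer than 2 tissues.
    """
    x = np.asarray(x, dtype=float)
    if exclude:
        if labels is None:
            raise ValueError("tissue exclusions require tissue labels")
        keep = [i for i, t in enumerate(labels) if t not in set(exclude)]
        x = x[keep]
    if x.size < 2:
        raise ValidationError("tau requires at least 2 tissues")
    if (x < 0).any():
        raise ValidationError("tau requires nonnegative expression values")
    m = x.max()
    if m == 0:
        return float("nan")
    return float(np.sum(1.0 - x / m) / (x.size - 1))


def tau_profile(means: pd.DataFrame, exclude=()) -> pd.Series:
    """Vectorized tau for all genes from a genes-x-tissues mean matrix."""
    cols = [c for c in means.columns if c not in set(exclude)]
    if len(cols) < 2:
        raise ValidationError("tau requires at least 2 tissues after exclusions")
    x = means[cols].to_numpy(float)
    if (x < 0).any():
        raise ValidationError("tau requires nonnegative expression values")
    m = x.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        xhat = x / m[:, None]
    tau = np.sum(1.0 - xhat, axis=1) / (x.shape[1] - 1)
    tau[m == 0] = np.nan
    return pd.Series(tau, index=means.index, name="tau")


def identify_max_tissue(variances: pd.Series) -> tuple[str, float]:
    """Argmax tissue of the per-tissue variances and its value.

    Ties are broken lexicographically by tissue label; all-missing input
    is an error.
    """
    v = variances.dropna()
    if v.empty:
        raise ValidationError("all per-tissue variances are missing")
    v = v.sort_index()
    idx = int(np.argmax(v.to_numpy()))
    return str(v.index[idx]), float(v.iloc[idx])


def max_tissue_table(variances: pd.DataFrame) -> pd.DataFrame:
    """Vectorized MaxTissue/MaxVariance for a genes-x-tissues variance matrix.

    Rows with every variance missing get NaN/NA. Lexicographic tie-break.
    """
    v = variances.reindex(columns=sorted(variances.columns))
    arr = v.to_numpy(float)
    all_nan = np.all(np.isnan(arr), axis=1)
    safe = np.where(np.isnan(arr), -np.inf, arr)
    pos = np.argmax(safe, axis=1)  # first occurrence = lexicographic winner
    max_tissue = np.asarray(v.columns, dtype=object)[pos]
    max_var = safe[np.arange(arr.shape[0]), pos]
    out = pd.DataFrame(
        {"max_tissue": max_tissue, "max_variance": max_var}, index=v.index
    )
    out.loc[all_nan, "max_tissue"] = pd.NA
    out.loc[all_nan, "max_variance"] = np.nan
    return out


class FactorResidualizer(BaseEstimator, TransformerMixin):
    """Residualize log expression on leading latent factors, per tissue.

    A lightweight latent-factor stand-in for hidden-confounder correction:
    within each tissue the gene-centered log2(x+1) sample-by-gene matrix is
    decomposed by SVD and the top ``k_factors`` sample loadings (plus any
    known covariates) are regressed out of every gene.

    Attributes (after fit): ``factors_`` mapping tissue -> (samples x k)
    loading matrix.
    """

    def __init__(self, k_factors: int = 0, covariates: dict | None = None):
        self.k_factors = k_factors
        self.covariates = covariates

    def fit(self, ds: ExpressionDataset, y=None):
        if self.k_factors < 0:
            raise ValidationError("k_factors must be >= 0")
        self.factors_ = {}
        for tissue in ds.tissues:
            cols = ds.samples_in(tissue)
            if self.k_factors >= len(cols):
                raise ValidationError(
                    f"k_factors={self.k_factors} >= {len(cols)} samples "
                    f"in tissue {tissue!r}"
                )
            x = np.log2(ds.values.loc[:, cols].to_numpy(float) + 1.0).T
            x = x - x.mean(axis=0, keepdims=True)
            if self.k_factors > 0:
                u, _, _ = np.linalg.svd(x, full_matrices=False)
                self.factors_[tissue] = u[:, : self.k_factors]
            else:
                self.factors_[tissue] = np.empty((len(cols), 0))
        return self

    def transform(self, ds: ExpressionDataset) -> ExpressionDataset:
        out = np.empty_like(ds.values.to_numpy(float))
        out_df = pd.DataFrame(out, index=ds.gene_ids, columns=ds.sample_ids)
        for tissue in ds.tissues:
            cols = ds.samples_in(tissue)
            x = np.log2(ds.values.loc[:, cols].to_numpy(float) + 1.0).T
            x = x - x.mean(axis=0, keepdims=True)
            design = [self.factors_[tissue]]
            if self.covariates and tissue in self.covariates:
                c = np.asarray(self.covariates[tissue], dtype=float)
                c = (c - c.mean(axis=0)).reshape(len(cols), -1)
                design.append(c)
            d = np.hstack(design)
            if d.shape[1] > 0:
                beta, *_ = np.linalg.lstsq(d, x, rcond=None)
                x = x - d @ beta
            out_df.loc[:, cols] = x.T
        return ExpressionDataset(out_df, ds.tissue_of, residual=True)


def residualize(
    ds: ExpressionDataset, k_factors: int, covariates: dict | None = None
) -> ExpressionDataset:
    """Functional wrapper over :class:`FactorResidualizer`."""
    return FactorResidualizer(k_factors, covariates).fit(ds).transform(ds)


def build_feature_table(
    ds: ExpressionDataset,
    rates: EvolRates | None = None,
    network: GeneNetwork | None = None,
    branches: pd.Series | None = None,
    imputation_r2: pd.Series | None = None,
    gene_sets: dict[str, set] | None = None,
    scale: MomentScale | str = MomentScale.raw,
    exclude_tissues=(),
) -> GeneFeatureTable:
    """Assemble the per-gene design matrix from a dataset and annotations.

    Moments (and hence MaxVariance/MaxTissue/max level) follow ``scale``;
    tau always uses raw-scale per-tissue means with ``exclude_tissues``
    dropped. Genes absent from an annotation get NA.
    """
    scale = MomentScale(scale)
    moments = per_tissue_moments(ds, scale)
    raw_means = (
        moments["mean"]
        if scale is MomentScale.raw
        else per_tissue_moments(ds, MomentScale.raw)["mean"]
    )
    mt = max_tissue_table(moments["variance"])
    summary = pd.DataFrame(index=ds.gene_ids)
    summary["tau"] = tau_profile(raw_means, exclude=exclude_tissues)
    summary["max_variance"] = mt["max_variance"]
    summary["max_tissue"] = mt["max_tissue"]
    summary["max_level"] = moments["mean"].max(axis=1)
    summary["mean_level"] = moments["mean"].mean(axis=1)
    if network is not None:
        summary["degree"] = network.degree_series().reindex(ds.gene_ids)
    else:
        summary["degree"] = np.nan
    summary["branch"] = (
        branches.reindex(ds.gene_ids) if branches is not None else pd.NA
    )
    summary["imputation_r2"] = (
        imputation_r2.reindex(ds.gene_ids) if imputation_r2 is not None else np.nan
    )
    for flag in ("essential", "mendelian", "lof_tolerant"):
        members = (gene_sets or {}).get(flag)
        summary[flag] = (
            summary.index.isin(members) if members is not None else pd.NA
        )
    return GeneFeatureTable(summary=summary, moments=moments, scale=scale.value)
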