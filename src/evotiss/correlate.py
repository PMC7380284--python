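"""Feature-rate correlation profiles, tissue clustering, highly-variable
gene comparisons and tau tissue-downsampling stability."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .datatypes import EvolRates, ExpressionDataset, GeneFeatureTable, ValidationError
from .features import per_tissue_moments, tau_profile

__all__ = [
    "spearman",
    "CorrelationProfile",
    "correlation_profile",
    "cluster_tissues",
    "compare_top_variable",
    "tau_downsampling",
    "TauDownsampling",
]

#: feature x rate-type cells of a correlation profile
PROFILE_FEATURES = ["mean", "variance", "var_to_mean"]
PROFILE_RATES = ["dN", "dS", "omega"]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p with pairwise deletion of missing pairs.

    Average ranks for ties; requires n >= 3 complete pairs and nonzero
    variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError(f"spearman needs >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("spearman undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationProfile:
    """Per-tissue Spearman rho (and p) for feature x rate-type combinations.

    Rows are tissues; columns are "<feature>|<rate>" pairs among
    {mean, variance, var_to_mean} x {dN, dS, omega}.
    """

    rho: pd.DataFrame
    pvalues: pd.DataFrame
    n_genes: pd.DataFrame

    @property
    def tissues(self) -> list[str]:
        return list(self.rho.index)


def correlation_profile(
    features: GeneFeatureTable, rates: EvolRates
) -> CorrelationProfile:
    """Spearman correlation of per-tissue expression moments with rates.

    Genes are matched between the feature table and the rate table;
    each cell uses pairwise-complete genes.
    """
    if features.moments is None:
        raise ValidationError("feature table lacks per-tissue moments")
    shared = features.moments.index.intersection(rates.gene_ids)
    if len(shared) < 3:
        raise ValidationError("fewer than 3 genes shared with the rate table")
    mom = features.moments.loc[shared]
    rate_vals = {r: rates.table.loc[shared, r].to_numpy(float) for r in PROFILE_RATES}
    tissues = sorted(mom["mean"].columns)
    cols = [f"{f}|{r}" for f in PROFILE_FEATURES for r in PROFILE_RATES]
    rho = pd.DataFrame(index=pd.Index(tissues, name="tissue"), columns=cols, dtype=float)
    pv = rho.copy()
    ng = rho.copy()
    for tissue in tissues:
        for feat in PROFILE_FEATURES:
            x = mom[(feat, tissue)].to_numpy(float)
            for rate in PROFILE_RATES:
                y = rate_vals[rate]
                keep = np.isfinite(x) & np.isfinite(y)
                cell = f"{feat}|{rate}"
                r, p = spearman(x[keep], y[keep])
                rho.loc[tissue, cell] = r
                pv.loc[tissue, cell] = p
                ng.loc[tissue, cell] = int(keep.sum())
    return CorrelationProfile(rho=rho, pvalues=pv, n_genes=ng)


def cluster_tissues(
    profile: CorrelationProfile, impute_row_mean: bool = False
) -> tuple[list[str], np.ndarray]:
    """Average-linkage hierarchical clustering of tissues on their rho rows.

    Euclidean distance, deterministic leaf ordering. Missing cells are an
    error unless ``impute_row_mean`` fills them with the row mean.
    Returns (ordered tissue labels, scipy linkage matrix); a single tissue
    yields a trivial ordering and an empty linkage.
    """
    x = profile.rho.copy()
    if x.isna().to_numpy().any():
        if not impute_row_mean:
            raise ValidationError("missing cells in profile; set impute_row_mean")
        x = x.T.fillna(x.mean(axis=1)).T
    if x.shape[0] < 2:
        return list(x.index), np.empty((0, 4))
    link = hierarchy.linkage(x.to_numpy(float), method="average", metric="euclidean")
    order = hierarchy.leaves_list(link)
    return [x.index[i] for i in order], link


def compare_top_variable(
    tissue_a: str,
    tissue_b: str,
    features: GeneFeatureTable,
    rates: EvolRates,
    top_n: int = 1000,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on omega of the two tissues' top-variance genes.

    The top ``top_n`` genes by per-tissue expression variance (with defined
    omega) are selected in each tissue; overlapping genes are retained.
    """
    if features.moments is None:
        raise ValidationError("feature table lacks per-tissue moments")
    var = features.moments["variance"]
    omega = rates.omega.reindex(var.index)
    sets = {}
    for tissue in (tissue_a, tissue_b):
        if tissue not in var.columns:
            raise ValidationError(f"unknown tissue {tissue!r}")
        v = var[tissue].where(omega.notna())
        avail = int(v.notna().sum())
        if avail < top_n:
            raise ValidationError(
                f"tissue {tissue!r} has only {avail} genes with variance and omega"
            )
        sets[tissue] = v.nlargest(top_n).index
    a = omega.loc[sets[tissue_a]].to_numpy(float)
    b = omega.loc[sets[tissue_b]].to_numpy(float)
    method = "exact" if max(len(a), len(b)) < 20 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class TauDownsampling:
    """Per-gene sd of tau across random tissue subsets, by subset size."""

    sd_tau: pd.DataFrame  # genes x subset sizes
    tau_full: pd.Series
    rho: dict[int, float]  # Spearman(sd_tau, tau_full) per size
    pvalue: dict[int, float]


def tau_downsampling(
    ds: ExpressionDataset,
    subset_sizes,
    n_reps: int = 100,
    seed: int = 0,
    exclude=(),
) -> TauDownsampling:
    """Stability of tau under random tissue-catalog downsampling.

    For each subset size, draw ``n_reps`` random tissue subsets without
    replacement, recompute tau from the per-tissue raw means, and report
    the per-gene sd across replicates plus its Spearman correlation with
    the full-catalog tau.
    """
    means = per_tissue_moments(ds, "raw")["mean"]
    means = means[[c for c in means.columns if c not in set(exclude)]]
    tissues = list(means.columns)
    tau_full = tau_profile(means)
    rng = np.random.default_rng(seed)
    sd = {}
    rho = {}
    pv = {}
    for size in subset_sizes:
        if size < 2:
            raise ValidationError("subset size must be >= 2")
        if size > len(tissues):
            raise ValidationError("subset size exceeds the tissue count")
        taus = np.empty((len(means), n_reps))
        for rep in range(n_reps):
            pick = rng.choice(len(tissues), size=size, replace=False)
            taus[:, rep] = tau_profile(means.iloc[:, pick]).to_numpy()
        sd[size] = np.nanstd(taus, axis=1, ddof=1)
        r, p = spearman(sd[size], tau_full.to_numpy())
        rho[size], pv[size] = r, p
    sd_df = pd.DataFrame(sd, index=means.index)
    return TauDownsampling(sd_tau=sd_df, tau_full=tau_full, rho=rho, pvalue=pv)
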