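"""The tissue-anchored model of evolutionary rate.

A gene's MaxTissue — the tissue in which it attains its maximum
inter-individual expression variance — is tested for association with
omega = dN/dS by a Kruskal-Wallis test, backed by a gene-count-preserving
permutation null; each tissue's "evolutionary signature" is the median
omega of the genes anchored there, with the MaxTissue-delta metric
3.14 (v75 - v25)/sqrt(n) as its dispersion; the MaxTissue / primary
affected tissue overlap supplies an independent developmental check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PermutationResult, ValidationError

__all__ = [
    "kruskal_h",
    "max_tissue_association",
    "max_tissue_permutation",
    "max_tissue_delta",
    "tissue_signature",
    "AnchorTestResult",
    "anchor_test",
    "affected_tissue_overlap",
    "OverlapResult",
]


def _codes_and_ranks(labels, values):
    labels = np.asarray(labels)
    values = np.asarray(values, dtype=float)
    if labels.shape != values.shape:
        raise ValidationError("labels and values must have equal length")
    keep = np.isfinite(values)
    labels, values = labels[keep], values[keep]
    groups, codes = np.unique(labels, return_inverse=True)
    if len(groups) < 2:
        raise ValidationError("need at least 2 tissues with genes")
    ranks = stats.rankdata(values)  # average ranks for ties
    return groups, codes, ranks, values


def _h_from_rank_sums(rank_sums, counts, n, tie_correction):
    h = 12.0 / (n * (n + 1)) * np.sum(rank_sums**2 / counts) - 3.0 * (n + 1)
    return h / tie_correction if tie_correction > 0 else 0.0


def _tie_correction(values, n):
    _, t = np.unique(values, return_counts=True)
    return 1.0 - np.sum(t**3 - t) / (n**3 - n)


def kruskal_h(labels, values) -> tuple[float, int]:
    """Kruskal-Wallis H with tie correction; returns (H, k groups)."""
    groups, codes, ranks, vals = _codes_and_ranks(labels, values)
    n = len(ranks)
    tie = _tie_correction(vals, n)
    if tie == 0:  # every observation identical
        return 0.0, len(groups)
    rank_sums = np.bincount(codes, weights=ranks)
    counts = np.bincount(codes).astype(float)
    return float(_h_from_rank_sums(rank_sums, counts, n, tie)), len(groups)


def max_tissue_association(max_tissue, omega) -> tuple[float, float]:
    """Kruskal-Wallis test of omega across MaxTissue groups.

    Returns (H, analytic p) with p from the chi-square distribution on
    (#tissues - 1) degrees of freedom. All-identical omega gives H = 0,
    p = 1.
    """
    h, k = kruskal_h(max_tissue, omega)
    return h, float(stats.chi2.sf(h, k - 1))


def max_tissue_permutation(
    max_tissue, omega, n_perm: int = 1000, seed: int = 0
) -> PermutationResult:
    """Gene-count-preserving permutation null for the MaxTissue association.

    Each permutation randomly reassigns genes to tissues while keeping the
    per-tissue gene counts of the observed MaxTissue configuration fixed
    (a uniform shuffle of the label vector); the statistic is the
    Kruskal-Wallis H, and the empirical p is the proportion of
    permutations with H >= observed.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    groups, codes, ranks, vals = _codes_and_ranks(max_tissue, omega)
    n = len(ranks)
    tie = _tie_correction(vals, n)
    counts = np.bincount(codes).astype(float)
    if tie == 0:
        observed = 0.0
        null = np.zeros(n_perm)
    else:
        rank_sums = np.bincount(codes, weights=ranks)
        observed = float(_h_from_rank_sums(rank_sums, counts, n, tie))
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm_codes = rng.permutation(codes)
            perm_counts = np.bincount(perm_codes, minlength=len(groups))
            assert np.array_equal(perm_counts, counts.astype(int))
            rs = np.bincount(perm_codes, weights=ranks, minlength=len(groups))
            null[i] = _h_from_rank_sums(rs, counts, n, tie)
    return PermutationResult(
        observed=observed, null_values=null, n_perm=n_perm, seed=seed, tail="ge"
    )


def max_tissue_delta(omega) -> float:
    """MaxTissue-delta: 3.14 (v75 - v25) / sqrt(n) for one tissue's genes.

    v75/v25 are the 75th/25th percentiles of omega (linear interpolation)
    and n the number of genes anchored in the tissue. The constant is the
    literal 3.14 of the metric's definition.
    """
    x = np.asarray(omega, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValidationError("empty gene group")
    v75, v25 = np.percentile(x, [75, 25])
    return float(3.14 * (v75 - v25) / np.sqrt(x.size))


def tissue_signature(max_tissue, omega, drop_tissue: str | None = None) -> pd.DataFrame:
    """Per-tissue evolutionary signature: (median omega, delta, n).

    The "evolutionary rate of a tissue" is the median omega of the genes
    for which it is the MaxTissue; rows are sorted by that median.
    ``drop_tissue`` removes one tissue's genes first (leave-one-tissue-out).
    """
    labels = np.asarray(max_tissue)
    vals = np.asarray(omega, dtype=float)
    keep = np.isfinite(vals)
    if drop_tissue is not None:
        keep &= labels != drop_tissue
    labels, vals = labels[keep], vals[keep]
    rows = []
    for tissue in np.unique(labels):
        grp = vals[labels == tissue]
        rows.append(
            {
                "tissue": tissue,
                "median_omega": float(np.median(grp)),
                "delta": max_tissue_delta(grp),
                "n": int(grp.size),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("median_omega", kind="mergesort")
        .set_index("tissue")
    )


@dataclass
class AnchorTestResult:
    """Full tissue-anchored test: analytic KW, permutation null, signatures."""

    h_statistic: float
    p_analytic: float
    permutation: PermutationResult | None
    signature: pd.DataFrame  # median omega, delta, n per tissue

    def __post_init__(self) -> None:
        if self.h_statistic < 0:
            raise ValidationError("H must be nonnegative")


def anchor_test(
    max_tissue,
    omega,
    n_perm: int = 1000,
    seed: int = 0,
    drop_tissue: str | None = None,
) -> AnchorTestResult:
    """Run the complete tissue-anchored association analysis."""
    labels = np.asarray(max_tissue)
    vals = np.asarray(omega, dtype=float)
    if drop_tissue is not None:
        keep = labels != drop_tissue
        labels, vals = labels[keep], vals[keep]
    h, p = max_tissue_association(labels, vals)
    perm = (
        max_tissue_permutation(labels, vals, n_perm=n_perm, seed=seed)
        if n_perm
        else None
    )
    return AnchorTestResult(
        h_statistic=h,
        p_analytic=p,
        permutation=perm,
        signature=tissue_signature(labels, vals),
    )


@dataclass
class OverlapResult:
    chi2: float
    pvalue: float
    dof: int
    match_odds_ratio: float
    odds_ratio_infinite: bool
    n_genes: int
    n_dropped: int


def affected_tissue_overlap(max_tissue: pd.Series, affected: pd.Series) -> OverlapResult:
    """Association between MaxTissue and the primary affected tissue.

    Chi-square test of independence on the full contingency table of
    MaxTissue x affected tissue over shared genes; genes whose MaxTissue
    label has no counterpart in the affected-tissue vocabulary are dropped
    (counted in ``n_dropped``). The per-tissue 2x2 tables
    (MaxTissue = t vs not) x (affected = t vs not) are combined across
    tissues into the Mantel-Haenszel common odds ratio, reported as
    ``match_odds_ratio`` (flagged infinite when the discordant cells
    vanish).
    """
    shared = max_tissue.index.intersection(affected.index)
    if len(shared) == 0:
        raise ValidationError("no shared genes between the two annotations")
    mt = max_tissue.loc[shared].astype(str)
    af = affected.loc[shared].astype(str)
    vocab = set(af.unique())
    keep = mt.isin(vocab)
    n_dropped = int((~keep).sum())
    mt, af = mt[keep], af[keep]
    table = pd.crosstab(mt, af)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("degenerate contingency table (single row or column)")
    chi2, p, dof, _ = stats.chi2_contingency(table)

    num = den = 0.0
    for tissue in sorted(set(mt.unique()) | set(af.unique())):
        is_mt = (mt == tissue).to_numpy()
        is_af = (af == tissue).to_numpy()
        n = len(mt)
        a = np.sum(is_mt & is_af)
        b = np.sum(is_mt & ~is_af)
        c = np.sum(~is_mt & is_af)
        d = n - a - b - c
        num += a * d / n
        den += b * c / n
    infinite = den == 0
    oratio = float("inf") if infinite else float(num / den)
    return OverlapResult(
        chi2=float(chi2),
        pvalue=float(p),
        dof=int(dof),
        match_odds_ratio=oratio,
        odds_ratio_infinite=bool(infinite),
        n_genes=int(len(mt)),
        n_dropped=n_dropped,
    )
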