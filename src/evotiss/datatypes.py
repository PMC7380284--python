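"""Core domain types shared by every stage of the pipeline.

The objects here are thin, validated wrappers around pandas/networkx
containers: an expression matrix with a sample->tissue map, a per-gene
substitution-rate table, a per-gene feature table, an undirected gene
network, and the common return shape of permutation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "EvolRates",
    "GeneFeatureTable",
    "GeneNetwork",
    "PermutationResult",
]


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


@dataclass
class ExpressionDataset:
    """Gene-by-sample nonnegative expression matrix (RPKM scale).

    Parameters
    ----------
    values : DataFrame, genes x samples, finite and >= 0.
    tissue_of : Series mapping every sample id to a tissue label.
    residual : bool
        When True the matrix holds signed residuals (e.g. after factor
        residualization) and the nonnegativity check is skipped.
    """

    values: pd.DataFrame
    tissue_of: pd.Series
    residual: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        arr = v.to_numpy()
        if not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression value for gene {v.index[g]!r}, "
                f"sample {v.columns[s]!r}"
            )
        if not self.residual and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative expression value for gene {v.index[g]!r}, "
                f"sample {v.columns[s]!r}"
            )
        missing = v.columns.difference(self.tissue_of.index)
        if len(missing) > 0:
            raise ValidationError(
                f"sample {missing[0]!r} has no tissue label in the tissue map"
            )
        # keep the map aligned and restricted to the matrix samples
        self.tissue_of = self.tissue_of.reindex(v.columns)

    # -- conveniences -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def tissues(self) -> list[str]:
        return sorted(self.tissue_of.unique())

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in(self, tissue: str) -> pd.Index:
        return self.tissue_of.index[self.tissue_of == tissue]

    def tissue_sample_counts(self) -> pd.Series:
        return self.tissue_of.value_counts().sort_index()

    def require_min_samples(self, minimum: int) -> None:
        counts = self.tissue_sample_counts()
        bad = counts[counts < minimum]
        if len(bad) > 0:
            raise ValidationError(
                f"tissue {bad.index[0]!r} has {bad.iloc[0]} samples "
                f"(minimum {minimum})"
            )

    def subset_tissues(self, tissues) -> "ExpressionDataset":
        keep = self.tissue_of.index[self.tissue_of.isin(list(tissues))]
        return ExpressionDataset(
            self.values.loc[:, keep], self.tissue_of.loc[keep], self.residual
        )


@dataclass
class EvolRates:
    """Per-gene dN, dS and omega = dN/dS for one species comparison.

    ``omega`` is missing (NaN), never 0 or inf, wherever dS = 0.
    """

    table: pd.DataFrame  # columns: dN, dS, omega; index: gene ids
    comparison: str = "unspecified"

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise ValidationError(
                f"duplicate gene id in rates: {t.index[t.index.duplicated()][0]!r}"
            )
        for col in ("dN", "dS"):
            x = t[col].to_numpy(float)
            if not np.isfinite(x).all():
                bad = t.index[~np.isfinite(x)][0]
                raise ValidationError(f"non-finite {col} for gene {bad!r}")
            if (x < 0).any():
                bad = t.index[x < 0][0]
                raise ValidationError(f"negative {col} for gene {bad!r}")
        with np.errstate(divide="ignore", invalid="ignore"):
            omega = np.where(
                t["dS"].to_numpy(float) > 0,
                t["dN"].to_numpy(float) / t["dS"].to_numpy(float),
                np.nan,
            )
        self.table = t.assign(omega=omega)

    @classmethod
    def from_arrays(cls, gene_ids, dN, dS, comparison="unspecified") -> "EvolRates":
        return cls(
            pd.DataFrame({"dN": dN, "dS": dS}, index=pd.Index(gene_ids, name="gene")),
            comparison=comparison,
        )

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def dN(self) -> pd.Series:
        return self.table["dN"]

    @property
    def dS(self) -> pd.Series:
        return self.table["dS"]

    @property
    def omega(self) -> pd.Series:
        return self.table["omega"]


#: gene-level columns of a feature table, in stable serialization order
FEATURE_COLUMNS = [
    "tau",
    "max_variance",
    "max_tissue",
    "max_level",
    "mean_level",
    "degree",
    "branch",
    "imputation_r2",
    "essential",
    "mendelian",
    "lof_tolerant",
]

#: per-tissue moment statistics, serialized as "<stat>.<tissue>" columns
MOMENT_STATS = ["mean", "median", "variance", "var_to_mean"]


@dataclass
class GeneFeatureTable:
    """Per-gene derived features: the design matrix of the analysis.

    ``summary`` holds the gene-level columns (tau, MaxVariance, MaxTissue,
    max level, degree, branch, imputation R2, gene-set flags); ``moments``
    holds per-tissue mean/median/variance/variance-to-mean with a
    (stat, tissue) column MultiIndex. Either may carry missing values (NA).
    """

    summary: pd.DataFrame
    moments: pd.DataFrame | None = None
    scale: str = "raw"

    def __post_init__(self) -> None:
        s = self.summary
        if s.index.duplicated().any():
            raise ValidationError("duplicate gene id in feature table")
        if "tau" in s:
            tau = s["tau"].to_numpy(float)
            ok = np.isnan(tau) | ((tau >= 0) & (tau <= 1 + 1e-12))
            if not ok.all():
                raise ValidationError(
                    f"tau out of [0,1] for gene {s.index[~ok][0]!r}"
                )
        if self.moments is not None and "max_variance" in s:
            var = self.moments["variance"]
            mv = s["max_variance"].to_numpy(float)
            vmax = var.max(axis=1).to_numpy(float)
            both = ~np.isnan(mv) & ~np.isnan(vmax)
            if both.any() and not np.allclose(mv[both], vmax[both], rtol=1e-9):
                raise ValidationError(
                    "max_variance does not equal the maximum per-tissue variance"
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.summary.index


@dataclass
class GeneNetwork:
    """Undirected gene graph: no self-loops, no multi-edges."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValidationError(f"self-loop on node {loops[0][0]!r}")

    @classmethod
    def from_edges(cls, edges, nodes=None) -> "GeneNetwork":
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        g.add_edges_from((a, b) for a, b in edges if a != b)
        return cls(g)

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree_series(self) -> pd.Series:
        deg = dict(self.graph.degree())
        return pd.Series(deg, name="degree").sort_index()

    def degree_sequence(self) -> np.ndarray:
        return np.array(sorted(d for _, d in self.graph.degree()))


@dataclass
class PermutationResult:
    """Observed statistic, permutation null draws and the empirical p.

    ``empirical_p`` follows the "matched or exceeded" convention:
    count(null >= observed)/n_perm for tail="ge" (may be exactly 0; the
    resolution bound is 1/n_perm), count(|null| >= |observed|)/n_perm for
    tail="two-sided".
    """

    observed: float
    null_values: np.ndarray
    n_perm: int
    seed: int
    tail: str = "ge"
    empirical_p: float = field(init=False)

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        if self.null_values.shape != (self.n_perm,):
            raise ValidationError("null_values length must equal n_perm")
        if self.tail == "ge":
            count = int(np.sum(self.null_values >= self.observed))
        elif self.tail == "two-sided":
            count = int(np.sum(np.abs(self.null_values) >= abs(self.observed)))
        else:
            raise ValidationError(f"unknown tail {self.tail!r}")
        self.empirical_p = count / self.n_perm

    @property
    def resolution(self) -> float:
        return 1.0 / self.n_perm

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1))
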