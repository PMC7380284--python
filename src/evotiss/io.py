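"""Readers and writers for the plain-text formats used by the pipeline.

All tables are TSV with "NA" as the missing-value token. Expression can
also be read from a GCT-like layout (two header lines before the matrix).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    FEATURE_COLUMNS,
    MOMENT_STATS,
    EvolRates,
    ExpressionDataset,
    GeneFeatureTable,
    GeneNetwork,
    ValidationError,
)

logger = logging.getLogger("evotiss")

NA = "NA"


def read_tissue_map(path) -> pd.Series:
    """Read a two-column sample->tissue TSV (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"tissue map {path} needs two columns")
    # tolerate an optional header line
    if df.iloc[0, 0].lower() in ("sample", "sample_id"):
        df = df.iloc[1:]
    ser = pd.Series(df.iloc[:, 1].values, index=pd.Index(df.iloc[:, 0], name="sample"))
    if ser.index.duplicated().any():
        raise ValidationError("duplicate sample id in tissue map")
    return ser


def read_expression(
    path,
    tissue_map_path,
    fmt: str = "tsv",
    min_samples_per_tissue: int = 1,
) -> ExpressionDataset:
    """Read a genes-x-samples expression TSV plus its sample->tissue map.

    ``fmt="gct"`` skips the two GCT header lines. Negative, non-numeric or
    duplicate entries are rejected with the offending record named.
    """
    skip = 2 if fmt == "gct" else 0
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip, na_values=[NA])
    arr = df.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        raise ValidationError(f"non-numeric expression value in {path}")
    tissue_of = read_tissue_map(tissue_map_path)
    ds = ExpressionDataset(df.astype(float), tissue_of)
    ds.require_min_samples(min_samples_per_tissue)
    return ds


def write_expression(ds: ExpressionDataset, path, tissue_map_path=None) -> None:
    ds.values.to_csv(path, sep="\t", na_rep=NA)
    if tissue_map_path is not None:
        ds.tissue_of.rename("tissue").to_csv(
            tissue_map_path, sep="\t", header=False
        )


def read_rates(path, comparison: str | None = None) -> EvolRates:
    """Read a gene/dN/dS TSV; omega is derived, missing where dS = 0."""
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    cols = {c.lower(): c for c in df.columns}
    try:
        gene_c, dn_c, ds_c = cols["gene"], cols["dn"], cols["ds"]
    except KeyError as exc:
        raise ValidationError(f"rates file {path} needs gene/dN/dS columns") from exc
    if comparison is None:
        comparison = cols.get("comparison")
        comparison = (
            str(df[comparison].iloc[0]) if comparison is not None else "unspecified"
        )
    table = pd.DataFrame(
        {"dN": df[dn_c].to_numpy(float), "dS": df[ds_c].to_numpy(float)},
        index=pd.Index(df[gene_c].astype(str), name="gene"),
    )
    return EvolRates(table, comparison=comparison)


def write_rates(rates: EvolRates, path) -> None:
    out = rates.table.reset_index()
    out.insert(0, "comparison", rates.comparison)
    out.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_network(path) -> GeneNetwork:
    """Read a two-column edge list; dedup edges, drop self-loops (logged)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.empty:
        raise ValidationError(f"empty network file: {path}")
    loops = int((df.iloc[:, 0] == df.iloc[:, 1]).sum())
    if loops:
        logger.info("read_network: dropped %d self-loop(s)", loops)
    return GeneNetwork.from_edges(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_network(net: GeneNetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in net.graph.edges:
            fh.write(f"{a}\t{b}\n")


def read_gene_set(path) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_gene_set(genes, path) -> None:
    Path(path).write_text("\n".join(sorted(map(str, genes))) + "\n")


# -- feature table -------------------------------------------------------


def write_feature_table(ft: GeneFeatureTable, path) -> None:
    """Serialize summary + per-tissue moments in a stable column order."""
    parts = [ft.summary.reindex(columns=[c for c in FEATURE_COLUMNS if c in ft.summary])]
    extra = [c for c in ft.summary.columns if c not in FEATURE_COLUMNS]
    if extra:
        parts.append(ft.summary[extra])
    if ft.moments is not None:
        flat = ft.moments.copy()
        flat.columns = [f"{stat}.{tissue}" for stat, tissue in flat.columns]
        parts.append(flat)
    out = pd.concat(parts, axis=1)
    out.index.name = "gene"
    out.to_csv(path, sep="\t", na_rep=NA)


def read_feature_table(path, scale: str = "raw") -> GeneFeatureTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    moment_cols = [
        c for c in df.columns if "." in c and c.split(".", 1)[0] in MOMENT_STATS
    ]
    summary = df[[c for c in df.columns if c not in moment_cols]]
    moments = None
    if moment_cols:
        moments = df[moment_cols].copy()
        moments.columns = pd.MultiIndex.from_tuples(
            [tuple(c.split(".", 1)) for c in moment_cols], names=["stat", "tissue"]
        )
    return GeneFeatureTable(summary=summary, moments=moments, scale=scale)


# -- config and run log --------------------------------------------------


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must be a key-value mapping")
    return cfg


def log_run(path, **fields) -> None:
    """Append one JSON line per run with seed, parameters and versions."""
    import evotiss

    fields.setdefault("evotiss_version", evotiss.__version__)
    with open(path, "a") as fh:
        fh.write(json.dumps(fields, default=str) + "\n")
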