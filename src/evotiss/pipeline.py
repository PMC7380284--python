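"""One driver chaining simulate -> features -> correlate -> anchor ->
eprca/gls/nulls -> boost -> power with a single config and seed.

Stages communicate only through files in the package's TSV formats, so
any stage can be run standalone on user-supplied data. A RunManifest
records the config snapshot, seed, per-stage outputs and checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .anchor import affected_tissue_overlap, anchor_test
from .correlate import correlation_profile, tau_downsampling
from .datatypes import ValidationError
from .features import build_feature_table
from .model import BoostConfig, importance_spectrum, out_of_sample_r2, twas_power
from .robust import branch_preserving_permutation, degree_preserving_null, eprca, gls_fit
from .simulate import SimConfig, block_covariance, simulate_dataset
from .correlate import spearman

STAGES = [
    "simulate",
    "features",
    "correlate",
    "anchor",
    "eprca",
    "gls",
    "nulls",
    "boost",
    "power",
]

#: per-stage upstream requirements (stage -> files it consumes)
_REQUIRES = {
    "simulate": [],
    "features": ["expression.tsv", "tissue_map.tsv"],
    "correlate": ["features.tsv", "rates.tsv"],
    "anchor": ["features.tsv", "rates.tsv"],
    "eprca": ["features.tsv", "rates.tsv"],
    "gls": ["features.tsv", "rates.tsv"],
    "nulls": ["features.tsv", "rates.tsv", "network.tsv", "branches.tsv"],
    "boost": ["features.tsv", "rates.tsv"],
    "power": ["imputation_r2.tsv", "rates.tsv"],
}

_PRODUCES = {
    "simulate": [
        "expression.tsv",
        "tissue_map.tsv",
        "rates.tsv",
        "network.tsv",
        "branches.tsv",
        "affected_tissue.tsv",
        "imputation_r2.tsv",
        "sim_manifest.json",
    ],
    "features": ["features.tsv"],
    "correlate": ["profile_rho.tsv", "profile_p.tsv", "tau_downsampling.tsv"],
    "anchor": ["anchor_signature.tsv", "anchor_summary.json"],
    "eprca": ["eprca.json"],
    "gls": ["gls.json"],
    "nulls": ["nulls.json"],
    "boost": ["importance_spectrum.tsv", "oos_adjusted_r2.tsv"],
    "power": ["power.tsv", "power_summary.json"],
}


@dataclass
class RunManifest:
    config: dict
    seed: int
    out_dir: str
    stages: list[str] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)  # stage -> {file: sha256}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _check_dependencies(stages: list[str], out: Path) -> None:
    available = set()
    for stage in STAGES:
        if stage not in stages:
            continue
        for req in _REQUIRES[stage]:
            if req not in available and not (out / req).exists():
                raise ValidationError(
                    f"stage {stage!r} requires {req!r}: run the producing stage "
                    "first or provide the file"
                )
        available.update(_PRODUCES[stage])


def run_pipeline(config: dict | str | Path, out_dir=None, seed=None) -> RunManifest:
    """Execute the selected stages in dependency order.

    ``config`` is a mapping (or path to a YAML file) with optional keys:
    ``stages`` (default: all), ``seed``, ``out_dir``, ``simulate`` (SimConfig
    fields), ``features`` (scale, exclude_tissues, subset sizes), ``anchor``
    (n_perm), ``eprca`` (n_perm), ``nulls`` (n_perm), ``boost`` (grid,
    n_splits) and ``power`` (gwas_n, alpha, phi2).
    """
    if not isinstance(config, dict):
        config = eio.read_config(config)
    unknown = set(config) - {
        "stages", "seed", "out_dir", "simulate", "features", "anchor",
        "eprca", "gls", "nulls", "boost", "power", "correlate",
    }
    if unknown:
        raise ValidationError(f"unknown config section(s): {sorted(unknown)}")
    seed = int(config.get("seed", 0) if seed is None else seed)
    out = Path(out_dir if out_dir is not None else config.get("out_dir", "evotiss_run"))
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", STAGES))
    for s in stages:
        if s not in STAGES:
            raise ValidationError(f"unknown stage {s!r}")
    stages = [s for s in STAGES if s in stages]
    _check_dependencies(stages, out)

    manifest = RunManifest(config=dict(config), seed=seed, out_dir=str(out))
    log = out / "run.log"

    def record(stage: str) -> None:
        manifest.stages.append(stage)
        manifest.outputs[stage] = {
            f: _sha256(out / f) for f in _PRODUCES[stage] if (out / f).exists()
        }
        eio.log_run(log, stage=stage, seed=seed)
        manifest.save(out / "manifest.json")

    for stage in stages:
        _RUNNERS[stage](config, out, seed)
        record(stage)
    return manifest


# -- stage runners -------------------------------------------------------


def _stage_simulate(config, out: Path, seed: int) -> None:
    sim_kwargs = dict(config.get("simulate", {}))
    sim_kwargs["seed"] = seed
    data = simulate_dataset(SimConfig(**sim_kwargs))
    eio.write_expression(
        data.expression, out / "expression.tsv", out / "tissue_map.tsv"
    )
    eio.write_rates(data.rates, out / "rates.tsv")
    eio.write_network(data.network, out / "network.tsv")
    data.branches.to_csv(out / "branches.tsv", sep="\t")
    data.affected_tissue.to_csv(out / "affected_tissue.tsv", sep="\t")
    data.imputation_r2.to_csv(out / "imputation_r2.tsv", sep="\t")
    for name, members in data.gene_sets.items():
        eio.write_gene_set(members, out / f"geneset_{name}.txt")
    with open(out / "sim_manifest.json", "w") as fh:
        json.dump(data.manifest(), fh, indent=2, default=str)


def _load_annotation(out: Path, name: str) -> pd.Series | None:
    path = out / name
    if not path.exists():
        return None
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[eio.NA])
    return df.iloc[:, 0]


def _stage_features(config, out: Path, seed: int) -> None:
    fcfg = config.get("features", {})
    ds = eio.read_expression(out / "expression.tsv", out / "tissue_map.tsv")
    rates_path = out / "rates.tsv"
    rates = eio.read_rates(rates_path) if rates_path.exists() else None
    network = (
        eio.read_network(out / "network.tsv") if (out / "network.tsv").exists() else None
    )
    gene_sets = {}
    for name in ("essential", "mendelian", "lof_tolerant"):
        p = out / f"geneset_{name}.txt"
        if p.exists():
            gene_sets[name] = eio.read_gene_set(p)
    ft = build_feature_table(
        ds,
        rates=rates,
        network=network,
        branches=_load_annotation(out, "branches.tsv"),
        imputation_r2=_load_annotation(out, "imputation_r2.tsv"),
        gene_sets=gene_sets or None,
        scale=fcfg.get("scale", "raw"),
        exclude_tissues=fcfg.get("exclude_tissues", ()),
    )
    eio.write_feature_table(ft, out / "features.tsv")


def _stage_correlate(config, out: Path, seed: int) -> None:
    ccfg = config.get("correlate", {})
    ft = eio.read_feature_table(out / "features.tsv")
    rates = eio.read_rates(out / "rates.tsv")
    profile = correlation_profile(ft, rates)
    profile.rho.to_csv(out / "profile_rho.tsv", sep="\t", na_rep=eio.NA)
    profile.pvalues.to_csv(out / "profile_p.tsv", sep="\t", na_rep=eio.NA)
    ds = eio.read_expression(out / "expression.tsv", out / "tissue_map.tsv")
    n_tissues = len(ds.tissues)
    sizes = [s for s in ccfg.get("subset_sizes", (10, 30)) if s < n_tissues]
    if sizes:
        td = tau_downsampling(
            ds, sizes, n_reps=int(ccfg.get("n_reps", 100)), seed=seed
        )
        td.sd_tau.to_csv(out / "tau_downsampling.tsv", sep="\t", na_rep=eio.NA)
    else:
        (out / "tau_downsampling.tsv").write_text("gene\n")


def _stage_anchor(config, out: Path, seed: int) -> None:
    acfg = config.get("anchor", {})
    ft = eio.read_feature_table(out / "features.tsv")
    rates = eio.read_rates(out / "rates.tsv")
    shared = ft.gene_ids.intersection(rates.gene_ids)
    labels = ft.summary.loc[shared, "max_tissue"]
    omega = rates.omega.loc[shared]
    keep = labels.notna() & omega.notna()
    res = anchor_test(
        labels[keep].to_numpy(),
        omega[keep].to_numpy(),
        n_perm=int(acfg.get("n_perm", 1000)),
        seed=seed,
        drop_tissue=acfg.get("drop_tissue"),
    )
    res.signature.to_csv(out / "anchor_signature.tsv", sep="\t", na_rep=eio.NA)
    summary = {
        "H": res.h_statistic,
        "p_analytic": res.p_analytic,
        "p_empirical": res.permutation.empirical_p if res.permutation else None,
        "n_perm": res.permutation.n_perm if res.permutation else 0,
        "seed": seed,
    }
    affected = _load_annotation(out, "affected_tissue.tsv")
    if affected is not None:
        ov = affected_tissue_overlap(labels[keep], affected)
        summary["overlap"] = {
            "chi2": ov.chi2,
            "p": ov.pvalue,
            "match_odds_ratio": ov.match_odds_ratio,
            "infinite": ov.odds_ratio_infinite,
        }
    with open(out / "anchor_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


def _stage_eprca(config, out: Path, seed: int) -> None:
    """Independent effect of MaxVariance on omega given expression breadth."""
    ecfg = config.get("eprca", {})
    ft = eio.read_feature_table(out / "features.tsv")
    rates = eio.read_rates(out / "rates.tsv")
    shared = ft.gene_ids.intersection(rates.gene_ids)
    s = ft.summary.loc[shared]
    omega = rates.omega.loc[shared]
    keep = s["max_variance"].notna() & s["tau"].notna() & omega.notna()
    res = eprca(
        np.log(s.loc[keep, "max_variance"] + 1e-12),
        np.log(omega[keep]),
        s.loc[keep, "tau"],
        n_perm=int(ecfg.get("n_perm", 1000)),
        seed=seed,
    )
    with open(out / "eprca.json", "w") as fh:
        json.dump(
            {
                "determinant": "log max_variance",
                "conditioner": "tau",
                "r_obs": res.r_obs,
                "null_mean": res.null_mean,
                "null_sd": res.null_sd,
                "empirical_p": res.empirical_p,
                "theta_adj": res.theta_adj,
                "n_perm": res.n_perm,
                "n_genes": int(keep.sum()),
            },
            fh,
            indent=2,
        )


def _stage_gls(config, out: Path, seed: int) -> None:
    """Level-rate effect re-estimated under a block co-expression covariance."""
    gcfg = config.get("gls", {})
    ft = eio.read_feature_table(out / "features.tsv")
    rates = eio.read_rates(out / "rates.tsv")
    shared = ft.gene_ids.intersection(rates.gene_ids)
    s = ft.summary.loc[shared]
    dn = rates.dN.loc[shared]
    keep = s["mean_level"].notna() & dn.notna()
    n = min(int(gcfg.get("n_genes", 500)), int(keep.sum()))
    idx = s.index[keep][:n]
    g = np.log(s.loc[idx, "mean_level"].to_numpy(float) + 1.0)
    g = g - g.mean()
    x = dn.loc[idx].to_numpy(float)
    delta = block_covariance(
        n, int(gcfg.get("block_size", 25)), float(gcfg.get("block_rho", 0.3))
    )
    fit = gls_fit(g, x, delta)
    ols = gls_fit(g, x, np.eye(n))
    with open(out / "gls.json", "w") as fh:
        json.dump(
            {
                "pi_hat_gls": fit.pi_hat,
                "var_pi_hat_gls": fit.var_pi_hat,
                "pi_hat_ols": ols.pi_hat,
                "var_pi_hat_ols": ols.var_pi_hat,
                "n": n,
            },
            fh,
            indent=2,
        )


def _stage_nulls(config, out: Path, seed: int) -> None:
    ncfg = config.get("nulls", {})
    n_perm = int(ncfg.get("n_perm", 10000))
    ft = eio.read_feature_table(out / "features.tsv")
    rates = eio.read_rates(out / "rates.tsv")
    network = eio.read_network(out / "network.tsv")
    branches = _load_annotation(out, "branches.tsv")
    shared = ft.gene_ids.intersection(rates.gene_ids)
    s = ft.summary.loc[shared]
    omega = rates.omega.loc[shared]
    keep = (s["mean_level"].notna() & omega.notna() & branches.loc[shared].notna()).to_numpy()
    level = np.log(s["mean_level"].to_numpy(float)[keep] + 1.0)
    om = omega.to_numpy(float)[keep]
    br = branches.loc[shared].to_numpy()[keep]

    def stat_branch(om_perm):
        return abs(spearman(om_perm, level)[0])

    branch_res = branch_preserving_permutation(
        om, br, stat_branch, n_perm=n_perm, seed=seed
    )

    def stat_degree(net, om_series):
        deg = net.degree_series().reindex(om_series.index)
        return abs(spearman(deg.to_numpy(float), om_series.to_numpy(float))[0])

    om_series = omega.dropna()
    net_nodes = pd.Index(network.nodes).intersection(om_series.index)
    sub = network.graph.subgraph(net_nodes).copy()
    degree_res = degree_preserving_null(
        type(network)(sub),
        om_series.loc[net_nodes],
        stat_degree,
        n_perm=n_perm,
        seed=seed,
        mode=ncfg.get("mode", "strata"),
    )
    with open(out / "nulls.json", "w") as fh:
        json.dump(
            {
                "branch": {
                    "statistic": "abs Spearman(omega, log mean level)",
                    "observed": branch_res.observed,
                    "empirical_p": branch_res.empirical_p,
                    "n_perm": branch_res.n_perm,
                },
                "degree": {
                    "statistic": "abs Spearman(degree, omega)",
                    "observed": degree_res.observed,
                    "empirical_p": degree_res.empirical_p,
                    "n_perm": degree_res.n_perm,
                },
            },
            fh,
            indent=2,
        )


_BOOST_FEATURES = [
    "max_level",
    "max_variance",
    "mean_level",
    "tau",
    "degree",
    "branch",
    "imputation_r2",
]


def boost_design(ft, rates):
    """Feature matrix and log-omega target for the boosted model."""
    shared = ft.gene_ids.intersection(rates.gene_ids)
    s = ft.summary.loc[shared]
    omega = rates.omega.loc[shared]
    keep = omega.notna() & (omega > 0)
    cols = [c for c in _BOOST_FEATURES if c in s.columns]
    return s.loc[keep, cols], np.log(omega[keep].to_numpy(float))


def _stage_boost(config, out: Path, seed: int) -> None:
    bcfg = config.get("boost", {})
    ft = eio.read_feature_table(out / "features.tsv")
    rates = eio.read_rates(out / "rates.tsv")
    X, y = boost_design(ft, rates)
    grid = [tuple(cell) for cell in bcfg.get("grid", [(500, 1), (1000, 4)])]
    spectrum = importance_spectrum(X, y, grid=grid, seed=seed)
    spectrum.scores.to_csv(out / "importance_spectrum.tsv", sep="\t")
    r2 = out_of_sample_r2(
        X,
        y,
        BoostConfig(
            n_trees=int(bcfg.get("n_trees", 1000)),
            interaction_depth=int(bcfg.get("interaction_depth", 4)),
            seed=seed,
        ),
        n_splits=int(bcfg.get("n_splits", 10)),
    )
    pd.Series(r2, name="adjusted_r2").to_csv(out / "oos_adjusted_r2.tsv", sep="\t")


def _stage_power(config, out: Path, seed: int) -> None:
    pcfg = config.get("power", {})
    r2 = _load_annotation(out, "imputation_r2.tsv")
    rates = eio.read_rates(out / "rates.tsv")
    res = twas_power(
        r2,
        gwas_n=int(pcfg.get("gwas_n", 1000)),
        alpha=float(pcfg.get("alpha", 0.05)),
        phi2=float(pcfg.get("phi2", 0.01)),
        omega=rates.omega,
    )
    res.power.to_csv(out / "power.tsv", sep="\t")
    with open(out / "power_summary.json", "w") as fh:
        json.dump(
            {
                "median_power": res.median_power,
                "prop_powered": res.prop_powered,
                "mwu_p": res.pvalue,
                "gwas_n": res.gwas_n,
                "alpha": res.alpha,
                "phi2": res.phi2,
            },
            fh,
            indent=2,
        )


_RUNNERS = {
    "simulate": _stage_simulate,
    "features": _stage_features,
    "correlate": _stage_correlate,
    "anchor": _stage_anchor,
    "eprca": _stage_eprca,
    "gls": _stage_gls,
    "nulls": _stage_nulls,
    "boost": _stage_boost,
    "power": _stage_power,
}
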