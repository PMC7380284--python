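"""Synthetic multi-tissue expression / evolutionary-rate generator.

Emulates the statistical structure the downstream analysis assumes:

* log-normal multi-tissue expression with a mean-variance relation,
* a tau spectrum from broadly expressed to tissue-specific genes,
* negative coupling of expression level and variance with omega = dN/dS,
* a latent anchor tissue per gene, with inflated inter-individual
  variance there and tissue-level shifts of median log omega,
* optional batch confounding and co-expression blocks,
* a heavy-tailed degree network rank-coupled to conservation,
* branch (gene-age) labels, affected-tissue annotation, and imputation-R2
  values positively coupled to omega.

The generative core is a three-axis latent factor model per gene:
``c`` (expression level), ``u`` (anchor-tissue variability) and ``h``
(tissue specificity, the normal score of the profile peakedness kappa).
log omega loads negatively on c and u and positively on h; the loadings
are calibrated once (constants below) so the realized per-tissue Spearman
correlation between expression level and omega matches the configured
target, and frozen.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .datatypes import EvolRates, ExpressionDataset, GeneNetwork, ValidationError

__all__ = [
    "SimConfig",
    "SimulatedData",
    "simulate_dataset",
    "simulate_noisy_proxy",
    "simulate_coexpressed",
    "block_covariance",
]

# ---------------------------------------------------------------------
# frozen generator constants (see module docstring and docs/methods.md)
# ---------------------------------------------------------------------
_M0 = np.log(3.0)  # baseline log-e expression (RPKM ~ 3)
_SIGMA_BASE = 1.2  # gene-level log-expression sd along c
_KAPPA_RANGES = ((0.0, 0.35), (0.3, 1.1), (1.1, 6.0))  # broad/intermediate/specific
_XI_RANGE = (0.3, 1.0)  # non-anchor attenuation multiplier of kappa
_S0 = 0.5  # within-tissue log-e sd baseline
_ANCHOR_INFL = 0.6  # anchor log-sd inflation intercept
_S_U = 0.35  # anchor log-sd loading on u
_SIGMA_JITTER = 0.15  # per-(gene,tissue) log-sd jitter
_W_H = 0.22  # specificity (h) loading in the omega latent
# linear map from the target per-tissue Spearman(level, omega) to the c
# loading: w_c = (_LEVEL_OFFSET - |target|) / _LEVEL_GAIN, clipped to >= 0.
# Calibrated at the default geometry (44 tissues, 70 samples/tissue).
_LEVEL_OFFSET = 0.088
_LEVEL_GAIN = -0.530
_BRANCH_PROPS = np.array(
    [0.35, 0.15, 0.10, 0.08, 0.07, 0.06, 0.05, 0.04, 0.03, 0.025, 0.02, 0.015, 0.01]
)
_BRANCH_NOISE = 0.9  # noise sd of the branch-assignment latent around c
_R2_INTERCEPT, _R2_SLOPE = -1.4, 0.9  # logistic map for imputation R2


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic generator.

    Defaults mirror the reference setting the analysis is designed for:
    a 44-tissue catalog with 70 samples per tissue, omega spanning two to
    three orders of magnitude, per-tissue level-omega Spearman near -0.3,
    and 60% of log-omega variance carried by the feature-driven signal.
    """

    n_genes: int = 5000
    n_tissues: int = 44
    samples_per_tissue: int = 70
    target_rho_level: float = -0.30
    target_rho_variance: float = -0.30
    anchor_effect_sd: float = 0.15
    tau_mixture: tuple[float, float, float] = (0.25, 0.35, 0.40)
    batch_effect_sd: float = 0.25
    coexpr_block_size: int = 25
    block_rho: float = 0.3
    degree_exponent: float = 2.5
    degree_swap_frac: float = 0.3
    r2_coupling: float = 0.3
    explainable_variance: float = 0.6
    p_match: float = 0.5
    omega_log_mean: float = float(np.log(0.08))
    omega_log_sd: float = 1.5
    ds_log_mean: float = float(np.log(0.5))
    ds_log_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_tissues < 2 or self.samples_per_tissue < 2:
            raise ValidationError("need n_genes>=1, n_tissues>=2, samples>=2")
        if abs(sum(self.tau_mixture) - 1.0) > 1e-9:
            raise ValidationError("tau_mixture proportions must sum to 1")
        for name in ("anchor_effect_sd", "batch_effect_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("target_rho_level", "target_rho_variance"):
            v = getattr(self, name)
            if not (-1.0 < v <= 0.0):
                raise ValidationError(f"{name} must lie in (-1, 0]")
        if not (0.0 < self.explainable_variance < 1.0):
            raise ValidationError("explainable_variance must lie in (0, 1)")
        if self.coexpr_block_size > self.n_genes:
            raise ValidationError("coexpr_block_size exceeds n_genes")
        if not (0.0 <= self.block_rho < 1.0):
            raise ValidationError("block_rho must lie in [0, 1)")
        if self.anchor_effect_sd**2 >= self.explainable_variance * self.omega_log_sd**2:
            raise ValidationError(
                "anchor_effect_sd^2 exceeds the explainable log-omega variance"
            )


@dataclass
class SimulatedData:
    """Bundle of everything one call to :func:`simulate_dataset` produces."""

    expression: ExpressionDataset
    rates: EvolRates
    network: GeneNetwork
    branches: pd.Series
    affected_tissue: pd.Series
    imputation_r2: pd.Series
    gene_sets: dict[str, set]
    config: SimConfig
    truth: dict = field(repr=False, default_factory=dict)

    def manifest(self) -> dict:
        out = dataclasses.asdict(self.config)
        out["n_edges"] = self.network.n_edges
        return out


def _power_law_degrees(rng, n, exponent, d_max=1000):
    u = rng.random(n)
    d = np.floor(u ** (-1.0 / (exponent - 1.0))).astype(int)
    return np.clip(d, 1, min(d_max, n - 1))


def simulate_dataset(config: SimConfig) -> SimulatedData:
    """Draw one complete synthetic study from ``config`` (deterministic per seed)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    G, T, S = cfg.n_genes, cfg.n_tissues, cfg.samples_per_tissue
    genes = pd.Index([f"g{i:05d}" for i in range(G)], name="gene")
    tissues = [f"T{t:02d}" for t in range(T)]

    # latent axes
    c = rng.standard_normal(G)  # expression level
    u = rng.standard_normal(G)  # anchor variability
    klass = rng.choice(3, size=G, p=np.asarray(cfg.tau_mixture))
    lo = np.array([_KAPPA_RANGES[k][0] for k in klass])
    hi = np.array([_KAPPA_RANGES[k][1] for k in klass])
    kappa = rng.uniform(lo, hi)
    # normal score of kappa: the specificity axis entering the omega latent
    h = norm.ppf((np.argsort(np.argsort(kappa)) + 0.5) / G)
    anchor = rng.integers(0, T, size=G)
    delta = rng.normal(0.0, cfg.anchor_effect_sd, size=T)
    e = rng.standard_normal(G)

    # omega latent: loadings calibrated to the configured couplings
    target = 0.5 * (abs(cfg.target_rho_level) + abs(cfg.target_rho_variance))
    w_c = max((_LEVEL_OFFSET - target) / _LEVEL_GAIN, 0.0)
    w_h = _W_H
    if w_c**2 + w_h**2 >= 1.0:
        raise ValidationError("coupling targets too strong for the latent model")
    w_u = np.sqrt(1.0 - w_c**2 - w_h**2)
    zeta = -w_c * c - w_u * u + w_h * h
    var_sys = cfg.explainable_variance * cfg.omega_log_sd**2 - cfg.anchor_effect_sd**2
    var_res = (1.0 - cfg.explainable_variance) * cfg.omega_log_sd**2
    log_omega = (
        cfg.omega_log_mean
        + np.sqrt(var_sys) * zeta
        + delta[anchor]
        + np.sqrt(var_res) * e
    )
    omega = np.exp(log_omega)
    dS = rng.lognormal(cfg.ds_log_mean, cfg.ds_log_sd, size=G)
    dN = omega * dS
    rates = EvolRates.from_arrays(genes, dN, dS, comparison="synthetic")

    # per-(gene,tissue) log-mean and log-sd
    xi = rng.uniform(*_XI_RANGE, size=(G, T))
    profile = -xi
    profile[np.arange(G), anchor] = 1.0
    mu = _M0 + _SIGMA_BASE * c[:, None] + kappa[:, None] * profile
    sigma = _S0 * np.exp(_SIGMA_JITTER * rng.standard_normal((G, T)))
    sigma[np.arange(G), anchor] = _S0 * np.exp(_ANCHOR_INFL + _S_U * u)

    # sample-level expression, tissue by tissue
    n_blocks = max(G // max(cfg.coexpr_block_size, 1), 1)
    block_of = np.arange(G) % n_blocks if cfg.block_rho > 0 else None
    cols: list[str] = []
    tissue_labels: list[str] = []
    mats = []
    b_gene = (
        rng.normal(0.0, cfg.batch_effect_sd, size=G)
        if cfg.batch_effect_sd > 0
        else None
    )
    batch_flags = {}
    for t, tissue in enumerate(tissues):
        eps = rng.standard_normal((G, S))
        if block_of is not None:
            f = rng.standard_normal((n_blocks, S))
            eps = np.sqrt(cfg.block_rho) * f[block_of] + np.sqrt(1 - cfg.block_rho) * eps
        logx = mu[:, t][:, None] + sigma[:, t][:, None] * eps
        if b_gene is not None:
            flag = rng.integers(0, 2, size=S)
            batch_flags[tissue] = flag
            logx = logx + np.outer(b_gene, flag)
        mats.append(np.exp(logx))
        cols.extend(f"{tissue}_s{j:03d}" for j in range(S))
        tissue_labels.extend([tissue] * S)
    values = pd.DataFrame(np.hstack(mats), index=genes, columns=cols)
    tissue_of = pd.Series(tissue_labels, index=pd.Index(cols, name="sample"))
    expression = ExpressionDataset(values, tissue_of)

    # degree-coupled heavy-tailed network (rank matching with swap noise)
    degrees = np.sort(_power_law_degrees(rng, G, cfg.degree_exponent))[::-1]
    r = 2.0 * np.sin((1.0 - cfg.degree_swap_frac) * np.pi / 6.0)
    noise_sd = np.sqrt(max(1.0 / r**2 - 1.0, 0.0)) if r > 0 else np.inf
    q = c + rng.standard_normal(G) * noise_sd
    order = np.argsort(-q)  # most conserved genes get the largest degrees
    deg_assigned = np.empty(G, dtype=int)
    deg_assigned[order] = degrees
    if deg_assigned.sum() % 2:
        deg_assigned[order[0]] += 1
    gm = nx.configuration_model(deg_assigned, seed=int(rng.integers(2**31 - 1)))
    graph = nx.Graph(gm)
    graph.remove_edges_from(nx.selfloop_edges(graph))
    graph = nx.relabel_nodes(graph, dict(enumerate(genes)))
    network = GeneNetwork(graph)

    # branch (gene age): oldest branches hold the most conserved genes
    b_lat = c + _BRANCH_NOISE * rng.standard_normal(G)
    counts = np.round(_BRANCH_PROPS / _BRANCH_PROPS.sum() * G).astype(int)
    counts[-1] = G - counts[:-1].sum()
    branch = np.empty(G, dtype=int)
    branch[np.argsort(-b_lat)] = np.repeat(np.arange(len(counts)), counts)
    branches = pd.Series(branch, index=genes, name="branch")

    # affected tissue: the anchor with probability p_match, else uniform
    match = rng.random(G) < cfg.p_match
    random_t = rng.integers(0, T, size=G)
    affected = np.where(match, anchor, random_t)
    affected_tissue = pd.Series(
        [tissues[t] for t in affected], index=genes, name="affected_tissue"
    )

    # imputation R2, positively coupled to omega
    z_omega = (log_omega - log_omega.mean()) / log_omega.std()
    lat = cfg.r2_coupling * z_omega + np.sqrt(
        1 - cfg.r2_coupling**2
    ) * rng.standard_normal(G)
    imputation_r2 = pd.Series(
        expit(_R2_INTERCEPT + _R2_SLOPE * lat), index=genes, name="imputation_r2"
    )

    # clinical gene sets along the conservation axis
    z_cons = -z_omega
    gene_sets = {
        "essential": set(genes[rng.random(G) < expit(-2.0 + 1.2 * z_cons)]),
        "mendelian": set(genes[rng.random(G) < expit(-2.3 + 0.6 * z_cons)]),
        "lof_tolerant": set(genes[rng.random(G) < expit(-3.0 - 1.0 * z_cons)]),
    }

    truth = {
        "c": c,
        "u": u,
        "h": h,
        "kappa": kappa,
        "tau_class": klass,
        "anchor": pd.Series([tissues[a] for a in anchor], index=genes, name="anchor"),
        "delta": pd.Series(delta, index=tissues, name="delta"),
        "log_omega": log_omega,
        "batch_flags": batch_flags,
        "batch_effect": b_gene,
        "loadings": {"w_c": w_c, "w_u": float(w_u), "w_h": w_h},
    }
    return SimulatedData(
        expression=expression,
        rates=rates,
        network=network,
        branches=branches,
        affected_tissue=affected_tissue,
        imputation_r2=imputation_r2,
        gene_sets=gene_sets,
        config=cfg,
        truth=truth,
    )


def simulate_noisy_proxy(x, noise_sd: float, seed: int) -> np.ndarray:
    """X' = X + independent zero-mean Gaussian noise with sd ``noise_sd``."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValidationError("x must be finite")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if noise_sd == 0:
        return x.copy()
    return x + rng.normal(0.0, noise_sd, size=x.shape)


def block_covariance(n: int, block_size: int, rho: float) -> np.ndarray:
    """Block-diagonal equicorrelation covariance (unit variances)."""
    cov = np.eye(n)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        cov[start:stop, start:stop] = rho
    np.fill_diagonal(cov, 1.0)
    return cov


def simulate_coexpressed(
    n_genes: int,
    delta_cov: np.ndarray,
    pi_true: float,
    dN,
    noise_scale: float,
    seed: int,
) -> np.ndarray:
    """G = pi_true * dN + eps with eps ~ N(0, noise_scale^2 * Delta)."""
    delta_cov = np.asarray(delta_cov, dtype=float)
    if delta_cov.shape != (n_genes, n_genes):
        raise ValidationError("Delta dimension must equal n_genes")
    try:
        chol = np.linalg.cholesky(delta_cov)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("Delta must be symmetric positive definite") from exc
    rng = np.random.default_rng(seed)
    eps = noise_scale * (chol @ rng.standard_normal(n_genes))
    return pi_true * np.asarray(dN, dtype=float) + eps
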