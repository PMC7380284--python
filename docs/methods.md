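# Methods

## The quantities and the model

The package treats protein evolutionary rate as ω = dN/dS per gene for a
named species comparison; ω is left undefined (missing, never 0 or ∞)
when dS = 0. Expression enters through per-tissue summaries of a
gene-by-sample nonnegative matrix: mean, median, sample variance
(n − 1 denominator) and variance-to-mean, on the raw scale by default or
on log2(x + 1) (pseudocount 1, so zero expression maps to zero). The
expression-breadth statistic τ = Σ(1 − x̂ᵢ)/(n − 1) is always computed
from raw-scale per-tissue means: the statistic's familiar behavior (τ→1
for single-tissue expression) depends on ratios of expression levels,
which a log transform would compress. An exclusion list allows dropping
redundant tissues (e.g. keeping a single brain region from a
multi-region catalog) before τ is computed.

The tissue-anchored model asks whether the tissue in which a gene shows
its maximum inter-individual expression variance (MaxTissue, with value
MaxVariance) carries information about ω — i.e. whether the variance of
ω across MaxTissue groups exceeds the variance within them. The test is
a tie-corrected Kruskal–Wallis H with an analytic chi-square p on
(#tissues − 1) degrees of freedom, plus an empirical p from a
permutation scheme that reassigns genes to tissues uniformly at random,
which preserves the per-tissue gene counts of the observed configuration
in distribution over label vectors (the counts are asserted equal in
every replicate). Empirical p-values throughout the package are the
proportion of permutations whose statistic matched or exceeded the
observed value; they may be exactly 0, and the resolution bound 1/n_perm
is always carried alongside. Each tissue's evolutionary signature is the
median ω of its anchored genes with dispersion δ = 3.14 (v₇₅ − v₂₅)/√n;
the constant is implemented literally as 3.14 (the difference from π is
below 0.06%), and percentiles use linear interpolation between order
statistics. MaxTissue ties are broken lexicographically by tissue label
so the assignment is deterministic and seed-free.

The MaxTissue/affected-organ overlap test uses the chi-square test of
independence on the full contingency table (genes whose MaxTissue label
has no counterpart in the affected-tissue vocabulary are dropped, with a
count), and additionally reports a Mantel–Haenszel common odds ratio
over the per-tissue 2×2 tables (MaxTissue = t vs not) × (affected = t vs
not). The MH construction is this package's choice of matched-odds
summary; when the discordant cells vanish the ratio is reported as
infinite with an explicit flag.

## EPRCA

The first-order partial Spearman correlation is
r = (r_DK − r_DX r_KX)/√((1 − r_DX²)(1 − r_KX²)) on the three pairwise
Spearman correlations (average ranks for ties). EPRCA forms a null for
r_{DK|X′} by applying one random row permutation per replicate jointly
to (D, X′) — their Spearman correlation is preserved exactly — and
recomputing the partial correlation against the fixed K. The empirical p
is two-sided on |r| (correlations here can take either sign), and the
adjusted coefficient is θ̂ = √(max(r² − E(M₀)², 0)), truncated at zero
where the root would be imaginary.

What this test can and cannot do deserves care. The joint-shuffle null
is an exchangeability null: it is exactly calibrated for the hypothesis
that K is independent of the (D, X′) pair, and the package's tests
confirm nominal type-I error there. It is **not** calibrated for the
subtler null "D ⊥ K given the latent X" when X is observed only through
a noisy X′: in that regime the observed partial correlation has a
nonzero mean (the spurious correlation induced by under-correction),
while the joint-shuffle null remains centered at zero, so the test
rejects. No correction computable from (D, K, X′) alone can fix this:
a trivariate Gaussian generated by a single latent factor with noisy
conditioning is observationally indistinguishable from one with a
genuine conditional dependence and less noise, so the spurious magnitude
is unidentified without external knowledge of the noise variance. The
package therefore documents EPRCA as a test of independent information
(its exchangeability null) and exposes the null mean and sd so users can
inspect the permutation distribution; the naive analytic partial-
correlation test, by contrast, is demonstrably anti-conservative under
noisy conditioning (shown in the test suite, where its rejection rate
under conditional independence exceeds 3× the nominal level).

## GLS under a known co-expression covariance

For G = π·dN + ε with var(ε) = σ²Δ and Δ known, the estimator is
π̂ = (dNᵀΔ⁻¹dN)⁻¹dNᵀΔ⁻¹G with var(π̂) = (dNᵀΔ⁻¹dN)⁻¹σ̂². The solve
whitens both vectors through a Cholesky factor of Δ (no explicit
inverse) and agrees with the explicit-inverse formula to 1e-10 relative
error; σ̂² is the whitened residual sum of squares over (n − 1). A
non-positive-definite Δ is reported with the index of the failing
leading minor. With Δ = I the fit reduces exactly to the
ordinary-least-squares slope through the origin.

## Permutation nulls for confounders

Branch-preserving nulls shuffle ω only within gene-age (branch) groups;
with a single group this is an unrestricted shuffle, and with singleton
groups it degenerates to the identity (p = 1), both verified. The
degree-preserving network null has two modes. `rewire` performs repeated
double-edge swaps (default 10× the edge count per replicate, bounded
attempts; graphs with no valid swap, such as a triangle, come back
unchanged) and preserves the exact degree sequence, asserted every
replicate. `strata` shuffles the gene attribute within log₂-spaced
degree bins. `strata` is the default because statistics that are
functions of (degree, attribute) pairs are invariant under rewiring,
which would make the test vacuous; `rewire` is intended for genuinely
topology-dependent statistics. Default replicate counts are 1000 for
EPRCA and 10000 for the branch/degree nulls.

## Boosted joint model

ω spans two to three orders of magnitude, so the joint model fits
log ω by stagewise least-squares boosting: learning rate (shrinkage)
0.01, tree depth equal to the interaction depth (1, 4 or 5; a depth-d
tree allows up to d-way interactions), 100–10000 trees, no subsampling,
single-threaded and deterministic given the seed. Tree induction is
delegated to xgboost with plain squared-error settings (no
regularization terms), and feature importance is the total
squared-error gain attributed to each feature, normalized so each
model's scores sum to 100. Categorical features (branch, MaxTissue if
included) are ordinal-encoded; missing values are routed natively by the
trees. The default feature set mirrors the cross-tissue summaries —
maximum expression level, MaxVariance, mean level, τ, network degree,
branch, imputation R² — rather than the full per-tissue expansion, to
keep the feature count well below the gene count; the per-tissue moments
remain available in the feature table for users who want the expanded
design. Out-of-sample performance is the adjusted
R² = 1 − (1 − R²)(m − 1)/(m − k − 1) on the held-out 30% of random
70/30 splits. For modeling, the feature table is built on the log2(x+1)
moment scale: raw-scale variance estimates of log-normal data have
sampling error comparable to their signal (the fourth moment diverges
quickly with the log-sd), while log-scale variances are chi-square with
69 degrees of freedom at 70 samples and carry the variability signal
almost noiselessly.

## TWAS power

The association test of imputed expression with a trait is modeled as a
1-df chi-square with non-centrality λ = N·R²·φ², where N is the GWAS
sample size, R² the expression imputation quality and φ² the fraction of
trait variance mediated by total expression; power is the
non-central-chi-square tail beyond the central critical value at α, so
R² = 0 gives power = α exactly and power is monotone in each of R², N
and φ². φ² defaults to 0.01 (a percent-level mediated effect, typical of
single-gene contributions to complex traits) and is always reported with
the result. Gene groups (conserved ω < 0.01 vs fast-evolving ω > 1) are
compared by a two-sided Mann–Whitney U.

## The synthetic generator

`simulate_dataset` draws a complete study from a three-axis latent
factor model per gene: c (expression level), u (anchor-tissue
variability) and h (tissue specificity, the normal score of the profile
peakedness κ). Per-tissue log-mean expression is a gene baseline plus
σ·c plus a profile that peaks (+κ) at a uniformly drawn anchor tissue
and is attenuated (−κ·ξ, ξ ~ U(0.3, 1)) elsewhere; samples are
log-normal around these means, giving the raw-scale mean–variance
relation, with the anchor tissue's log-sd inflated by a factor
exp(0.6 + 0.35·u) so the anchor is the realized MaxTissue for most
genes. log ω loads negatively on c and u, positively on h, receives a
per-tissue anchor shift δ_t ~ N(0, anchor_effect_sd) and independent
noise; the loading split is calibrated once against the generator's own
contract — the realized per-tissue Spearman between expression level and
ω matches `target_rho_level` within ±0.05 at 5000 genes — and frozen as
constants in `simulate.py`. Because raw-scale variance tracks the mean,
the within-tissue variance–ω coupling follows the level target through
the mean–variance relation; `target_rho_variance` is honored at the
default (equal) setting, and the independent u axis is what gives
MaxVariance its additional signal. dS is drawn log-normally and
independently of the conservation axes, treating synonymous divergence
as a mutation-rate proxy, so ω and dN carry the signal.

Defaults are the study conditions the analysis is designed around:
5000 genes, 44 tissues, 70 samples per tissue; level coupling −0.30
(within the −0.42…−0.19 range typical of mammalian multi-tissue
catalogs); τ mixture (0.25, 0.35, 0.40) across broad/intermediate/
specific classes, giving a τ spectrum with median ≈ 0.83; anchor shifts
of sd 0.15 on log ω; 60% of log-ω variance assigned to the feature-
driven signal (`explainable_variance`, mirroring the ~60% jointly
explainable variance such feature sets reach); batch effects of sd 0.25
on log expression in random half-batches per tissue; co-expression
blocks of 25 genes at ρ = 0.3; a truncated power-law degree
distribution (exponent 2.5, rank-coupled to conservation with a 30%
swap fraction, built through a configuration-model graph); 13 branch
labels with old-heavy proportions; affected tissue equal to the anchor
with probability 0.5; and imputation R² as a logistic transform of a
latent correlated 0.3 with log ω.

What the generator does **not** emulate: library-size normalization and
count-level noise (expression is drawn directly on the RPKM-like
scale), cell-type composition within tissues, dependence between dS and
expression, temporally varying (developmental-stage) expression, and
realistic network clustering beyond the degree law. Passing tests
therefore certify the statistical machinery and its calibration under
the stated couplings, not the biological conclusions one would draw
from real catalogs. The hidden-factor residualizer is likewise a plain
SVD factor model per tissue — a deliberately simple stand-in for richer
factor-analysis approaches to expression confounding — and the realized
coupling calibration holds at the default geometry; strongly different
tissue counts or τ mixtures can shift realized couplings at the edges of
the ±0.05 band.

## Numerical and interface conventions

Missing values are "NA" in every TSV, and missing is distinguished from
zero internally. Tissue labels are free strings compared exactly.
Every randomized operation takes an explicit integer seed, recorded in
run logs along with the p-value resolution of permutation tests.
Mann–Whitney comparisons use the exact distribution below 20
observations and the tie-corrected normal approximation above. Tissue
clustering of correlation profiles uses Euclidean distance with average
linkage (a fixed, deterministic choice). The pipeline driver
communicates between stages only through files, so every stage can be
run standalone on user data; a manifest records the config snapshot,
seed and SHA-256 checksums of every output, and rerunning with the same
config and seed reproduces the checksums bit for bit.
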