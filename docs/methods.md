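# Methods

## Models

**Logistic mixed model (LMM).** The binary trait is Bernoulli with logit
link; fixed effects are an intercept plus k principal-component scores
(default k = 3), and the random line effect has covariance 2 K σ_G², with K
the additive kinship matrix. The factor 2 lives in the model (the
`kinship_scale` argument), not in K, so externally supplied kinship matrices
keep their usual scale.

Fitting is penalized quasi-likelihood (PQL): given the current linear
predictor η and μ = expit(η), form the working response
z = η + (y − μ)/W with weights W = μ(1 − μ), fit the working linear mixed
model z = Xβ + b + ε with Var(b) = σ_G²·2K and Var(ε) = W⁻¹, update σ_G² by
REML of the working model, and iterate to convergence
(max|Δβ|, |Δσ_G²| < 1e−6, at most 100 cycles; non-convergence raises an
error carrying the last iterate). The REML step eigendecomposes
B = W^{1/2}(2K)W^{1/2} each cycle (n ≤ a few hundred, so this is cheap),
profiles the restricted likelihood on a log-σ grid with bounded local
refinement, and compares the optimum against the σ_G² = 0 boundary; σ_G² is
constrained ≥ 0 and boundary fits are flagged, as are fits whose
probabilities reach machine bounds (quasi-separation).

Per-marker inference is a score test using only the null fit: T = gᵀ(y − μ̂)
and V = gᵀP̂g with P̂ = Σ̂⁻¹ − Σ̂⁻¹X(XᵀΣ̂⁻¹X)⁻¹XᵀΣ̂⁻¹ and
Σ̂ = Ŵ⁻¹ + 2σ̂_G²K; T²/V is referred to χ²₁ (two-sided). At the PQL optimum
y − μ̂ = P̂z, so Xᵀ(y − μ̂) = 0 and the statistic is invariant to adding any
column-space vector of X to g, and to the allele-coding flip g → 2 − g.
Markers with V < 1e−12 are reported not-tested and excluded from λ, QQ data
and the BH test count. With σ_G² fixed at 0 the machinery reduces exactly to
logistic regression and the classical Rao score test, which is how it is
cross-checked against statsmodels in the tests.

A deliberate property of PQL worth knowing: with K = I and data containing
no random effect, σ̂_G² does not sit exactly at the boundary — the binomial
working model (dispersion fixed at 1) absorbs a little linearization error
as variance (≈ 0.01–0.04 at n = 200–400, shrinking with n). The working-model
REML itself is unbiased (on correctly specified working data it lands on the
boundary about half the time); score-test calibration is unaffected.

**Unified MLM (comparison arm).** The same design with the trait treated as
a continuous response: y = Xβ + u + e, Var(u) = 2σ_g²K, Var(e) = σ_e²I.
Binary traits are passed as raw 0/1 reals on purpose — this is the
misspecification whose consequences the diagnostics expose. Variance
components are REML estimates computed once under the null and reused for
every marker (P3D). After eigendecomposing 2K, the profiled restricted
likelihood is maximized over log δ (δ = σ_e²/σ_g²) on [−10, 10] by grid plus
bounded Brent refinement (xatol 1e−8); the σ_g² = 0 model is evaluated with
the same criterion and wins ties, so unidentifiable cases (e.g. K ∝ I, where
the likelihood is flat in δ) resolve to the parsimonious null rather than an
arbitrary interior ratio. Each marker then gets a GLS Wald t-test: trait,
covariates and marker are whitened by the fitted covariance, covariates
projected out, and the effect tested on n − p − 1 df with the residual scale
re-estimated per marker — so with σ_g² = 0 the test is *exactly* the OLS
t-test (any overall scaling of the covariance cancels).

## Diagnostics

Genomic control is λ = median(statistic)/0.4549 (the χ²₁ median). LMM score
statistics are used directly; MLM t² statistics are converted through their
p-values and the χ²₁ quantile function, which is exact under the t reference
distribution. Benjamini–Hochberg calls (via statsmodels) are reported at 5%
and 10% FDR with not-tested markers excluded from the test count. QQ data
are (−log10(i/(m+1)), −log10 p_(i)) pairs, both in descending order.

The stratified diagnostic first removes markers monomorphic within either of
the two subpopulations, then bins the rest by the ratio of expected
genotypic variance 2·MAF(1−MAF) computed within each subpopulation
(focal/other): < 0.80 → rare-in-focal, 0.80–1.25 → similar, > 1.25 →
common-in-focal. The middle bin is closed at both ends (the strict
inequalities belong to the outer bins); the focal subpopulation is the
high-prevalence one. Per-stratum λ for a misspecified model reveals the
inflation/deflation pattern that the overall λ averages away.

## Synthetic panels

The generator is the minimal model that produces the MAF-differentiation
strata the diagnostic needs: Balding–Nichols. Per marker an ancestral
frequency is drawn from Uniform(0.05, 0.5); each subpopulation draws its own
frequency from Beta(p(1−F)/F, (1−p)(1−F)/F) (p itself when F = 0) and
individuals draw Binomial(2, p_s) genotypes. Defaults: two subpopulations of
64 ("tropical") and 216 ("non-tropical") lines — the simulated-trait design
uses 216 even though the corresponding observed-data summaries describe 214
non-tropical lines; both are supported and 216 is kept as the default —
F_ST = 0.3 (chosen to make the differential-prevalence inflation pattern
robust at desk scale; the real panels' differentiation is not printed), and
5,000 markers.

Binary traits are independent Bernoulli draws with per-subpopulation
prevalence (default 0.5 tropical / 0.05 non-tropical); with no QTN they have
no genetic component, so every marker is null by construction. Optional QTN
effects act on the log-odds scale with mean-centered dosages, keeping the
stated prevalences equal to the realized trait prevalences. Quantitative
traits are additive QTN effects plus an optional structure-confounded shift
for the focal subpopulation and Gaussian noise scaled so the QTN component
explains the requested h².

The type-I-error experiment holds one panel fixed across replicates
(mirroring repeated trait simulation on a single panel; regeneration is
optional), filters monomorphic-within markers, computes PCs and kinship, and
per replicate simulates a fresh null trait (replicate r uses seed + r), runs
both GWAS models, and records per-stratum λ plus pooled empirical type-I
error at α ∈ {0.05, 0.01}. Replicate failures are tolerated up to 20%.
Aggregates report both the mean of per-replicate λ and a pooled-statistics λ.

What the simulations do *not* emulate: linkage disequilibrium (markers are
independent given subpopulation frequencies), admixed individuals, family
structure beyond the two-block covariance, genotyping error, and missing
data patterns of real GBS panels. Passing calibration here therefore shows
correctness of the statistical machinery under the assumed covariance model,
not robustness to everything real panels contain.

## Problem sizes and determinism

The calibration experiments run at 280 lines × 5,000 markers × 5 trait
replicates (≈ 25,000 pooled null tests per model), which binomial error puts
a ±0.3% band around the nominal 5% type-I rate; the power check uses 300
lines × 2,000 markers × 10 replicates with a log-odds-1.0 marker at MAF 0.3
on an undifferentiated panel (F = 0), since at F_ST = 0.3 a MAF-0.3 marker
is often strongly subpopulation-differentiated and the PCs rightly absorb
much of a planted effect — structure belongs to the calibration experiments,
not the power check. All generators take explicit seeds; identical configs
give byte-identical association tables.

## Known limitations

PQL underestimates variance components for binary GLMMs in general; here
only the score test's null behavior matters, and it is verified empirically
(KS-uniform p-values, calibrated λ and type-I error). P-values are not
saddlepoint-corrected, so extreme case-control imbalance beyond the studied
designs (prevalence ≪ 0.05 or n ≪ 100) may show small-sample miscalibration.
Kinship is VanRaden method 1 only; externally estimated kinship can be
supplied as a TSV override. No compressed-MLM clustering, multi-locus
models, dominance/GxE terms, or binomial (plot-count) traits.
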