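# Methods

`kfnet` implements two neural-network-inspired models for genetic risk
prediction, together with the file formats, simulators and evaluation
machinery needed to run them end to end.

## Kernel neural network (variance-component model)

### Model

For n individuals with genotype matrix **X** (n × p allele counts), fixed
covariates **Z** and phenotype **y**, the model is a three-level Gaussian
hierarchy:

    y | a        ~ N(Z β + a, φ I)
    a | u_1…u_m  ~ N(0, Σ_j τ_j H_j(U))
    u_1…u_m      ~ N(0, Σ_l ξ_l K_l(X))

The input kernels K_l are genotype similarity matrices — the product kernel
K = XXᵀ/p (optionally on column-standardized genotypes, which makes it the
GCTA-style genetic relationship matrix), a Gaussian kernel
exp(−‖x_i−x_j‖²/(bp)), or a polynomial kernel (XXᵀ/p + c)^d. The hidden
kernels H_j are polynomial kernels on the rows of the latent n × m matrix U:
H_ij = (u_i·u_j/m + c)^d. The 1/m scaling keeps the expected hidden kernel
stable in the hidden-layer width.

### Expected hidden kernels and the component expansion

Marginally, Var(y) = Σ_j τ_j E[H_j(U)] + φI. For polynomial hidden kernels of
degree 1 and 2 the expectation is available in closed form from Gaussian
moments (with k = Σ_l ξ_l K_l):

* degree 1: E[H]_ij = k_ij + c
* degree 2: E[H]_ij = (k_ij + c)² + (k_ii k_jj + k_ij²)/m

the latter by the fourth-moment identity E[z_a z_b z_c z_d] =
k_ab k_cd + k_ac k_bd + k_ad k_bc. Both forms are cross-checked against
Monte-Carlo means in the test suite. Degree > 2 is out of contract.

Because E[H_j] is polynomial in the ξ's, the marginal covariance is *linear*
in a set of free coefficients θ_r over an expanded basis of known matrices
V_r (`knn.expand_components`): the K_l themselves for degree 1; for degree 2,
one matrix per unordered kernel pair, K_l∘K_l' + (sym(d_l d_l'ᵀ) + K_l∘K_l')/m
with d_l = diag(K_l), plus offset cross terms and an all-ones matrix; the
identity is always appended last (its coefficient is φ). We estimate θ and
never invert back to (τ, ξ): the map is many-to-one, and prediction only
needs Σ θ_r V_r. Duplicate basis matrices arising from several hidden kernels
are merged, since their coefficients are not separately identifiable.

### Estimation: MINQUE(0) → iterative MINQUE

One MINQUE pass solves S θ = q with

    S_rs = tr(R V_r R V_s),   q_r = yᵀ R V_r R y,
    R = V_w⁻¹ − V_w⁻¹ Z (Zᵀ V_w⁻¹ Z)⁻¹ Zᵀ V_w⁻¹

under working covariance V_w. MINQUE(0) uses V_w = I and provides the
initial values; iterative MINQUE re-solves with V_w built from the previous
estimates until the maximum relative coefficient change falls below `tol`
(default 1e-4, cap 20 iterations — the iteration typically stabilizes well
inside 10). β̂ is GLS under the estimated covariance. Numerical policies:

* a singular S falls back to the pseudo-inverse with a flag;
* a singular V_w gets a ridge bump of 1e-8·tr(V_w)/n, logged;
* MINQUE is unbiased but not sign-constrained: raw (possibly negative) θ̂ are
  reported, negatives are truncated at 0 for iterative weights and for
  prediction, and φ is floored at 1e-6·var(y) to keep V_w invertible;
* a constant phenotype is flagged degenerate and returns all-zero components;
* each solve records its relative system residual (asserted ≤ 1e-8).

### Prediction

BLUP-style conditional mean for test samples:

    ŷ = Z_test β̂ + (Σ_r θ̂_r⁺ V_r^cross) (Σ_r θ̂_r⁺ V_r + φ̂ I)⁻¹ (y − Z β̂)

Cross components are obtained by expanding the stacked (test+train) kernels
and slicing the off-diagonal block, which guarantees exact consistency with
the training expansion. With a single degree-1 kernel this is algebraically
kernel ridge regression with ridge φ̂/τ̂ (asserted at machine precision in the
tests). Binary traits are fitted on the observed 0/1 scale with the same
Gaussian machinery (a linear-probability mixed model); scores are
thresholded at 0.5 by default, ties classifying positive. No
liability-threshold link is attempted.

### Batch training

`batch.split_batches` partitions samples into B near-equal batches
(deterministic in the seed; original sample order is preserved within each
batch, so B=1 reproduces the unbatched fit bit for bit).
`batch.fit_knn_batched` fits each batch independently — slicing the input
kernels, or recomputing them from genotype subsets via a caller-supplied
builder; the two paths agree exactly for the product kernel — and averages
θ̂ and β̂ without weights (sizes differ by ≤ 1, so weighting is immaterial).
Failed batches are dropped with a warning. Prediction defaults to the
averaged parameters with cross kernels against *all* training samples;
averaging per-batch predictions instead is available behind a flag.

## Functional neural network

### Representation

A candidate-gene region's p variants are mapped to [0, 1] by min-max scaling
their base-pair positions. Each sample's dosages become a curve G(t) by
penalized least squares onto an order-4 (cubic) B-spline basis with equally
spaced interior knots — basis dimension = knots + order; the penalty is the
integrated squared second derivative (Gram matrices computed exactly by
per-span Gauss-Legendre quadrature, since all integrands are piecewise
polynomials). Missing dosages are simply omitted from the residual sum: the
smoothing itself supplies the missing-data handling.

### Layers

Hidden layer d maps the incoming function x(t) to

    h(s) = α₀^(d)(s) + ∫ α^(d)(s, t) x(t) dt   (+ Zᵀw(s) at the first layer)

with α₀ on the layer's basis and α on the tensor product of adjacent bases,
so the integral is exact matrix algebra through the incoming basis Gram
matrix J. The activation (tanh by default; relu/identity selectable) is
applied pointwise on a global Gauss-Legendre grid (2 × basis dimension
nodes) and re-projected onto the layer basis by weighted least squares. The
scalar head is α₀ + ∫ α(t) x(t) dt; binary traits get a logistic link and
cross-entropy loss. Covariates enter at the first layer only.

### Loss, penalty, training

The objective is mean squared error (or mean cross-entropy) plus
λ · Σ over all parameter functions of ∫(∂²)², computed exactly from spline
Gram matrices — so affine parameter functions carry exactly zero penalty,
and λ→∞ drives all learned functions toward affine shapes. Training is
full-batch adam (lr 1e-3 default, β = 0.9/0.999) with hand-derived analytic
gradients (validated against central finite differences); a NaN loss halves
the learning rate and restarts once. One shared λ is selected from a grid by
validation *data* loss, every λ starting from the identical seed-determined
initialization, so runs are bit-reproducible given (seed, grid, epochs).

**Initialization.** Weight kernels are initialized as smooth low-rank random
surfaces, α(s,t) = Σ_jk Z_jk P_j(s) P_k(t) over the first three Legendre
polynomials projected onto the spline bases, with Z_jk ~ N(0, 1/3) from the
seed. White noise on spline coefficients would fail twice over: the basis
Gram matrix contracts integrals by ~1/dim, collapsing the across-sample
variance of every layer's output toward zero (training then plateaus at the
sample mean), and a white-noise coefficient vector is a *rough* function, so
the run starts with an enormous roughness penalty. Smooth low-rank modes
keep both the output scale and the initial penalty O(1).

**Defaults vs desk scale.** The CLI defaults mirror the genome-scale
protocol: two hidden layers with 100 and 50 interior knots ("knots" is read
as interior-knot count; basis dimension = knots + order) and 10 000 epochs.
The test suite and acceptance script run a scaled-down protocol — (8, 6)
knots, ≤ 1500 epochs, lr 2e-2, λ grid {1e-4, 1e-2}, n = 400 split
256/64/80 — chosen once as the smallest configuration at which the network
reliably learns an epistatic signal.

The functional *linear* model (y = α₀ + ⟨α, G⟩ + Zγ, closed-form penalized
least squares in `fnn.fit_flm`) serves as both a baseline and the exact
reduction oracle of a single linear-activation layer.

## Synthetic data

* `sim_genotypes`: each of two haplotypes is a latent Gaussian AR(1) chain
  across variants (lag-one correlation `ld_rho`), thresholded at the MAF
  quantile — marginal allele frequencies match the drawn MAF exactly while
  giving plausible LD and Hardy-Weinberg structure. MAFs are uniform on the
  requested range (default 0.05–0.5); positions are ~1 kb spaced with jitter.
* `sim_knn_phenotype`: an exact draw of the full three-level hierarchy
  (latent U, hidden kernel H(U), genetic effect a, noise). Its empirical
  covariance is tested against the closed-form marginal covariance for both
  hidden-kernel degrees. Note the conditional covariance of a given U is a
  random rank-m matrix, so single draws are much rougher than a Gaussian
  with the same marginal covariance.
* `sim_lmm_phenotype`: a direct Gaussian draw y ~ N(Zβ, Σ θ_r V_r) — the
  marginal law itself. This is the generator used for estimator-calibration
  studies, where the hierarchy's extra replicate-level variability would
  only inflate Monte-Carlo error.
* `sim_fnn_phenotype`: functional signals at a requested signal-to-noise
  ratio — `linear` (a smooth position-weight function applied to dosages),
  `interaction` (the product of the *centred* mean-dosage burdens of the two
  region halves — centring removes the marginal main effects so the signal
  is purely epistatic), `nonlinear` (sine of a regional burden). Default
  snr 1.0: a modest candidate-gene signal.

What the simulator does *not* emulate: realistic demography or coalescent
LD patterns, genotyping error, imputation dosages, ascertainment, or
covariate confounding. Passing tests therefore demonstrate correctness of
the estimators and algorithms under their own model assumptions, not
field performance on real cohorts.

## Evaluation

Continuous traits: MSE (population mean) and Pearson correlation
(zero-variance inputs report correlation 0 with a flag). Binary traits:
misclassification rate at the threshold (ties positive) and ROC AUC
(Mann-Whitney probability, ties counted ½; undefined with one class, flagged).

## Numerical conventions and edge cases

* Dosages count copies of the bim A1 allele (PLINK's counted allele);
  the 2-bit codes 00/10/11/01 decode to 2/1/0/missing.
* Missing genotypes are mean-imputed per variant immediately before kernel
  construction; the FNN path instead omits them from the smoothing fit.
* Phenotype missing codes: both `-9` and `NA`.
* GRM triangle: row-major i ≥ j, single precision (GCTA layout).
* Zero-variance variants are dropped (with a warning) under
  standardization.
* Kernels are not double-centred before MINQUE; standardization of the
  product kernel is the supported way to remove the allele-frequency mean
  structure.
* Sample alignment across files is always by (family ID, individual ID),
  never by row order; non-overlapping sources fail loudly.
* In ped files a monomorphic variant's only observed allele is taken as the
  major allele (A1 = "0"), matching PLINK's convention.

## Known limitations

* Recovery of the original (τ, ξ) from the expanded coefficients is out of
  scope by design.
* No standard errors or tests on variance components.
* Binary traits use the linear-probability fit; probabilities are not
  calibrated.
* The FNN is for candidate-gene regions (tens to hundreds of variants), not
  genome-wide input.
* Genome-scale cohorts (10^5+ samples) need the batched path; the dense
  n × n solves are cubic.
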