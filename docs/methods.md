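# Methods

## Model

A calibration experiment produces counts `Y` (taxa × samples) where sample
`i` is an aliquot of a known pool amplified for `x_i` PCR cycles. The
multiplicative amplification model `w_ij = a_j b_j^{x_i}` becomes linear
after a log-ratio contrast: with a (D−1)×D contrast matrix Ψ whose rows sum
to zero,

    Ψ log w_i = Ψ log a + (Ψ log b) · x_i  =  α + β x_i.

Counting noise, overdispersion and batch structure are layered on through a
multinomial logistic-normal linear model:

    Y_i ~ Multinomial(π_i),   π_i = C[exp(Ψ† η_i)],   η_i ~ N(Λ X_i, Σ),
    Λ ~ MN(Θ, Σ, Γ),          Σ ~ IW(Ξ, υ),

where C is closure (normalization to the simplex) and Ψ† is a right-inverse
of Ψ (ΨΨ† = I). Because ker(Ψ) = span(1) and closure removes the common
factor, the inverse transform does not depend on which right-inverse is
used; the package uses the padded ALR inverse and verifies agreement with
the Moore–Penrose pseudo-inverse in tests. A widely printed alternative
condition, (Ψ†)ᵀΨ = I_{D−1}, is dimensionally inconsistent for non-square
contrasts; the right-inverse convention here reproduces the intended
C[exp(·)] behavior exactly for ALR coordinates.

The design matrix X stacks per-group 0/1 intercepts, the raw PCR cycle
count, and 0/1 machine indicators (first machine = reference level, no
column). The cycle covariate is deliberately uncentered so the intercept is
the composition at cycle 0, i.e. unamplified. Machine effects are plain
indicator covariates with their own prior scale in Γ rather than a separate
hierarchical variance — the calibration designs used here have few machines
and the indicator form keeps the model fully conjugate after collapsing.

## Inference

Integrating Λ (matrix-normal) and Σ (inverse-Wishart) out analytically
leaves η with a matrix-t prior T(υ, ΘX, Ξ, I_N + XᵀΓX). Conventions are
pinned by the scalar case: with P = D−1 = 1, N = 1 the collapsed density is
Student-t with df = υ and scale² = Ξ/υ; a nested-quadrature oracle in the
test suite checks the full density against direct numerical double
integration of the mixture to ~1e-10 relative.

The collapsed posterior (multinomial log-likelihood + matrix-t log density)
is maximized over η by L-BFGS with analytic gradients, then polished with
damped Newton steps using the exact Hessian (multinomial part block-diagonal
per sample; matrix-t part a Kronecker-plus-outer-product form). Convergence
requires relative gradient norm ≤ 1e-6; the terminal Newton steps accept
gradient reduction when the objective is flat at machine precision, which
happens routinely on deep count data. Posterior draws of η come from the
Gaussian Laplace approximation at the mode (negative Hessian with 1e-8
jitter before Cholesky; failure after jitter is an error, never a silent
fallback). Λ and Σ draws follow per η draw through the exact conjugate
updates ("uncollapsing"): Σ | η ~ IW(Ξ + R(I+XᵀΓX)⁻¹Rᵀ, υ+N) and
Λ | Σ, η ~ MN(Θ_N, Σ, (Γ⁻¹+XXᵀ)⁻¹).

Point estimates of coefficients use the Rao-Blackwellized posterior mean
E[Λ|Y] = E_η[Θ_N(η)], which is free of Σ/Λ sampling noise; `BiasEstimate`
exposes it as `beta_mean`/`alpha_mean` alongside the raw draws.

The marginal likelihood is estimated by the Laplace evidence (posterior at
the MAP, multinomial normalizing constants included, plus the Gaussian
volume term). `select_scale` profiles it over a grid of σ² values for
Γ = σ²I; ties return the smallest maximizer with a warning. The evidence
carries the usual O(1/n) Laplace error — the test suite quantifies it
against importance sampling (≈0.01 nats at ~1000 reads/sample for a small
instance).

An ensemble-MCMC reference sampler (independent affine-invariant ensembles
on the collapsed posterior; split R-hat across ensembles, warning above
1.05) provides an asymptotically exact cross-check for small instances. It
is a test oracle, not the production path.

## Priors and defaults

| parameter | default | meaning |
|---|---|---|
| Θ | 0 | prior mean of coefficients (log-ratio units) |
| Γ | σ²·I_Q, σ² = 10 | coefficient scale; σ² selectable by marginal likelihood; diagonal overrides supported (e.g. larger intercept scales) |
| Ξ | Ψ I_D Ψᵀ | independence of taxa on the absolute log-abundance scale |
| υ | D + 2 | weakest proper df giving a finite IW mean Ξ/(υ−D) |
| read filter | > 1000 reads | strict inequality; samples at exactly the threshold are dropped |
| rare-taxon rule | ≥ 3 counts in ≥ 30% of samples | taxa failing it are pooled into "other"; per-sample totals conserved |
| ALR reference | last taxon | results are basis-equivariant (tested in CLR) |

All internal coordinates use natural logarithms; base-2 appears only in the
reporting of fold changes (`bias_fold_change`), where +2 means 4-fold
over-representation after the stated number of cycles. CLR-scale bias is
linear in cycle number exactly; proportion-scale (log2 fold) bias is not,
because closure renormalizes.

## Correction and evaluation

`correct_composition` subtracts x·β from the observed log-ratio coordinates
draw-wise, propagating slope uncertainty rather than plugging in a mean.
Batch terms are excluded from predictions and corrections (reference-machine
convention): machine effects are nuisance structure of the calibration run,
not part of the bias being removed. Observed compositions containing zeros
are refused — the supported route for sparse samples is to include them in
the model (their own group intercept) and read the corrected composition
off the intercept posterior, which is how the bundled mock-study evaluation
works. `reference_correction` computes a single CLR-scale correction vector
against an external reference (δ = clr(reference) − clr(posterior-mean
inferred composition)); applying it is a compositional perturbation and
therefore preserves all Aitchison distances. A draw-wise δ would propagate
reference-side uncertainty but produces a distribution of corrections
rather than one auditable vector; the single-vector form is the default.

Diagnostics: the multivariate R² is, per posterior draw, 1 minus the ratio
of squared Frobenius norms of the regression residual and the row-centered
total variation of η — the simplest multivariate extension of the familiar
decomposition computed "for each posterior sample"; it is a declared
convention, since competing definitions exist. Batch-effect norms are
per-draw Euclidean norms of each machine's coefficient vector in the fit's
log-ratio basis (basis-dependent by nature; fixed to the fit basis).
Credible intervals are equal-tailed with numpy's linear-interpolation
quantile rule, stated for bit-reproducibility.

Evaluation: alpha diversity (Shannon with natural log, Simpson, inverse
Simpson) on composition draws; the centered-ECDF statistic (posterior CDF
at the true value minus ½, so 0 = truth at the posterior median and ±0.5 =
truth outside the posterior) summarizes both accuracy and calibration in
one number; Aitchison distance to a reference composition measures bias
removal, with 0 = perfect.

## Synthetic data

The generator draws what the model assumes, plus controlled violations:

- per-taxon efficiencies log-normal around 2 with sd 0.05 log units
  (amplification is slightly less than perfect doubling, and taxa differ by
  a few percent per cycle — enough to compound into ~4-fold biases by cycle
  35);
- expected composition at cycle x is closure(a ⊙ b^x); logistic-normal
  noise (default sd 0.10 per ALR coordinate) perturbs each aliquot;
  counts are multinomial at 5·10⁴ reads/sample;
- mock communities are uniform draws from the simplex conditioned on a
  pairwise fold change ≤ 10 (exact rejection sampling from the flat
  Dirichlet, attempt-capped), matching how random lab mixtures are
  constrained by pipetting dynamic range;
- the default study bundles one calibration curve sampled at every cycle
  from 10 to 35 with ten held-out mock communities amplified 35 cycles;
- optional per-machine CLR perturbation vectors emulate batch effects;
- `simulate_from_generative` draws Σ, Λ, η, Y from the prior itself for
  coverage/self-consistency studies.

What the generator does *not* emulate: sequencing error and chimeras,
primer-mismatch bias (an early-cycle phenomenon the calibration design
cannot see), 16S copy-number variation, extraction bias, and
cycle-dependent (non-log-linear) efficiency changes such as late-cycle
saturation. Passing tests therefore demonstrate correct inference under
the stated multiplicative model, not robustness to these real-world
departures.

## Numerical choices and problem sizes

Tolerances: simplex and contrast invariants at 1e-9; round trips tested to
1e-10; optimizer relative gradient 1e-6; Hessian jitter 1e-8. Degenerate
inputs: all-zero count columns contribute only the prior (multinomial of
total 0 is constant); depth-0 simulation is allowed as a prior-predictive
edge; empty tables after read filtering warn rather than error, and the
model itself requires N ≥ 1 and D ≥ 2. All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; fits and simulations are
byte-reproducible given identical inputs and seed.

Test and acceptance runs use deliberately modest sizes — D up to 10, up to
~60 samples, 10–20 replicate seeds, MCMC cross-checks at D = 3 — chosen so
the full suite completes in minutes on one core while still exercising
every code path; the same code scales to larger tables since the dominant
costs are a (D−1)N-dimensional optimization and one Cholesky of that
dimension. Two analysis choices in the checks deserve note: the two-taxon
closed-form comparison uses a diffuse coefficient prior (σ² = 100) so that
ridge shrinkage — a real feature of the Bayesian estimate at n = 6 — does
not obscure the regression identity being verified; and the noise→0 limit
of bias mitigation is assessed on the posterior-mean corrected composition,
since the mean *distance over draws* has an irreducible floor set by
posterior spread (the IW prior keeps Σ away from zero at finite N).

## Known limitations

- The Laplace approximation is a mode-matched Gaussian in η; for very
  sparse, shallow tables its evidence and tail quantiles are approximate
  (the MCMC oracle bounds the error on small instances at <0.05 ALR units
  in posterior means).
- Group intercepts estimated from a single sequenced sample (the held-out
  communities) are shrunk toward zero by the Γ prior; with σ² = 10 this is
  a few percent and is part of the posterior's honest uncertainty.
- The calibration design cannot identify biases that are invariant along
  the cycle axis (e.g. a constant extraction bias) — those fold into the
  intercept, which is why the reference-correction step exists.
- BIOM input is not supported; count tables are TSV/CSV.
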