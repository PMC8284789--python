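# pcrbias

Measure and mitigate per-cycle PCR amplification bias in 16S rRNA amplicon
count data using calibration experiments and Bayesian multinomial
logistic-normal log-ratio linear models.

## The problem

PCR amplifies different templates with different efficiencies. If taxon *j*
starts at abundance *a<sub>j</sub>* and multiplies by a factor
*b<sub>j</sub>* per cycle, then after *x* cycles its abundance is
*a<sub>j</sub> b<sub>j</sub><sup>x</sup>*. Efficiencies near — but not
exactly — 2 compound over 25–35 cycles into several-fold distortions of the
sequenced community composition, biasing relative-abundance and
alpha-diversity estimates.

The fix implemented here needs no mock community: split one pooled DNA
sample into aliquots, amplify each for a different number of cycles,
sequence them alongside the study samples, and fit a log-ratio linear
model. On the log-ratio scale the two-template model

log(*w*<sub>1</sub>/*w*<sub>2</sub>) = log(*a*<sub>1</sub>/*a*<sub>2</sub>) + *x* · log(*b*<sub>1</sub>/*b*<sub>2</sub>)

is linear in cycle number: the **intercept** is the unamplified composition
and the **slope** is the per-cycle bias. For *D* taxa with sparse counts the
package fits the Bayesian multinomial logistic-normal generalization

- *Y<sub>i</sub>* ~ Multinomial(*π<sub>i</sub>*)
- *π<sub>i</sub>* = φ⁻¹(*η<sub>i</sub>*), the inverse log-ratio transform
- *η<sub>i</sub>* ~ N(Λ*X<sub>i</sub>*, Σ)
- Λ ~ MatrixNormal(Θ, Σ, Γ),  Σ ~ InverseWishart(Ξ, υ)

where *X<sub>i</sub>* stacks group intercepts, the PCR cycle count and
PCR-machine indicators. Inference uses the collapsed matrix-t representation
(Λ, Σ integrated out analytically), a MAP + Laplace approximation over the
latent *η* with exact gradients and Hessian, and conjugate "uncollapse"
updates for Λ and Σ — zeros are modeled directly by the multinomial; no
pseudo-counts anywhere. Study samples are then corrected by subtracting
*x* cycles of the slope posterior on the log-ratio scale.

Who it is for: microbiome researchers running 16S (or other amplicon)
surveys who can add a single calibration curve to their sequencing run, and
methodologists studying compositional measurement error.

## Worked example

```python
from pcrbias import calibration, diagnostics, simulate

study = simulate.simulate_mock_study(seed=1)          # 10 taxa, cycles 10-35
design = calibration.build_design(study.metadata, study.counts.samples)
bias = calibration.estimate_bias(study.counts, design, n_draws=500, seed=2)

r2 = diagnostics.posterior_r2(bias.fit)
print(f"posterior R^2: {r2.mean():.3f}")
fold = calibration.bias_fold_change(bias, "calibration", 35.0)
print(f"taxon_4 log2 fold after 35 cycles: {fold[:, 3].mean():+.2f}")
```

prints

```
posterior R^2: 0.903
taxon_4 log2 fold after 35 cycles: -4.18
```

meaning the log-ratio linear model explains ~90% of the compositional
variation along the simulated calibration curve, and taxon 4 (the slowest
amplifier in this simulation) ends up under-represented by a factor of
2<sup>4.18</sup> ≈ 18 after 35 cycles. `examples/` contains five narrative
scripts covering simulation, bias estimation, correction, batch-effect
detection and the two-taxon closed-form sanity check; a thin CLI
(`pcrbias simulate|fit|correct|evaluate`) wraps the same functions for
file-based workflows.

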