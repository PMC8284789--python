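"""Estimate per-cycle PCR bias from calibration samples.

Fits the Bayesian multinomial logistic-normal linear model: composition
(in additive log-ratio coordinates) regressed on PCR cycle number. The
slope posterior is the per-cycle bias; the intercept is the unamplified
composition.
"""

import numpy as np

from pcrbias import calibration, diagnostics, simulate

study = simulate.simulate_mock_study(seed=1)
design = calibration.build_design(study.metadata, study.counts.samples)
bias = calibration.estimate_bias(study.counts, design, n_draws=500, seed=2)

r2 = diagnostics.posterior_r2(bias.fit)
print(f"posterior R^2: mean {r2.mean():.3f}, 95% CS "
      f"({np.quantile(r2, 0.025):.3f}, {np.quantile(r2, 0.975):.3f})")

print("\nper-taxon log2 fold change after 35 cycles (posterior mean, 95% CI):")
fold = calibration.bias_fold_change(bias, "calibration", 35.0)
for j, taxon in enumerate(bias.taxa):
    cs = diagnostics.credible_summary(fold[:, j])
    flag = "*" if cs.excludes_zero else " "
    print(f"  {taxon:10s} {cs.mean:+.2f} ({cs.lower:+.2f}, {cs.upper:+.2f}) {flag}")
print("\n(* = credible interval excludes zero; +2 means the taxon is")
print("over-represented 4-fold after 35 cycles)")
print("recovered slope vs truth, max abs error:",
      np.round(np.max(np.abs(bias.beta_mean - study.truth['true_beta'])), 4))
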