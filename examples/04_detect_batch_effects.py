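"""Detect a misbehaving PCR machine through batch-effect norms.

Machine effects are modeled as indicator covariates; the posterior Euclidean
norm of each machine's coefficient vector flags instruments whose reactions
systematically shift composition (e.g. a mis-set annealing temperature).
"""

import numpy as np

from pcrbias import calibration, diagnostics, simulate
from pcrbias.composition import closure

D = 6
rng = np.random.default_rng(3)
shift = np.array([0.9, -0.5, 0.4, -0.6, 0.1, -0.3])  # CLR shift of machine 3
cfg = simulate.SimulationConfig(
    true_a=closure(np.full(D, 1.0 / D)),
    true_b=simulate.default_efficiencies(D, rng),
    cycles=tuple(range(10, 36, 2)),
    replicates_per_cycle=2,
    depth=50_000,
    noise_sigma=0.05,
    batch_effects={"machine1": np.zeros(D), "machine2": np.zeros(D),
                   "machine3": shift},
    seed=5,
)
table, meta, truth = simulate.simulate_calibration(cfg)
design = calibration.build_design(meta, table.samples)
bias = calibration.estimate_bias(table, design, n_draws=500, seed=6)

print("posterior mean batch-effect norm by machine (machine1 = reference):")
for name, norms in diagnostics.batch_effect_norms(bias).items():
    print(f"  {name}: {norms.mean():.3f}")
print("\nmachine3 was simulated with a compositional shift of norm "
      f"{np.linalg.norm(truth['basis'].psi @ shift):.3f} (log-ratio scale);")
print("a clearly dominating norm is grounds for excluding that machine.")
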