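"""Simulate a calibration experiment with held-out mock communities.

The bundle contains one pooled calibration sample amplified for every cycle
count from 10 to 35, plus ten random mock communities (pairwise fold change
at most 10) amplified for 35 cycles, all sharing one set of hidden per-taxon
amplification efficiencies.
"""

import numpy as np

from pcrbias import simulate

study = simulate.simulate_mock_study(seed=1)

print(f"count table: {study.counts.D} taxa x {study.counts.N} samples")
print(f"reads per sample: {study.counts.counts.sum(axis=0)[0]}")
print("true per-taxon efficiencies (2 = perfect doubling):")
print(np.round(study.truth["true_b"], 3))
print("cycle range:", study.metadata.table["cycle"].min(), "-",
      study.metadata.table["cycle"].max())
# The efficiencies scatter around 2; their *differences* are what bias the
# sequenced composition, compounding every cycle.
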