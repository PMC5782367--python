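"""Plethysmography slopes to plasma flow, plus isotopic-plateau QC.

Ten occlusion readings before and after the sampling period give leg
blood flow (the %/min volume slope equals ml/min/100 ml inflow); the
patient's hematocrit converts it to plasma flow. The steady-state QC then
checks that concentrations and enrichments were flat across the four
plateau samples.
"""

import numpy as np

from legflux import occasion_flow, steady_state_qc
from legflux.config import SimulationConfig
from legflux.synthetic import simulate_cohort

rng = np.random.default_rng(0)
pre = 4.3 * rng.lognormal(sigma=0.1, size=10)   # %/min readings
post = 4.1 * rng.lognormal(sigma=0.1, size=10)

flow = occasion_flow(pre, post, hematocrit=0.31)
print(f"phase means (pre, post): {flow.phase_means[0]:.2f}, "
      f"{flow.phase_means[1]:.2f} %/min")
print(f"blood flow : {flow.blood_flow:.2f} ml/min/100 ml leg")
print(f"plasma flow: {flow.plasma_flow:.2f} ml/min/100 ml leg "
      "(blood flow x (1 - hct))")

cohort, _ = simulate_cohort(SimulationConfig(n_patients=1), seed=3)
pid, day = cohort.occasion_keys()[0]
qc = steady_state_qc(cohort.samples_for(pid, day))
print()
print("plateau QC for one simulated occasion (flag if CV > 15%):")
print(qc.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print()
print("All CVs sit near the 2-3% measurement noise, far below the 15% "
      "threshold: the isotopic steady state assumed by the models holds.")
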