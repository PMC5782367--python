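"""Forward-simulate a cohort and recover its ground truth.

The generator inverts the kinetic algebra: it draws true synthesis,
breakdown and transport fluxes, emits the observables a study would
measure (with realistic measurement noise), and keeps the truth aside.
Running the analysis pipeline on the simulated tables then shows how
well each flux is recovered — the package's core validation loop.
"""

from legflux.config import SimulationConfig
from legflux.pipeline import analyze_cohort
from legflux.synthetic import simulate_cohort

cfg = SimulationConfig(n_patients=8)
cohort, truth = simulate_cohort(cfg, seed=42)
kinetics, aaflux = analyze_cohort(cohort)

m = kinetics.merge(truth, on=["patient_id", "icu_day"],
                   suffixes=("", "_true"))
print(f"{len(m)} occasions across {cohort.patients.shape[0]} patients\n")
print("occasion        S_true  S_est   B_true  B_est   PF_true PF_est")
for _, r in m.iterrows():
    print(f"{r.patient_id} day {r.icu_day:>2}   "
          f"{r.S:7.1f} {r.F_0M:7.1f} {r.B:7.1f} {r.F_M0:7.1f} "
          f"{r.PF_true:6.2f} {r.PF:6.2f}")

err_s = (m["F_0M"] / m["S"] - 1).abs().mean()
err_b = (m["F_M0"] / m["B"] - 1).abs().mean()
print(f"\nmean |relative error|: synthesis {err_s:.1%}, breakdown {err_b:.1%}")
print("Small enrichment-measurement errors are amplified by the (Ea - Em) "
      "and 1/Em terms, so per-occasion flux errors of ~5-10% are expected "
      "at the default CVs; with noise set to zero the recovery is exact "
      "(see the test suite).")
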