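"""Longitudinal statistics over a serially studied cohort.

Runs the full pipeline on a simulated 20-patient cohort and prints both
analyses the package offers per outcome: the random-intercept mixed model
against ICU day (all observations) and the nonparametric early (day
10-20) vs late (day 30-40) comparison after the keep-last / keep-first
selection rules.
"""

from legflux.config import Config
from legflux.pipeline import analyze_cohort, run_stats
from legflux.synthetic import simulate_cohort

cfg = Config()
cohort, _ = simulate_cohort(cfg.simulate, seed=7)
kinetics, _ = analyze_cohort(cohort, cfg)
trend, comparison = run_stats(kinetics, config=cfg)

print("mixed model: outcome, slope/day, p, zero-crossing day")
for _, r in trend.iterrows():
    zc = f"{r.zero_crossing_day:7.1f}" if abs(r.beta1) > 0.05 else "     --"
    print(f"  {r.outcome:<15} {r.beta1:+8.3f}  {r.p_slope:8.4f}  {zc}")

print("\nperiod comparison (Mann-Whitney): outcome, median early/late, p")
for _, r in comparison.iterrows():
    print(f"  {r.outcome:<15} {r.median_early:+9.2f} {r.median_late:+9.2f} "
          f"  p={r.p_value:.4f}  (n={r.n_early}/{r.n_late})")

print("\nThe default scenario builds a rising net balance crossing zero "
      "near day 35 with constant breakdown and 3-MH release: NB and "
      "total_aa_flux trend toward zero, while F_M0, Ra3 and PF stay flat.")
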