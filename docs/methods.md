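# Methods

## The measurement being modelled

A critically ill patient receives a primed continuous infusion of
[ring-²H₅]phenylalanine and [²H₃]3-methylhistidine for 150 minutes. Once
the plasma pools have reached an isotopic plateau, four paired blood
samples are drawn (135, 140, 145, 150 min) from an arterial line and a
femoral-vein catheter, a quadriceps biopsy is taken at 150 min, and leg
blood flow is measured by venous-occlusion plethysmography before and
after the sampling window. From these, the package computes leg-muscle
protein synthesis, breakdown and net balance, the 3-methylhistidine
(3-MH) release that indexes contractile-protein breakdown, and the net
flux of every plasma amino acid, all per 100 ml of leg volume. Repeating
the study every 8–12 days between ICU days 10 and 40 produces the
longitudinal data the statistics stage analyses.

## Kinetic models

All equations assume (i) an isotopic and mass steady state during the
sampling window, (ii) that phenylalanine is neither made nor oxidized in
muscle, so its only intramuscular fates are incorporation into and
release from protein, and (iii) that the four-timepoint means are the
plateau values. Enrichments are tracer-to-tracee ratios (TTR): with TTR
the tracer and tracee balances are exactly linear, which keeps every
identity below exact rather than approximate (helpers convert to and
from mole percent excess). Concentrations are plasma concentrations in
µmol/L (≡ nmol/ml) and are paired with plasma flow; no whole-blood
correction is attempted.

**Two-pool (artery/vein) model.** With arterial/venous tracee
concentrations Ca, Cv, enrichments Ea, Ev and plasma flow PF:

    NB = (Ca − Cv)·PF
    Rd = PF·(Ca·Ea − Cv·Ev)/Ea        (disappearance ≈ synthesis)
    Ra = Rd − NB                      (appearance  ≈ breakdown)

Negative NB means net release from the leg. Rd is the tracer uptake
divided by the arterial enrichment; it misses phenylalanine that is
released by proteolysis and re-incorporated into protein without ever
leaving the cell.

**Three-pool model.** The biopsy enrichment Em of the muscle free pool
resolves that blind spot. Steady-state mass balance over the
artery–muscle–vein system gives

    F_VM = PF·Cv·(Ea − Ev)/(Ea − Em)   muscle→vein transport
    F_MA = NB + F_VM                   artery→muscle transport
    F_VA = Ca·PF − F_MA                arteriovenous shunt
    F_M0 = F_MA·(Ea − Em)/Em           breakdown into the free pool
    F_0M = F_M0 + NB                   synthesis out of the free pool

Three identities hold exactly on every input and are asserted in the
tests: F_0M − F_M0 = NB, F_MA + F_M0 = F_VM + F_0M, F_VA + F_MA = Ca·PF.
A useful consequence of the tracer balance is F_0M = Rd·Ea/Em, so the
"recycling gap" F_0M − Rd = F_M0 − Ra = Rd·(Ea/Em − 1) is non-negative
exactly when Rd ≥ 0, which tracer conservation guarantees for any
physiologically realizable observable set. The strict ordering
Em < Ev < Ea (the tracer dilutes monotonically from artery to cell) is a
precondition; violations within 1e-9 are clamped (floating-point noise),
larger ones raise an error naming the violated inequality, because
silently repairing genuinely inverted gradients would hide bad data.

**3-methylhistidine.** 3-MH arises only from post-translational
methylation of histidine in actin/myosin and is neither degraded nor
re-used, so its rate of appearance is a specific contractile-breakdown
index. The same two-pool algebra is applied to the 3-MH columns; the
no-reuse biology predicts Rd3 ≈ 0, and Rd3 is reported rather than
forced to zero so that departures act as a built-in QC signal.

**Flow.** During venous occlusion the limb swells at the arterial
inflow rate, so a volume slope of x %/min equals x ml/min per 100 ml of
limb. One measurement is ten readings; the occasion's blood flow is the
unweighted mean of the pre- and post-phase means (the phases bracket the
sampling period symmetrically, and no pooling rule is physiologically
preferable), and PF = blood flow × (1 − hematocrit). No automatic
outlier rejection is applied by default — an optional symmetric
median-based trim sits behind `flow.trim` — and a linear-regression
slope fit for raw digitized traces is provided for labs that record
them.

**Amino-acid fluxes.** For amino acids without a tracer the net flux is
(Ca − Cv)·PF, negative = release. The total is summed over a
configurable panel defaulting to the 20 proteinogenic amino acids; 3-MH
is never included in totals.

## Longitudinal statistics

Each outcome gets two analyses, mirroring a serial-measurement ICU
study design:

* **Period comparison.** Observations are labelled early (ICU days
  10–20) or late (30–40); both intervals closed — the protocol wording
  does not qualify the endpoints, and closed intervals keep day-20/30/40
  observations usable. A patient studied in both periods contributes
  only the last measurement (keeping groups comparable in size); a
  patient studied twice within one period contributes the first. The
  groups are then compared with a two-sided Mann-Whitney U test: exact
  enumeration when the combined sample is ≤ 12 and untied, otherwise the
  tie-corrected normal approximation (both modes are available
  explicitly; all-tied input returns p = 1 with a degenerate flag).
* **Random-intercept model.** y_ij = β0 + β1·day_ij + b_i + ε_ij with
  b_i ~ N(0, σ_b²), ε_ij ~ N(0, σ_e²), fitted by REML through
  statsmodels' MixedLM. The slope test uses a t reference with
  df = n_obs − n_patients − 1 by default — the within-group df
  convention of nlme-style software, which simulation shows is
  calibrated for 20-patient cohorts with 1–3 occasions each (a normal
  reference is available via `stats.slope_df: normal` but is mildly
  anticonservative at these sizes).

Numerical details that matter:

* The fixed-effect covariance is the GLS form (Σᵢ Xᵢ'Vᵢ⁻¹Xᵢ)⁻¹ evaluated
  at the REML variance estimates. The Hessian-based covariance that the
  optimizer reports is indefinite when σ_b² is estimated at its zero
  boundary (common with many singleton patients); the GLS form is well
  defined there and reduces to OLS as σ_b² → 0. Boundary fits are
  flagged, not failed.
* Optimizer fallback order: default (lbfgs), then Powell, then
  Nelder-Mead; a fit is accepted only with finite estimates and positive
  residual variance, otherwise a convergence error with diagnostics.
* Exactly collinear data (a noise-free line) short-circuits to the least
  squares solution with σ_b = σ_e = 0 before the likelihood machinery,
  which cannot handle zero residual variance.
* The ±3 SD sensitivity analysis uses conditional (within-patient)
  residuals y − Xβ̂ − b̂_i, with the SD taken from the original fit's
  residuals; patients with any flagged measurement are removed and the
  model refitted, recording whether slope significance at the 5% level
  flipped. Conditional residuals are the quantity a residual-plot check
  of the fitted model actually examines; a marginal-residual variant
  would conflate patient offsets with measurement error.
* The zero-crossing day is t₀ = −β0/β1 with a first-order delta-method
  SE from the fixed-effect covariance; |β1| below 1e-12 flags the
  crossing undefined.
* Multiple outcomes are tested without multiplicity adjustment by
  default (matching common practice for exploratory serial physiology);
  Holm correction is available behind `stats.holm`.

## The synthetic cohort generator

The generator is the exact inverse of the three-pool algebra: given true
synthesis S, breakdown B, inward transport F_MA, plasma flow PF and the
arterial boundary (Ca, Ea), the noise-free observables are

    Em = Ea·F_MA/(F_MA + B)
    Cv = Ca − (S − B)/PF
    Ev = (F_VA·Ea + F_VM·Em)/(Cv·PF),  F_VA = Ca·PF − F_MA,
                                       F_VM = F_MA − (S − B)

which guarantees Em < Ev < Ea whenever the validity constraints
(F_VA > 0, F_VM > 0, S, B > 0) hold; violations raise an error naming
the constraint. 3-MH is pure dilution: Cv3 = Ca3 + Ra3/PF,
Ev3 = Ca3·Ea3/Cv3, so the true Rd3 is exactly zero.

Default study conditions (all per 100 ml leg; chosen as plausible
physiology for a catabolic ICU cohort and labelled generator defaults —
they are not values reported by any study):

| parameter | default | meaning |
|---|---|---|
| n_patients | 20 | cohort size |
| entry day | 10 + U{0..12} | first study between days 10 and 22 |
| gap | U{8..12} days | inter-study interval, censor at day 40, ≤3 occasions |
| dropout | 0.45 | chance each follow-up occasion is lost |
| NB(t) | 0.68·(t − 35) | rises from ≈ −17 at day 10 through 0 at day 35 |
| B_i | N(82.5, 8²), constant in t | per-patient breakdown (the no-change scenario) |
| F_MA | 1.0·B | inward transport ratio |
| Ca, Ea | 60 µmol/L, 0.08 | arterial phe boundary |
| Ra3_i | N(3.5, 0.5²), constant | contractile breakdown index |
| Ca3, Ea3 | 5 µmol/L, 0.05 | arterial 3-MH boundary |
| PF_i | N(3.0, 0.4²) ∈ (2.0, 4.5) | per-patient plasma flow, constant in t |
| hct_i | N(0.32, 0.04²) | hematocrit |
| noise CVs | 3% / 2% / 10% | concentration / enrichment / flow reading |

Noise is multiplicative mean-one lognormal (concentrations, enrichments
and occlusion slopes are positive), applied per timepoint per analyte
and per occlusion reading. The amino-acid panel carries fixed arterial
concentrations, a negative day-10 flux for every amino acid except
glutamate (net uptake, as leg muscle behaves), and an exponential decay
of all arteriovenous differences at 0.03/day so the efflux fades over
the stay. Phenylalanine's panel flux is not a free parameter — it *is*
the protein net balance, so it crosses zero with NB at day 35.

The staggered entry day deserves a note: with every patient first
studied on day 10, gaps of 8–12 days and realistic dropout, almost no
occasion would fall in the day 30–40 window; real cohorts accumulate
late-window measurements because patients meet inclusion criteria at
different times, and the generator reproduces that.

What the generator deliberately does not emulate: tracer equilibration
kinetics (the plateau is assumed attained; prime/infusion rates are
metadata only), informative dropout (sicker patients dying earlier),
within-occasion drift across the four timepoints, correlated
measurement errors between artery and vein, analytical batch effects,
and leg-volume change over the stay. Parameter-recovery results
therefore certify the estimators and the statistics under the stated
noise model, not robustness to those real-world failure modes.

## Validation strategy and problem sizes

* **Exact identities** on randomly drawn realizable inputs (1000 draws).
* **ODE oracle**: an independent numerical integration (LSODA,
  rtol = 1e-12) of the muscle-pool tracee/tracer ODEs with imposed
  fluxes, run to steady state over 100 random configurations; the
  algebraic estimators must reproduce the imposed fluxes to 1e-6
  relative (observed: ~1e-12).
* **Recycling dominance** over 10⁴ realizable draws.
* **Noise-free inversion**: a zero-CV cohort must return every true S,
  B, PF, Ra3 and amino-acid flux to 1e-9 relative through the full
  pipeline.
* **Noisy recovery**: 200 default-condition cohorts; the NB slope is
  recovered with < 5% bias, the 95% Wald CI covers the truth 90–99% of
  the time, and the mean zero-crossing estimate lands within ±2 days of
  the built-in day-35 crossing.
* **Calibration**: 1000 null replicates each for the mixed-model slope
  test (simulated directly from the random-intercept model over a
  cohort-shaped design) and the Mann-Whitney test at n = 10 vs 9; both
  rejection rates must sit inside the binomial 95% CI of 5%. The exact
  Mann-Whitney path is cross-checked against exhaustive enumeration.

These sizes (200 cohorts, 1000 replicates, 10⁴ draws) are the package's
chosen validation scale: large enough that the binomial CIs are
informative, small enough that the whole suite runs in a few minutes on
one core.

## Known limitations

* The ±3 SD residual rule and the slope-test df convention are
  conventions; both are configurable, and conclusions at the simulated
  effect sizes do not depend on them.
* Fluxes are per 100 ml of leg volume; muscle wasting and edema change
  the denominator over a long ICU stay, and no correction is attempted.
* The three-pool estimates are sensitive to the biopsy enrichment
  (1/Em and 1/(Ea − Em) factors): at 2% enrichment CV, per-occasion
  synthesis/breakdown errors of 5–10% are typical even though the
  cohort-level trend estimates are nearly unbiased.
* No blood-water or protein-binding correction is applied before the
  balance equations.
* The loader makes no assumption about the number of occasions per
  patient or in total.
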