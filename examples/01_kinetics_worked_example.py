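"""Two-pool vs three-pool phenylalanine kinetics on a single occasion.

Builds the per-occasion averages by hand (arterial/venous phenylalanine
concentration and enrichment, biopsy enrichment, plasma flow) and runs
both kinetic models, showing how the biopsy correction uncovers the
intracellular recycling that the two-pool model cannot see.
"""

from legflux import recycling_gap, three_pool, two_pool
from legflux.datamodel import OccasionAverages

av = OccasionAverages(
    Ca=60.0,   # arterial phe, nmol/ml
    Cv=65.0,   # venous phe — higher than arterial: the leg releases phe
    Ea=0.08,   # arterial tracer-to-tracee ratio
    Ev=0.06,   # venous TTR, diluted by unlabeled phe from breakdown
    Em=0.04,   # muscle free-pool TTR from the biopsy
    Ca3=5.0, Cv3=6.0, Ea3=0.05, Ev3=0.04,  # 3-methylhistidine analogues
    PF=3.0,    # plasma flow, ml/min/100 ml leg
)

two = two_pool(av)
three = three_pool(av)
gap = recycling_gap(two, three)

print(f"net balance NB          : {two.NB:8.2f} nmol/min/100 ml (negative = release)")
print(f"two-pool   Rd (synthesis): {two.Rd:8.2f}   Ra (breakdown): {two.Ra:8.2f}")
print(f"three-pool F_0M (synth.) : {three.F_0M:8.2f}   F_M0 (breakd.): {three.F_M0:8.2f}")
print(f"transports F_MA/F_VM/F_VA: {three.F_MA:.1f} / {three.F_VM:.1f} / {three.F_VA:.1f}")
print(f"recycling gap            : {gap[0]:8.2f} nmol/min/100 ml")
print()
print("The leg loses 15 nmol phe/min/100 ml. The biopsy-corrected model "
      "shows synthesis 67.5 and breakdown 82.5; the two-pool model "
      "underestimates both by the 33.75 recycled within the cell.")
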