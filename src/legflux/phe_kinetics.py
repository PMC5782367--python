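"""Two-pool and three-pool phenylalanine kinetics across the leg.

Phenylalanine is neither synthesized nor degraded in muscle, so its only
fates in the leg are incorporation into protein (synthesis) and release
from protein (breakdown). With arterial (A), venous (V) and muscle
intracellular (M) pools at isotopic steady state, the per-occasion means
give, per 100 ml of leg volume:

Two-pool (A/V balance only)::

    NB = (Ca - Cv) * PF                  net balance (negative = release)
    Rd = PF * (Ca*Ea - Cv*Ev) / Ea       disappearance ~ synthesis
    Ra = Rd - NB                         appearance  ~ breakdown

Two-pool rates miss phenylalanine recycled from breakdown directly into
new protein inside the cell. The three-pool model uses the biopsy
enrichment Em to resolve the intracellular pool:

    F_VM = PF * Cv * (Ea - Ev) / (Ea - Em)    muscle -> vein transport
    F_MA = NB + F_VM                          artery -> muscle transport
    F_VA = Ca*PF - F_MA                       arteriovenous shunt
    F_M0 = F_MA * (Ea - Em) / Em              breakdown (into free pool)
    F_0M = F_M0 + NB                          synthesis (out of free pool)

The mass-balance identities NB = F_0M - F_M0, F_MA + F_M0 = F_VM + F_0M
and F_VA + F_MA = Ca*PF hold exactly by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .config import KineticsConfig
from .datamodel import OccasionAverages
from .errors import DegenerateEnrichmentError, OrderingError, ValidationError


@dataclass(frozen=True)
class TwoPoolResult:
    NB: float   # net balance, nmol/min/100 ml leg
    Rd: float   # rate of disappearance (synthesis estimate)
    Ra: float   # rate of appearance (breakdown estimate)
    inverted_gradient: bool = False  # Ev > Ea beyond tolerance


@dataclass(frozen=True)
class ThreePoolResult:
    F_MA: float  # inward transmembrane transport
    F_VM: float  # outward transmembrane transport
    F_VA: float  # arteriovenous shunt
    F_M0: float  # intracellular appearance from proteolysis (breakdown)
    F_0M: float  # intracellular disappearance to synthesis
    NB: float
    inconsistent_transport: bool = False  # F_VA < 0


def net_balance(Ca: float, Cv: float, PF: float) -> float:
    """(Ca - Cv) * PF; negative values mean net release from the leg."""
    if PF <= 0:
        raise ValidationError(f"plasma flow must be > 0, got {PF}")
    if Ca < 0 or Cv < 0:
        raise ValidationError("concentrations must be >= 0")
    return (Ca - Cv) * PF


def two_pool(av: OccasionAverages) -> TwoPoolResult:
    """A/V-balance phenylalanine kinetics; blind to intracellular recycling."""
    return _two_pool(av.Ca, av.Cv, av.Ea, av.Ev, av.PF)


def _two_pool(Ca: float, Cv: float, Ea: float, Ev: float,
              PF: float) -> TwoPoolResult:
    if Ea <= 0:
        raise DegenerateEnrichmentError(
            f"arterial enrichment must be > 0, got Ea={Ea}")
    NB = net_balance(Ca, Cv, PF)
    inverted = Ev > Ea
    if inverted:
        # measurement noise can invert the gradient; report, don't hide
        warnings.warn(
            f"venous enrichment Ev={Ev} exceeds arterial Ea={Ea}: "
            "physiologically inverted gradient, results flagged", stacklevel=3)
    Rd = PF * (Ca * Ea - Cv * Ev) / Ea
    return TwoPoolResult(NB=NB, Rd=Rd, Ra=Rd - NB, inverted_gradient=inverted)


def three_pool(av: OccasionAverages,
               config: KineticsConfig | None = None) -> ThreePoolResult:
    """Biopsy-corrected kinetics resolving transport, synthesis, breakdown.

    Requires the strict enrichment ordering Em < Ev < Ea (tracer dilutes
    monotonically from artery to muscle). Violations within the configured
    tolerance are clamped; larger ones raise :class:`OrderingError`.
    """
    cfg = config or KineticsConfig()
    if av.Em is None:
        raise DegenerateEnrichmentError(
            "three-pool model needs a biopsy enrichment (Em); none available")
    Ea, Ev, Em, tol = av.Ea, av.Ev, av.Em, cfg.ordering_tolerance
    if Em <= 0:
        raise DegenerateEnrichmentError(
            f"muscle enrichment must be > 0, got Em={Em}")
    if Ev - Ea > tol:
        raise OrderingError(f"enrichment ordering violated: Ev={Ev} > Ea={Ea}")
    if Em - Ev > tol:
        raise OrderingError(f"enrichment ordering violated: Em={Em} > Ev={Ev}")
    Ev = min(Ev, Ea)
    Em = min(Em, Ev)
    if Ea == Em:
        raise DegenerateEnrichmentError(
            f"Ea == Em == {Ea}: no arteriovenous tracer dilution to resolve")

    NB = net_balance(av.Ca, av.Cv, av.PF)
    F_VM = av.PF * av.Cv * (Ea - Ev) / (Ea - Em)
    F_MA = NB + F_VM
    F_VA = av.Ca * av.PF - F_MA
    F_M0 = F_MA * (Ea - Em) / Em
    F_0M = F_M0 + NB
    return ThreePoolResult(F_MA=F_MA, F_VM=F_VM, F_VA=F_VA,
                           F_M0=F_M0, F_0M=F_0M, NB=NB,
                           inconsistent_transport=F_VA < 0)


def recycling_gap(two: TwoPoolResult,
                  three: ThreePoolResult) -> tuple[float, float]:
    """Intracellular recycling missed by the two-pool model.

    Returns (F_0M - Rd, F_M0 - Ra). Both components are equal (the models
    share the same NB) and non-negative whenever Em < Ev < Ea.
    """
    return (three.F_0M - two.Rd, three.F_M0 - two.Ra)
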