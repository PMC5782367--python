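"""3-Methylhistidine dilution kinetics: contractile-protein breakdown.

3-Methylhistidine (3-MH) arises only by post-translational methylation of
histidine residues in actin and myosin, and humans can neither degrade nor
re-incorporate it. Its rate of appearance across the leg is therefore a
specific index of myofibrillar protein breakdown, and its rate of
disappearance should be ~0 — a built-in sanity check, which is why Rd3 is
reported rather than forced to zero.

The algebra is the phenylalanine two-pool model applied to the 3-MH
concentration and enrichment columns; an isotopic label is used purely for
sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datamodel import OccasionAverages
from .phe_kinetics import _two_pool


@dataclass(frozen=True)
class Mh3Result:
    NB3: float  # 3-MH net balance, nmol/min/100 ml leg
    Rd3: float  # rate of disappearance (expected ~0: no reutilization)
    Ra3: float  # rate of appearance = contractile-protein breakdown index
    inverted_gradient: bool = False


def mh3_two_pool(av: OccasionAverages) -> Mh3Result:
    """Two-pool tracer-dilution kinetics on the 3-MH averages."""
    r = _two_pool(av.Ca3, av.Cv3, av.Ea3, av.Ev3, av.PF)
    return Mh3Result(NB3=r.NB, Rd3=r.Rd, Ra3=r.Ra,
                     inverted_gradient=r.inverted_gradient)
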