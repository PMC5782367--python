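"""Per-amino-acid net fluxes across the leg.

For amino acids other than phenylalanine and 3-methylhistidine no tracer is
needed: the net flux is the arteriovenous concentration difference times
plasma flow,

    flux_aa = (Ca_aa - Cv_aa) * PF     [nmol/min/100 ml leg]

with the sign convention that a negative flux is a net release from muscle
tissue and a positive flux a net uptake. The total free amino-acid flux is
the sum over a configured panel (default: the 20 proteinogenic amino
acids; 3-methylhistidine is never part of the total).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .config import PROTEINOGENIC
from .errors import ConfigError, ValidationError


@dataclass
class AAFluxResult:
    flux: dict[str, float]            # amino acid -> nmol/min/100 ml
    total_flux: float                 # sum over the panel members present
    arterial_conc: dict[str, float]   # amino acid -> umol/L
    total_arterial: float
    missing: tuple[str, ...] = field(default=())


def aa_fluxes(aa_arterial: Mapping[str, float],
              aa_venous: Mapping[str, float],
              PF: float,
              panel: Iterable[str] = PROTEINOGENIC) -> AAFluxResult:
    """Net flux per panel amino acid plus panel totals.

    Panel members absent from the input are excluded from the totals with
    a warning (they stay out of ``flux`` as well, listed in ``missing``).
    """
    panel = tuple(panel)
    if not panel:
        raise ConfigError("amino-acid panel is empty")
    if PF <= 0:
        raise ValidationError(f"plasma flow must be > 0, got {PF}")
    flux: dict[str, float] = {}
    conc: dict[str, float] = {}
    missing = []
    for aa in panel:
        if aa not in aa_arterial or aa not in aa_venous:
            missing.append(aa)
            continue
        flux[aa] = (aa_arterial[aa] - aa_venous[aa]) * PF
        conc[aa] = float(aa_arterial[aa])
    if missing:
        warnings.warn(
            f"amino acids missing from occasion, excluded from totals: "
            f"{missing}", stacklevel=2)
    return AAFluxResult(
        flux=flux,
        total_flux=sum(flux.values()),
        arterial_conc=conc,
        total_arterial=sum(conc.values()),
        missing=tuple(missing),
    )
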