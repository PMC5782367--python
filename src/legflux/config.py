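"""Configuration for the analysis pipeline and the cohort simulator.

Configuration is a tree of frozen-by-convention dataclasses mirroring the
sections of the YAML config file::

    units:    enrichment scale and conversion conventions
    qc:       steady-state coefficient-of-variation thresholds
    flow:     plethysmography handling (minimum readings, optional trim)
    kinetics: enrichment-ordering tolerance for the three-pool model
    stats:    Mann-Whitney mode, slope-test reference distribution, alpha
    simulate: the synthetic-cohort generator (see SimulationConfig)

``load_config`` reads a YAML file in which any subset of keys may be given;
unspecified keys keep their defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError

#: Minutes at which arterial/venous samples are drawn during the primed
#: continuous infusion (isotopic plateau window).
SAMPLE_MINUTES = (135, 140, 145, 150)

#: The 20 proteinogenic amino acids, standard lowercase 3-letter codes.
PROTEINOGENIC = (
    "ala", "arg", "asn", "asp", "cys", "gln", "glu", "gly", "his", "ile",
    "leu", "lys", "met", "phe", "pro", "ser", "thr", "trp", "tyr", "val",
)


@dataclass
class UnitsConfig:
    # tracer-to-tracee ratio; "mpe" inputs are converted on load
    enrichment_scale: str = "ttr"


@dataclass
class QCConfig:
    cv_threshold: float = 0.15     # flag analytes whose plateau CV exceeds this
    min_timepoints: int = 4        # full plateau required per site by default
    allow_partial: bool = False    # if True, average >=2 timepoints with a warning


@dataclass
class FlowConfig:
    min_readings: int = 5          # per occlusion phase (protocol takes 10)
    trim: bool = False             # optional median-based trimming of readings
    trim_fraction: float = 0.1
    regression_window_s: float = 4.0  # initial window for raw-trace slope fits


@dataclass
class KineticsConfig:
    ordering_tolerance: float = 1e-9  # Em<Ev<Ea violations below this are clamped


@dataclass
class StatsConfig:
    exact_mw_max_n: int = 12       # exact Mann-Whitney when combined n <= this
    slope_df: str = "within"       # "within": t with df = n_obs-n_patients-1; "normal": z
    alpha: float = 0.05
    holm: bool = False             # optional multiplicity correction across outcomes
    outlier_sd: float = 3.0        # sensitivity-refit residual cutoff (in SD)


@dataclass
class AAPanelConfig:
    """Per-amino-acid truth for the simulator: arterial concentration
    (umol/L) and day-10 net flux (nmol/min/100 ml leg; negative = release).

    Phenylalanine's flux is tied to the protein net balance trajectory and is
    therefore not listed here. Glutamate is the one amino acid taken up by
    the leg.
    """

    arterial: dict[str, float] = field(default_factory=lambda: {
        "ala": 250.0, "arg": 80.0, "asn": 50.0, "asp": 10.0, "cys": 50.0,
        "gln": 450.0, "glu": 80.0, "gly": 220.0, "his": 80.0, "ile": 60.0,
        "leu": 120.0, "lys": 180.0, "met": 25.0, "phe": 60.0, "pro": 170.0,
        "ser": 110.0, "thr": 130.0, "trp": 50.0, "tyr": 60.0, "val": 220.0,
    })
    flux_day10: dict[str, float] = field(default_factory=lambda: {
        "ala": -55.0, "arg": -12.0, "asn": -9.0, "asp": -2.0, "cys": -4.0,
        "gln": -60.0, "glu": 25.0, "gly": -28.0, "his": -8.0, "ile": -10.0,
        "leu": -18.0, "lys": -22.0, "met": -5.0, "pro": -16.0,
        "ser": -14.0, "thr": -13.0, "trp": -4.0, "tyr": -9.0, "val": -20.0,
    })
    efflux_decay_per_day: float = 0.03  # exponential shrinkage of |A-V| with ICU day


@dataclass
class SimulationConfig:
    """Ground-truth scenario for the forward simulator.

    The default scenario: net balance NB(t) = eta1 * (t - t_cross) rises
    linearly through zero at ``t_cross`` (day 35) from about -17 at day 10,
    while protein breakdown stays constant per patient — synthesis carries
    the whole trend. 3-methylhistidine release is constant. Noise is
    multiplicative lognormal with the listed CVs.
    """

    n_patients: int = 20
    first_day: int = 10
    # patients meet inclusion criteria at different days: first study day is
    # drawn uniformly from first_day .. first_day + entry_jitter_days, which
    # populates the late (day 30-40) window the way a real cohort does
    entry_jitter_days: int = 12
    gap_min: int = 8               # inter-study interval drawn uniformly
    gap_max: int = 12
    censor_day: int = 40
    dropout_prob: float = 0.45     # chance each follow-up occasion is missed

    # phenylalanine truth
    mu_breakdown: float = 82.5     # nmol/min/100 ml; per-patient mean (mu_B)
    tau_breakdown: float = 8.0     # between-patient SD of breakdown (tau_B)
    breakdown_slope: float = 0.0   # per-day drift of breakdown (default: constant)
    eta1: float = 0.68             # NB slope, nmol/min/100 ml per day (> 0)
    t_cross: float = 35.0          # day at which mean NB crosses zero
    transport_ratio: float = 1.0   # r = F_MA / B (inward transport vs breakdown)
    arterial_phe: float = 60.0     # umol/L
    arterial_phe_ttr: float = 0.08

    # 3-methylhistidine truth
    mu_ra3: float = 3.5            # nmol/min/100 ml contractile breakdown marker
    tau_ra3: float = 0.5
    arterial_mh3: float = 5.0      # umol/L
    arterial_mh3_ttr: float = 0.05

    # plasma flow / hematocrit
    mu_plasma_flow: float = 3.0    # ml/min/100 ml leg
    tau_plasma_flow: float = 0.4
    plasma_flow_bounds: tuple[float, float] = (2.0, 4.5)
    mu_hct: float = 0.32
    tau_hct: float = 0.04
    hct_bounds: tuple[float, float] = (0.18, 0.50)

    # noise coefficients of variation (multiplicative lognormal)
    cv_conc: float = 0.03
    cv_enrich: float = 0.02
    cv_flow_reading: float = 0.10

    aa: AAPanelConfig = field(default_factory=AAPanelConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if not (0 < self.gap_min <= self.gap_max):
            raise ConfigError("require 0 < gap_min <= gap_max")
        for name in ("cv_conc", "cv_enrich", "cv_flow_reading"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.eta1 <= 0:
            raise ConfigError("eta1 must be > 0 (net balance rises over time)")
        if self.transport_ratio <= 0:
            raise ConfigError("transport_ratio must be > 0")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ConfigError("dropout_prob must lie in [0, 1]")
        lo, hi = self.hct_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ConfigError("hct_bounds must lie strictly inside (0, 1)")


@dataclass
class Config:
    units: UnitsConfig = field(default_factory=UnitsConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    flow: FlowConfig = field(default_factory=FlowConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    aa_panel: tuple[str, ...] = PROTEINOGENIC  # panel used for total AA flux


def _update_dataclass(obj: Any, data: dict[str, Any], path: str) -> Any:
    if not isinstance(data, dict):
        raise ConfigError(f"section '{path}' must be a mapping")
    names = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in names:
            raise ConfigError(f"unknown config key '{path}.{key}'")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current):
            _update_dataclass(current, value, f"{path}.{key}")
        elif isinstance(current, dict):
            current.update(value)
        elif isinstance(current, tuple) and isinstance(value, (list, tuple)):
            setattr(obj, key, tuple(value))
        else:
            setattr(obj, key, value)
    return obj


def load_config(path: str | Path | None = None) -> Config:
    """Build a :class:`Config`, overlaying a YAML file if given."""
    cfg = Config()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping at top level")
        for key, value in data.items():
            if key == "aa_panel":
                cfg.aa_panel = tuple(value)
            elif hasattr(cfg, key):
                _update_dataclass(getattr(cfg, key), value, key)
            else:
                raise ConfigError(f"unknown config section '{key}'")
    cfg.simulate.validate()
    return cfg


def dump_config(cfg: Config, path: str | Path) -> None:
    """Echo the effective configuration to YAML (pipeline provenance)."""
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)
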