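import numpy as np
import pandas as pd
import pytest

from legflux.config import Config, SimulationConfig
from legflux.datamodel import OccasionAverages


@pytest.fixture
def worked_averages() -> OccasionAverages:
    """The hand-worked occasion: Ca=60, Cv=65, PF=3, Ea=0.08, Ev=0.06,
    Em=0.04 (phe) and Ca3=5, Cv3=6, Ea3=0.05, Ev3=0.04 (3-MH)."""
    return OccasionAverages(Ca=60.0, Cv=65.0, Ea=0.08, Ev=0.06, Em=0.04,
                            Ca3=5.0, Cv3=6.0, Ea3=0.05, Ev3=0.04, PF=3.0)


@pytest.fixture
def default_cfg() -> Config:
    return Config()


@pytest.fixture
def small_sim_cfg() -> SimulationConfig:
    return SimulationConfig(n_patients=6)


def occasion_samples(Ca=60.0, Cv=65.0, Ea=0.08, Ev=0.06,
                     Ca3=5.0, Cv3=6.0, Ea3=0.05, Ev3=0.04,
                     aa=None, jitter=None) -> pd.DataFrame:
    """Build a full 8-row (4 timepoints x 2 sites) samples table for one
    occasion; optional per-timepoint additive jitter on the phe column."""
    rows = []
    for k, minute in enumerate((135, 140, 145, 150)):
        for site in ("artery", "vein"):
            arterial = site == "artery"
            dj = jitter[k] if jitter is not None else 0.0
            row = {"patient_id": "P001", "icu_day": 10, "minute": minute,
                   "site": site,
                   "phe": (Ca if arterial else Cv) + dj,
                   "phe_ttr": Ea if arterial else Ev,
                   "mh3": Ca3 if arterial else Cv3,
                   "mh3_ttr": Ea3 if arterial else Ev3}
            for name, (a, v) in (aa or {}).items():
                row[name] = a if arterial else v
            rows.append(row)
    return pd.DataFrame(rows)


def selection_fixture() -> pd.DataFrame:
    """A 20-patient, 31-observation study layout satisfying the protocol:
    10 patients studied once, 9 twice, 1 thrice; inter-study gaps 8-12
    days; exactly one patient studied in both periods and exactly two
    patients studied twice within a single period. The keep-last /
    keep-first rules must reduce it to groups of (10, 9)."""
    layout = {
        "P01": [20, 30],        # both periods -> keep day 30 (last)
        "P02": [11, 19],        # twice in early -> keep day 11 (first)
        "P03": [31, 39],        # twice in late  -> keep day 31 (first)
        "P04": [13, 21, 29],    # thrice -> only day 13 falls in a period
        "P05": [14, 24], "P06": [15, 26], "P07": [16, 27],
        "P08": [21, 31], "P09": [22, 33], "P10": [23, 34],
        # singletons
        "P11": [10], "P12": [12], "P13": [15], "P14": [18], "P15": [20],
        "P16": [30], "P17": [35], "P18": [38], "P19": [40], "P20": [25],
    }
    rows = [{"patient_id": pid, "icu_day": d}
            for pid, days in layout.items() for d in days]
    return pd.DataFrame(rows)


def random_valid_averages(rng: np.random.Generator) -> OccasionAverages:
    """Draw physiologically realizable averages with Em < Ev < Ea.

    Realizable means producible by some steady-state flux configuration:
    the draw goes through the forward model, which also enforces tracer
    conservation across the leg (Cv*Ev <= Ca*Ea)."""
    from legflux.synthetic import forward_mh3, forward_occasion

    while True:
        PF = rng.uniform(1.5, 5.0)
        Ca = rng.uniform(40, 90)
        Ea = rng.uniform(0.04, 0.12)
        B = rng.uniform(40, 120)
        S = B + rng.uniform(-25, 10)
        F_MA = rng.uniform(0.4, 1.6) * B
        if S <= 0 or F_MA >= Ca * PF or F_MA - (S - B) <= 0:
            continue
        Cv, Ev, Em = forward_occasion(S, B, F_MA, PF, Ca, Ea)
        Ca3, Ea3 = rng.uniform(2, 10), rng.uniform(0.02, 0.08)
        Cv3, Ev3 = forward_mh3(rng.uniform(0, 6), PF, Ca3, Ea3)
        return OccasionAverages(Ca=Ca, Cv=Cv, Ea=Ea, Ev=Ev, Em=Em,
                                Ca3=Ca3, Cv3=Cv3, Ea3=Ea3, Ev3=Ev3, PF=PF)
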