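"""Venous-occlusion plethysmography: slopes to leg blood and plasma flow.

During a brief venous occlusion, arterial inflow continues while venous
outflow is blocked, so the limb swells at a rate equal to the blood inflow.
A volume slope of x % per minute is therefore numerically x ml of blood per
minute per 100 ml of limb — the standard plethysmographic identity. Plasma
flow follows from the patient's hematocrit:

    PF = blood_flow * (1 - hct)

One flow measurement comprises ten occlusion readings; a measurement is
taken before and immediately after the blood-sampling period and the two
phase means are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import FlowConfig
from .errors import InsufficientDataError, InvalidReadingError, ValidationError


@dataclass(frozen=True)
class FlowResult:
    blood_flow: float    # ml blood / min / 100 ml leg
    plasma_flow: float   # ml plasma / min / 100 ml leg (PF)
    n_readings_used: int
    phase_means: tuple[float, float]  # (pre, post)


def slope_to_flow(slope: float) -> float:
    """Relabel a %/min limb-volume slope as ml/min/100 ml blood flow.

    The magnitude is unchanged; only the units change. Negative slopes
    cannot arise from a valid occlusion (the limb swells) and are rejected.
    """
    if not np.isfinite(slope):
        raise InvalidReadingError(f"non-finite plethysmography slope: {slope}")
    if slope < 0:
        raise InvalidReadingError(
            f"negative plethysmography slope {slope} %/min is not a valid "
            "occlusion reading")
    return float(slope)


def _phase_mean(slopes, phase: str, cfg: FlowConfig) -> tuple[float, int]:
    x = np.asarray(slopes, dtype=float)
    if x.size < cfg.min_readings:
        raise InsufficientDataError(
            f"phase '{phase}' has {x.size} readings; at least "
            f"{cfg.min_readings} required")
    for s in x:
        slope_to_flow(float(s))
    if cfg.trim and x.size >= 3:
        # symmetric trim around the median, robust to single bad readings
        k = int(np.floor(cfg.trim_fraction * x.size))
        if k > 0:
            x = np.sort(x)[k:x.size - k]
    return float(x.mean()), int(x.size)


def occasion_flow(pleth_pre, pleth_post, hematocrit: float,
                  config: FlowConfig | None = None) -> FlowResult:
    """Blood and plasma flow for one occasion from its two occlusion phases.

    blood_flow = mean(mean(pre), mean(post)); PF = blood_flow * (1 - hct).
    The two phases bracket the sampling period symmetrically, hence the
    unweighted average of phase means (not a pooled 20-reading mean).
    """
    cfg = config or FlowConfig()
    # hct = 0 is admitted here as the plasma==blood limit (the loader holds
    # recorded hematocrits to the open interval)
    if not (0 <= hematocrit < 1):
        raise ValidationError(
            f"hematocrit {hematocrit} outside [0, 1)")
    pre_mean, n_pre = _phase_mean(pleth_pre, "pre", cfg)
    post_mean, n_post = _phase_mean(pleth_post, "post", cfg)
    blood = 0.5 * (pre_mean + post_mean)
    return FlowResult(
        blood_flow=blood,
        plasma_flow=blood * (1.0 - hematocrit),
        n_readings_used=n_pre + n_post,
        phase_means=(pre_mean, post_mean),
    )


def slope_from_trace(time_s, volume_pct, window_s: float = 4.0) -> float:
    """Fit the initial slope of a digitized volume-vs-time occlusion trace.

    Ordinary least squares on the first ``window_s`` seconds, returned in
    % per minute. Provided for labs that record raw traces; the default
    pipeline input is pre-computed slopes.
    """
    t = np.asarray(time_s, dtype=float)
    v = np.asarray(volume_pct, dtype=float)
    mask = t <= t[0] + window_s
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"fewer than 2 trace points inside the {window_s}s fitting window")
    slope_per_s = np.polyfit(t[mask], v[mask], 1)[0]
    return slope_to_flow(slope_per_s * 60.0)
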