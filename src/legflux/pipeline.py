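"""Pipeline orchestration: simulate/load -> flow -> kinetics -> flux -> stats.

``analyze_cohort`` turns a validated cohort into per-occasion kinetics and
amino-acid flux tables; ``run_stats`` applies the longitudinal statistics
to the outcome columns; ``run_pipeline`` wires the stages together with
logging and CSV reports. Occasions that cannot support a stage (missing
biopsy, inverted enrichment gradient) yield NaN for that stage's columns
plus a flag rather than failing the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aa_flux import aa_fluxes
from .cohort_stats import (
    compare_periods,
    fit_random_intercept,
    sensitivity_refit,
    zero_crossing_day,
)
from .config import Config
from .datamodel import Cohort, average_occasion, load_cohort, steady_state_qc
from .errors import DegenerateEnrichmentError, LegfluxError, OrderingError
from .flow import occasion_flow
from .mh3_kinetics import mh3_two_pool
from .phe_kinetics import three_pool, two_pool
from .synthetic import simulate_cohort


#: outcome columns the statistics stage runs over by default
DEFAULT_OUTCOMES = ("NB", "Rd", "Ra", "F_0M", "F_M0", "PF", "Ra3",
                    "total_aa_flux", "total_arterial")

THREE_POOL_COLS = ("F_MA", "F_VM", "F_VA", "F_M0", "F_0M")


def analyze_cohort(cohort: Cohort, config: Config | None = None,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-occasion kinetics and amino-acid fluxes for a whole cohort.

    Returns ``(kinetics, aaflux)``: kinetics has one row per occasion with
    flow, two-pool, three-pool and 3-MH results plus QC flags; aaflux is
    long-format with one row per occasion x amino acid and a ``total`` row
    per occasion.
    """
    cfg = config or Config()
    kin_rows, aa_rows = [], []
    for pid, day in cohort.occasion_keys():
        samples = cohort.samples_for(pid, day)
        flow = occasion_flow(
            cohort.pleth_slopes_for(pid, day, "pre"),
            cohort.pleth_slopes_for(pid, day, "post"),
            cohort.hematocrit_for(pid, day), cfg.flow)
        av = average_occasion(samples, cohort.biopsy_ttr_for(pid, day),
                              flow.plasma_flow, cfg)
        qc = steady_state_qc(samples, cfg.qc.cv_threshold)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            two = two_pool(av)
            mh3 = mh3_two_pool(av)
        row = {
            "patient_id": pid, "icu_day": day,
            "PF": flow.plasma_flow, "blood_flow": flow.blood_flow,
            "NB": two.NB, "Rd": two.Rd, "Ra": two.Ra,
            "NB3": mh3.NB3, "Rd3": mh3.Rd3, "Ra3": mh3.Ra3,
            "qc_flag": bool(qc["flag"].any()),
            "inverted_gradient": two.inverted_gradient,
        }
        for c in THREE_POOL_COLS:
            row[c] = np.nan
        row["three_pool_flag"] = ""
        if av.Em is None:
            row["three_pool_flag"] = "no-biopsy"
        else:
            try:
                three = three_pool(av, cfg.kinetics)
                for c in THREE_POOL_COLS:
                    row[c] = getattr(three, c)
                if three.inconsistent_transport:
                    row["three_pool_flag"] = "inconsistent-transport"
            except (OrderingError, DegenerateEnrichmentError) as exc:
                row["three_pool_flag"] = f"failed: {exc}"

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            aar = aa_fluxes(av.aa_arterial, av.aa_venous, av.PF, cfg.aa_panel)
        row["total_aa_flux"] = aar.total_flux
        row["total_arterial"] = aar.total_arterial
        kin_rows.append(row)
        for aa in aar.flux:
            aa_rows.append({"patient_id": pid, "icu_day": day,
                            "amino_acid": aa, "flux": aar.flux[aa],
                            "arterial_conc": aar.arterial_conc[aa]})
        aa_rows.append({"patient_id": pid, "icu_day": day,
                        "amino_acid": "total", "flux": aar.total_flux,
                        "arterial_conc": aar.total_arterial})
    return pd.DataFrame(kin_rows), pd.DataFrame(aa_rows)


def aaflux_wide(aaflux: pd.DataFrame) -> pd.DataFrame:
    """Wide export of the long aaflux table (one column per amino acid)."""
    return aaflux.pivot(index=["patient_id", "icu_day"],
                        columns="amino_acid", values="flux").reset_index()


def run_stats(kinetics: pd.DataFrame,
              outcomes=DEFAULT_OUTCOMES,
              config: Config | None = None,
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mixed-model and period-comparison reports over outcome columns."""
    cfg = config or Config()
    trend_rows, comp_rows = [], []
    for outcome in outcomes:
        if outcome not in kinetics.columns:
            continue
        d = kinetics.dropna(subset=[outcome])
        if d.empty:
            continue
        fit = fit_random_intercept(d, outcome, config=cfg.stats)
        sens = sensitivity_refit(fit, d, outcome, config=cfg.stats)
        zc = zero_crossing_day(fit)
        trend_rows.append({
            "outcome": outcome, "beta0": fit.beta0, "beta1": fit.beta1,
            "se_beta1": fit.se_beta1, "p_slope": fit.p_slope,
            "sigma_b": fit.sigma_b, "sigma_e": fit.sigma_e,
            "n_obs": fit.n_obs, "n_patients": fit.n_patients,
            "boundary": fit.boundary,
            "zero_crossing_day": zc.day, "zero_crossing_se": zc.se,
            "n_removed_sensitivity": len(sens.removed_patient_ids),
            "conclusion_changed": sens.conclusion_changed,
        })
        cmp_res = compare_periods(d, outcome, cfg.stats)
        comp_rows.append({"outcome": outcome,
                          **dataclasses.asdict(cmp_res)})
    return pd.DataFrame(trend_rows), pd.DataFrame(comp_rows)


def plot_trajectories(kinetics: pd.DataFrame, outcome: str, path: str | Path,
                      fit=None) -> None:
    """Per-patient trajectories of one outcome with the fitted mean line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for _, grp in kinetics.dropna(subset=[outcome]).groupby("patient_id"):
        g = grp.sort_values("icu_day")
        ax.plot(g["icu_day"], g[outcome], "o-", color="0.6", lw=0.8, ms=3)
    if fit is not None:
        days = np.linspace(kinetics["icu_day"].min(),
                           kinetics["icu_day"].max(), 50)
        ax.plot(days, fit.beta0 + fit.beta1 * days, "k-", lw=2,
                label=f"slope {fit.beta1:.3g}/day, p={fit.p_slope:.3g}")
        ax.legend(frameon=False)
    ax.axhline(0, color="k", lw=0.5, ls=":")
    ax.set_xlabel("ICU day")
    ax.set_ylabel(f"{outcome} (nmol/min/100 ml leg)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: Config | None = None,
                 input_dir: str | Path | None = None,
                 simulate: bool = False,
                 outdir: str | Path = "legflux_out",
                 seed: int | None = None,
                 plots: bool = False) -> dict[str, Path]:
    """Execute simulate/load -> kinetics -> flux -> stats, writing reports.

    Returns a map of report name -> written path. Raises LegfluxError
    subclasses with the failing stage named.
    """
    cfg = config or Config()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    status: list[str] = []
    paths: dict[str, Path] = {}

    def stage(name: str, fn):
        try:
            result = fn()
        except LegfluxError as exc:
            status.append(f"{name}: FAILED - {exc}")
            _write_log(outdir, cfg, seed, status)
            raise LegfluxError(f"stage '{name}' failed: {exc}") from exc
        status.append(f"{name}: ok")
        return result

    if simulate:
        cohort, truth = stage("simulate",
                              lambda: simulate_cohort(cfg.simulate, seed=seed))
        simdir = outdir / "simulated"
        cohort.write(simdir)
        truth.to_csv(simdir / "truth.csv", index=False)
        paths["truth"] = simdir / "truth.csv"
    else:
        if input_dir is None:
            raise LegfluxError("either --simulate or an input directory is required")
        cohort = stage("datamodel", lambda: load_cohort(input_dir, cfg))

    kinetics, aaflux = stage("kinetics", lambda: analyze_cohort(cohort, cfg))
    trend, comparison = stage("stats", lambda: run_stats(kinetics, config=cfg))

    for name, frame in (("kinetics", kinetics), ("aaflux", aaflux),
                        ("stats_report", trend),
                        ("comparison_report", comparison)):
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    if plots:
        for outcome in ("NB", "F_0M", "F_M0", "total_aa_flux"):
            if outcome in kinetics.columns and kinetics[outcome].notna().any():
                plot_trajectories(kinetics, outcome,
                                  outdir / f"{outcome}_trajectories.png")
                paths[f"plot_{outcome}"] = outdir / f"{outcome}_trajectories.png"
    _write_log(outdir, cfg, seed, status)
    paths["log"] = outdir / "run.log"
    return paths


def _write_log(outdir: Path, cfg: Config, seed, status: list[str]) -> None:
    cfg_yaml = yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)
    digest = hashlib.sha256(cfg_yaml.encode()).hexdigest()[:16]
    lines = [f"legflux {__version__}", f"config_hash {digest}",
             f"seed {seed if seed is not None else cfg.simulate.seed}"]
    lines += status
    (outdir / "run.log").write_text("\n".join(lines) + "\n")
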