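"""On-disk schemas, run configuration and the end-to-end pipeline.

Canonical time-series schema is one long-format CSV:

    well, time_min, channel, reporter_id, value      (channel in {OD600, CPS})

Layouts are ``well, arabinose_percent, camp_mM``; activity profiles are
``index, A_star, C_star, sigma``; fit results and prediction metrics are
JSON.  Configuration is a flat-ish mapping read from JSON (canonical) or
TOML; unknown keys are rejected and every random seed must be explicit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import (
    ActivityProfile,
    GradientLayout,
    PlateTimeSeries,
    ReporterCalibration,
    RepressionReporter,
    calibrate_reporter,
)
from .dynamics import (
    ARAC_DEGRADATION_PER_MIN,
    LossModel,
    align_and_average,
    evaluate_prediction,
    integrate_expression,
)
from .model import reduce_and_compare
from . import simulate as sim

log = logging.getLogger("aralogic")

__all__ = [
    "RunConfig",
    "read_plate_csv",
    "write_plate_csv",
    "read_layout_csv",
    "write_layout_csv",
    "read_activity_csv",
    "write_activity_csv",
    "load_config",
    "run_pipeline",
]

_PLATE_COLUMNS = ["well", "time_min", "channel", "reporter_id", "value"]


# ---------------------------------------------------------------------------
# time-series CSV

def write_plate_csv(plate: PlateTimeSeries, path) -> None:
    """Write the canonical long-format CSV, rows sorted (well, time, channel)."""
    frames = []
    for channel, wide in (("OD600", plate.od), ("CPS", plate.lum)):
        long = wide.reset_index().melt(
            id_vars="time_min", var_name="well", value_name="value"
        )
        long["channel"] = channel
        frames.append(long)
    df = pd.concat(frames, ignore_index=True)
    df["reporter_id"] = df["well"].map(plate.reporter_id)
    df = df[_PLATE_COLUMNS].sort_values(["well", "time_min", "channel"], kind="mergesort")
    df.to_csv(path, index=False)


def read_plate_csv(path) -> PlateTimeSeries:
    """Load and validate the canonical long-format CSV (order-insensitive)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate CSV missing column(s): {missing}")
    bad_channel = set(df["channel"].unique()) - {"OD600", "CPS"}
    if bad_channel:
        raise ValueError(f"unknown channel value(s): {sorted(bad_channel)}")
    dup = df.duplicated(subset=["well", "time_min", "channel"])
    if dup.any():
        rows = df.loc[dup, ["well", "time_min", "channel"]].head()
        raise ValueError(f"duplicate (well, time_min, channel) rows, e.g.\n{rows}")
    od = df[df["channel"] == "OD600"].pivot(index="time_min", columns="well", values="value")
    lum = df[df["channel"] == "CPS"].pivot(index="time_min", columns="well", values="value")
    od = od.sort_index()
    lum = lum.sort_index()[od.columns]
    reporter = (
        df.drop_duplicates("well").set_index("well")["reporter_id"].loc[od.columns]
    )
    times = od.index.to_numpy(float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("non-monotone time grid after canonicalization")
    return PlateTimeSeries(od=od, lum=lum, reporter_id=reporter)


def write_layout_csv(layout: GradientLayout, path) -> None:
    layout.table.sort_index().to_csv(path, index_label="well")


def read_layout_csv(path) -> GradientLayout:
    df = pd.read_csv(path).set_index("well")
    return GradientLayout(df)


def write_activity_csv(profile: ActivityProfile, path) -> None:
    profile.to_frame().to_csv(path, index_label="index")


def read_activity_csv(path) -> ActivityProfile:
    return ActivityProfile.from_frame(pd.read_csv(path, index_col="index"))


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; all randomness flows through ``seed``.

    Units: concentrations in % w/v (arabinose) and mM (cAMP); times in
    minutes; expression in CPS/OD; activities dimensionless.
    """

    seed: int
    outdir: str = "results"
    promoters: tuple = ("araBAD", "araC", "araE", "araFGH")
    # gradient design
    n_arabinose_levels: int = 12
    n_camp_levels: int = 8
    steady_state_time_min: float = 44.0
    steady_state_window: int = 1  # points averaged at/around the read
    # reporter calibrations (truth used for simulation and analysis)
    reporter_alpha_rep: float = 1000.0
    reporter_basal_T: float = 20.0
    activity_cap: float = 50.0
    calibrate_from_data: bool = False
    # noise
    lum_lognormal_sigma: float = 0.05
    od_gaussian_sd: float = 0.002
    # fitting
    form: str = "additive"
    significance_level: float = 0.05
    fit_basal: bool = True
    # dynamics
    tau_min: float = 30.0
    n_replicates: int = 7
    align_offset_min: float = 20.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed must be explicit")
        if not self.promoters:
            raise ValueError("need at least one promoter")
        unknown = set(self.promoters) - set(sim.REFERENCE_COEFFICIENTS)
        if unknown:
            raise ValueError(f"unknown promoter(s): {sorted(unknown)}")

    def loss_model(self, promoter: str) -> LossModel:
        # AraC is short-lived: degradation added on top of dilution.
        if promoter == "araC":
            return LossModel(
                tau_min=self.tau_min,
                k_deg=ARAC_DEGRADATION_PER_MIN,
                mode="dilution_plus_degradation",
            )
        return LossModel(tau_min=self.tau_min, mode="dilution_only")


def load_config(path) -> RunConfig:
    """Read a RunConfig from JSON (canonical) or TOML; unknown keys rejected."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path) as fh:
            raw = json.load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "seed" not in raw:
        raise ValueError("config must set an explicit seed")
    for tuple_key in ("promoters",):
        if tuple_key in raw:
            raw[tuple_key] = tuple(raw[tuple_key])
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# pipeline

def _gradient_design(config: RunConfig) -> sim.GradientDesign:
    return sim.GradientDesign(
        arabinose_levels=tuple(
            np.round(np.linspace(0.0, 0.2, config.n_arabinose_levels), 6)
        ),
        camp_levels=tuple(np.round(np.linspace(0.0, 1.0, config.n_camp_levels), 6)),
    )


def _steady_state_expression(plate: PlateTimeSeries, config: RunConfig) -> pd.Series:
    """Per-well expression at the steady-state read time (optionally a window)."""
    expr = plate.expression()
    times = expr.index.to_numpy(float)
    idx = int(np.argmin(np.abs(times - config.steady_state_time_min)))
    half = (config.steady_state_window - 1) // 2
    lo, hi = max(0, idx - half), min(len(times), idx + half + 1)
    return expr.iloc[lo:hi].mean(axis=0)


def run_pipeline(config: RunConfig) -> dict:
    """Simulate, infer activities, fit, reduce, predict the shift, evaluate.

    Deterministic given the config seed.  Writes activity CSVs, fit and
    comparison JSON, prediction CSVs and metrics JSON under ``config.outdir``
    and returns the in-memory bundle.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("config: %s", dataclasses.asdict(config))
    log.info(
        "defaults: repression form S=alpha/(1+A)+T; additive integration "
        "B=sigma*(aA+bC+gAC)+T_B; AIC=n*ln(rss/n)+2(k+1); activity cap %s; "
        "OD floor 0.01; RK4 substeps 4; rise detection window 5, k_sd 3; "
        "align offset %s min; araC k_deg %s /min",
        config.activity_cap, config.align_offset_min, ARAC_DEGRADATION_PER_MIN,
    )

    design = _gradient_design(config)
    cal = ReporterCalibration(
        alpha_rep=config.reporter_alpha_rep,
        basal_T=config.reporter_basal_T,
        activity_cap=config.activity_cap,
    )
    bundle: dict = {"config": dataclasses.asdict(config), "promoters": {}}

    try:
        for p_i, promoter in enumerate(config.promoters):
            truth = sim.REFERENCE_COEFFICIENTS[promoter]
            noise = sim.NoiseModel(
                lum_lognormal_sigma=config.lum_lognormal_sigma,
                od_gaussian_sd=config.od_gaussian_sd,
                seed=config.seed + 1000 * p_i,
            )
            # --- steady-state gradient ---------------------------------
            plate, layout, _truth_prof = sim.simulate_gradient_plate(
                design, truth, cal, cal, noise=noise, promoter_id=promoter
            )
            write_plate_csv(plate, outdir / f"gradient_{promoter}.csv")
            write_layout_csv(layout, outdir / f"layout_{promoter}.csv")
            ss = _steady_state_expression(plate, config)
            by_channel = {
                rid: ss[[w for w in plate.wells if plate.reporter_id[w] == rid]]
                .to_numpy(float)
                for rid in ("synARA", "synCRP", "synRNAPs70", promoter)
            }
            if config.calibrate_from_data:
                cal_A = calibrate_reporter(by_channel["synARA"], activity_cap=config.activity_cap)
                cal_C = calibrate_reporter(by_channel["synCRP"], activity_cap=config.activity_cap)
            else:
                cal_A = cal_C = cal
            rep_A = RepressionReporter(cal_A.alpha_rep, cal_A.basal_T, cal_A.activity_cap)
            rep_C = RepressionReporter(cal_C.alpha_rep, cal_C.basal_T, cal_C.activity_cap)
            a_star = rep_A.fit(by_channel["synARA"]).transform(by_channel["synARA"])
            c_star = rep_C.fit(by_channel["synCRP"]).transform(by_channel["synCRP"])
            sigma = by_channel["synRNAPs70"]
            dataset = pd.DataFrame(
                {
                    "A_star": a_star,
                    "C_star": c_star,
                    "sigma": sigma,
                    "expression": by_channel[promoter],
                }
            )
            profile = ActivityProfile(
                index=np.arange(len(dataset)), a_star=a_star, c_star=c_star, sigma=sigma
            )
            write_activity_csv(profile, outdir / f"activities_{promoter}.csv")

            # --- fit and reduce ---------------------------------------
            comparison = reduce_and_compare(
                dataset,
                level=config.significance_level,
                form=config.form,
                fit_basal=config.fit_basal,
            )
            with open(outdir / f"fit_{promoter}.json", "w") as fh:
                json.dump(comparison.to_record(), fh, indent=2)
            selected = (
                comparison.reduced
                if comparison.selected == "reduced"
                else comparison.full
            )
            log.info("%s: selected %s model, dropped %s, coefficients %s",
                     promoter, comparison.selected, comparison.dropped,
                     selected.coefficients.as_dict())

            # --- diauxic shift ----------------------------------------
            scenario = sim.DiauxicScenario(n_replicates=config.n_replicates)
            loss = config.loss_model(promoter)
            shift = sim.simulate_diauxic_experiment(
                scenario, truth, loss, cal_A, cal_C,
                noise=sim.NoiseModel(
                    lum_lognormal_sigma=config.lum_lognormal_sigma,
                    od_gaussian_sd=config.od_gaussian_sd,
                    seed=config.seed + 1000 * p_i + 500,
                ),
            )
            pairs = []
            for rep in shift.replicates:
                a_t = rep_A.transform(rep.reporter_expression["synARA"].to_numpy())
                c_t = rep_C.transform(rep.reporter_expression["synCRP"].to_numpy())
                s_t = rep.reporter_expression["synRNAPs70"].to_numpy(float)
                pairs.append(
                    (
                        ActivityProfile(rep.times, a_t, c_t, s_t),
                        rep.promoter_expression,
                    )
                )
            mean_profile, mean_expr = align_and_average(
                pairs, offset_min=config.align_offset_min
            )
            predicted = integrate_expression(
                mean_profile, selected.coefficients, loss,
                b0=float(mean_expr["expression"].iloc[0]),
            )
            pred_df = pd.DataFrame(
                {
                    "time_min": np.asarray(mean_profile.index, dtype=float),
                    "predicted": predicted,
                    "observed": mean_expr["expression"].to_numpy(float),
                    "n_replicates": mean_expr["n_replicates"].to_numpy(int),
                }
            )
            pred_df.to_csv(outdir / f"prediction_{promoter}.csv", index=False)
            metrics = evaluate_prediction(
                pred_df["time_min"], pred_df["predicted"], pred_df["observed"]
            )
            with open(outdir / f"metrics_{promoter}.json", "w") as fh:
                json.dump(metrics.to_record(), fh, indent=2)
            log.info("%s: prediction metrics %s", promoter, metrics.to_record())

            bundle["promoters"][promoter] = {
                "comparison": comparison,
                "metrics": metrics,
                "prediction": pred_df,
            }
    except Exception as exc:  # annotate the failing stage, then re-raise
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return bundle
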