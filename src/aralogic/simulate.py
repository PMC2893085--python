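"""Synthetic gradient-plate and diauxic-shift data with known ground truth.

The generator emulates the two experiment classes the analysis consumes:

* a steady-state gradient plate — up to 96 combinations of arabinose
  (0-0.2 % w/v) and cAMP (0-1 mM), read at 4-minute intervals, with the
  44-minute read taken as steady state;
* diauxic-shift time courses in which CRP-cAMP activity pulses sharply at
  glucose exhaustion and AraC-arabinose activity rises afterwards, with
  replicate-to-replicate jitter in the exhaustion time (seven replicates by
  default, matching the replication of the shift experiments).

Ground-truth activities, coefficients and trajectories are returned alongside
the noisy observables so every downstream stage can be checked by recovery.
All randomness flows through a single seed; zero noise reproduces the forward
model exactly.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .activity import (
    ActivityProfile,
    GradientLayout,
    PlateTimeSeries,
    ReporterCalibration,
    repression_forward,
)
from .dynamics import LossModel, integrate_expression, loss_rate
from .model import IntegrationCoefficients, forward_expression

__all__ = [
    "PulseParams",
    "RiseParams",
    "NoiseModel",
    "GradientDesign",
    "DoseResponse",
    "DiauxicScenario",
    "DiauxicDataset",
    "REFERENCE_COEFFICIENTS",
    "crp_activity_pulse",
    "arac_activity_rise",
    "gradient_conditions",
    "simulate_gradient_expression",
    "simulate_gradient_plate",
    "simulate_diauxic_experiment",
]

#: Published steady-state coefficient sets for the four promoters, with the
#: CRP-alone term structurally absent (it was insignificant at every
#: promoter and dropped on refit).  Used as generator ground truth.
REFERENCE_COEFFICIENTS: dict[str, IntegrationCoefficients] = {
    "araBAD": IntegrationCoefficients(alpha=2.535, gamma=4.347),
    "araC": IntegrationCoefficients(alpha=1.656, gamma=1.078),
    "araE": IntegrationCoefficients(alpha=1.684, gamma=7.726),
    "araFGH": IntegrationCoefficients(alpha=0.6546, gamma=3.344),
}


# ---------------------------------------------------------------------------
# activity wave forms

@dataclass(frozen=True)
class PulseParams:
    """Transient CRP-cAMP activity pulse at glucose exhaustion.

    Piecewise-exponential: baseline before onset, saturating rise over
    ``rise_min``, then exponential decay back to baseline with time scale
    ``decay_min``.
    """

    baseline: float = 0.1
    amplitude: float = 2.5
    onset_min: float = 60.0
    rise_min: float = 6.0
    decay_min: float = 10.0

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.amplitude < 0:
            raise ValueError("baseline and amplitude must be >= 0")
        if self.rise_min <= 0 or self.decay_min <= 0:
            raise ValueError("rise_min and decay_min must be > 0")


@dataclass(frozen=True)
class RiseParams:
    """Monotone AraC-arabinose activation after the cAMP pulse.

    Saturating exponential approach from baseline to ceiling at ``rate``
    per minute, starting at ``onset_min``.
    """

    baseline: float = 0.05
    rate: float = 0.04
    onset_min: float = 70.0
    ceiling: float = 3.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.ceiling < self.baseline:
            raise ValueError("ceiling must be >= baseline")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")


def crp_activity_pulse(t, p: PulseParams):
    """CRP-cAMP activity at time ``t`` (min): baseline, pulse, relaxation.

    Equals baseline for t <= onset, has a single maximum shortly after
    ``onset + rise``, and returns to baseline as t grows.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t_arr)) or np.any(t_arr < 0):
        raise ValueError("t must be finite and >= 0")
    dt = t_arr - p.onset_min
    rising = 1.0 - np.exp(-np.clip(dt, 0.0, None) / p.rise_min)
    decaying = np.exp(-np.clip(dt - p.rise_min, 0.0, None) / p.decay_min)
    out = np.where(dt <= 0, p.baseline, p.baseline + p.amplitude * rising * decaying)
    return float(out) if np.isscalar(t) else out


def arac_activity_rise(t, p: RiseParams):
    """AraC-arabinose activity at time ``t`` (min): non-decreasing, bounded.

    Baseline before onset; afterwards relaxes exponentially toward the
    ceiling, so a zero rate leaves the baseline unchanged.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t_arr)) or np.any(t_arr < 0):
        raise ValueError("t must be finite and >= 0")
    dt = np.clip(t_arr - p.onset_min, 0.0, None)
    out = p.ceiling - (p.ceiling - p.baseline) * np.exp(-p.rate * dt)
    return float(out) if np.isscalar(t) else out


# ---------------------------------------------------------------------------
# designs and noise

@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: multiplicative lognormal on luminescence,
    additive Gaussian on OD (floored at a small positive value).

    Zero sigmas reproduce the noise-free forward model exactly; the same
    seed reproduces the identical dataset.
    """

    lum_lognormal_sigma: float = 0.05
    od_gaussian_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lum_lognormal_sigma < 0 or self.od_gaussian_sd < 0:
            raise ValueError("noise scales must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _default_ara_levels() -> tuple:
    return tuple(np.round(np.linspace(0.0, 0.2, 12), 6))


def _default_camp_levels() -> tuple:
    return tuple(np.round(np.linspace(0.0, 1.0, 8), 6))


@dataclass(frozen=True)
class GradientDesign:
    """Arabinose x cAMP combinatorial gradient on one 96-well plate."""

    arabinose_levels: tuple = field(default_factory=_default_ara_levels)
    camp_levels: tuple = field(default_factory=_default_camp_levels)
    read_interval_min: float = 4.0
    horizon_min: float = 90.0

    def __post_init__(self) -> None:
        ara = np.asarray(self.arabinose_levels, dtype=float)
        camp = np.asarray(self.camp_levels, dtype=float)
        if ara.size * camp.size > 96:
            raise ValueError("more than 96 arabinose x cAMP combinations")
        for name, levels, hi in (("arabinose", ara, 0.2), ("camp", camp, 1.0)):
            if np.any(levels < 0) or np.any(levels > hi):
                raise ValueError(f"{name} levels must lie in [0, {hi}]")
            if np.any(np.diff(levels) < 0):
                raise ValueError(f"{name} levels must be sorted ascending")
        if self.read_interval_min <= 0 or self.horizon_min <= 0:
            raise ValueError("read interval and horizon must be > 0")

    @property
    def n_wells(self) -> int:
        return len(self.arabinose_levels) * len(self.camp_levels)

    def times(self) -> np.ndarray:
        return np.arange(0.0, self.horizon_min + 1e-9, self.read_interval_min)


@dataclass(frozen=True)
class DoseResponse:
    """Map inducer concentrations to true activities.

    AraC responds to arabinose in a step-like (high-Hill) manner; CRP
    responds to cAMP gradedly (Hill 1); the polymerase signal sigma is
    constant.  Defaults span activities of roughly 0-3.
    """

    a_max: float = 3.0
    K_a: float = 0.05   # % w/v arabinose at half-max before the Hill power
    hill: float = 4.0
    c_max: float = 3.0
    K_c: float = 0.2    # mM cAMP at half-max
    sigma: float = 1.0

    def activities(self, arabinose, camp):
        ara = np.asarray(arabinose, dtype=float)
        cam = np.asarray(camp, dtype=float)
        a = self.a_max * (ara / (self.K_a + ara)) ** self.hill
        c = self.c_max * cam / (self.K_c + cam)
        s = np.broadcast_to(self.sigma, np.broadcast(ara, cam).shape).astype(float)
        return a, c, s


def gradient_conditions(design: GradientDesign) -> pd.DataFrame:
    """All (arabinose, cAMP) pairs of a design, one row per well."""
    rows = [
        (f"{string.ascii_uppercase[i]}{j + 1:02d}", ara, camp)
        for i, camp in enumerate(design.camp_levels)
        for j, ara in enumerate(design.arabinose_levels)
    ]
    return pd.DataFrame(rows, columns=["well", "arabinose_percent", "camp_mM"]).set_index("well")


def simulate_gradient_expression(
    design: GradientDesign,
    truth: IntegrationCoefficients,
    dose_response: DoseResponse = DoseResponse(),
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Steady-state promoter expression across the gradient, one row per well.

    Returns columns arabinose_percent, camp_mM, A_star, C_star, sigma,
    expression.  ``noise_sigma`` applies multiplicative lognormal noise to the
    expression channel only; the returned activities are exact.
    """
    cond = gradient_conditions(design)
    a, c, s = dose_response.activities(
        cond["arabinose_percent"].to_numpy(), cond["camp_mM"].to_numpy()
    )
    expr = forward_expression(a, c, s, truth)
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("noisy simulation requires an explicit rng")
        expr = expr * rng.lognormal(mean=0.0, sigma=noise_sigma, size=expr.shape)
    out = cond.copy()
    out["A_star"] = a
    out["C_star"] = c
    out["sigma"] = s
    out["expression"] = expr
    return out


# ---------------------------------------------------------------------------
# full plate simulations

def _logistic_od(times: np.ndarray, od0: float = 0.05, rate: float = np.log(2) / 30.0,
                 od_max: float = 1.0) -> np.ndarray:
    return od_max / (1.0 + (od_max / od0 - 1.0) * np.exp(-rate * times))


def simulate_gradient_plate(
    design: GradientDesign,
    truth: IntegrationCoefficients,
    cal_A: ReporterCalibration,
    cal_C: ReporterCalibration,
    noise: NoiseModel = NoiseModel(lum_lognormal_sigma=0.0, od_gaussian_sd=0.0),
    dose_response: DoseResponse = DoseResponse(),
    promoter_id: str = "araBAD",
) -> tuple[PlateTimeSeries, GradientLayout, ActivityProfile]:
    """Simulate a gradient experiment: promoter plus reporter channels.

    Each (arabinose, cAMP) condition yields four wells, one per channel:
    the catabolic promoter (forward integration model), the AraC and CRP
    repression reporters (repression model of the true activities) and the
    constitutive sigma-70 reporter (raw sigma).  Expression is constant over
    the read window (steady state); luminescence = expression x OD with
    noise per the model; true per-condition activities are returned.
    """
    cond = gradient_conditions(design)
    a, c, s = dose_response.activities(
        cond["arabinose_percent"].to_numpy(), cond["camp_mM"].to_numpy()
    )
    channels = {
        promoter_id: forward_expression(a, c, s, truth),
        "synARA": repression_forward(a, cal_A),
        "synCRP": repression_forward(c, cal_C),
        "synRNAPs70": s.astype(float),
    }
    times = design.times()
    rng = noise.rng()
    od_clean = _logistic_od(times)

    lum_cols, od_cols, reporter_ids, layout_rows = {}, {}, {}, []
    for reporter, expr in channels.items():
        for w, well in enumerate(cond.index):
            wid = f"{reporter}:{well}"
            od = od_clean.copy()
            if noise.od_gaussian_sd > 0:
                od = od + rng.normal(0.0, noise.od_gaussian_sd, size=od.shape)
            od = np.clip(od, 1e-4, None)
            lum = expr[w] * od
            if noise.lum_lognormal_sigma > 0:
                lum = lum * rng.lognormal(0.0, noise.lum_lognormal_sigma, size=lum.shape)
            od_cols[wid] = od
            lum_cols[wid] = lum
            reporter_ids[wid] = reporter
            layout_rows.append(
                (wid, cond.loc[well, "arabinose_percent"], cond.loc[well, "camp_mM"])
            )

    plate = PlateTimeSeries(
        od=pd.DataFrame(od_cols, index=pd.Index(times, name="time_min")),
        lum=pd.DataFrame(lum_cols, index=pd.Index(times, name="time_min")),
        reporter_id=pd.Series(reporter_ids, name="reporter_id"),
    )
    layout = GradientLayout(
        pd.DataFrame(
            layout_rows, columns=["well", "arabinose_percent", "camp_mM"]
        ).set_index("well")
    )
    profile = ActivityProfile(index=np.asarray(cond.index), a_star=a, c_star=c, sigma=s)
    return plate, layout, profile


# ---------------------------------------------------------------------------
# diauxic shift

@dataclass(frozen=True)
class DiauxicScenario:
    """Diauxic-shift experiment plan.

    ``crp_pulse.onset_min`` and ``arac_rise.onset_min`` are offsets relative
    to each replicate's glucose-exhaustion time; exhaustion times are jittered
    uniformly within ``exhaustion_jitter_min`` of ``exhaustion_time_min``.
    """

    n_replicates: int = 7
    exhaustion_time_min: float = 60.0
    exhaustion_jitter_min: float = 12.0
    crp_pulse: PulseParams = PulseParams(onset_min=0.0)
    arac_rise: RiseParams = RiseParams(onset_min=10.0)
    sigma_level: float = 1.0
    tau_min: float = 30.0
    horizon_min: float = 180.0
    read_interval_min: float = 4.0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.tau_min <= 0:
            raise ValueError("cell-cycle time must be > 0")
        if self.sigma_level <= 0:
            raise ValueError("sigma_level must be > 0")
        if self.exhaustion_time_min - self.exhaustion_jitter_min <= 0:
            raise ValueError("exhaustion times must stay positive under jitter")


@dataclass
class DiauxicReplicate:
    """One shift replicate: truth, observables and the exhaustion time."""

    times: np.ndarray
    truth_profile: ActivityProfile
    promoter_expression: np.ndarray
    reporter_expression: pd.DataFrame  # columns synARA, synCRP, synRNAPs70
    od: np.ndarray
    exhaustion_min: float


@dataclass
class DiauxicDataset:
    """Replicated diauxic-shift series with retained ground truth."""

    replicates: list
    truth: IntegrationCoefficients
    loss: LossModel
    scenario: DiauxicScenario

    def __post_init__(self) -> None:
        if len(self.replicates) < 1:
            raise ValueError("need at least one replicate")


def _diauxic_od(times: np.ndarray, exhaustion: float, tau: float,
                lag_min: float = 20.0, od0: float = 0.05) -> np.ndarray:
    """Biphasic growth: exponential, flat lag at exhaustion, regrowth."""
    rate = np.log(2) / tau
    od = np.empty_like(times)
    phase1 = times <= exhaustion
    od[phase1] = od0 * np.exp(rate * times[phase1])
    od_ex = od0 * np.exp(rate * exhaustion)
    lag = (~phase1) & (times <= exhaustion + lag_min)
    od[lag] = od_ex
    regrow = times > exhaustion + lag_min
    od[regrow] = od_ex * np.exp(rate * (times[regrow] - exhaustion - lag_min))
    return np.clip(od, None, 1.5)


def simulate_diauxic_experiment(
    scenario: DiauxicScenario,
    truth: IntegrationCoefficients,
    loss: LossModel,
    cal_A: ReporterCalibration,
    cal_C: ReporterCalibration,
    noise: NoiseModel = NoiseModel(lum_lognormal_sigma=0.0, od_gaussian_sd=0.0),
) -> DiauxicDataset:
    """Simulate replicated diauxic-shift time courses.

    Per replicate: a jittered glucose-exhaustion time positions the CRP-cAMP
    pulse and subsequent AraC-arabinose rise; reporter channels follow the
    repression model of those true activities; the promoter channel solves
    the production-minus-loss dynamics driven by them, started at its
    pre-shift steady state.  Noise enters only the luminescence/OD
    observables; the true trajectories are retained.
    """
    rng = noise.rng()
    times = np.arange(0.0, scenario.horizon_min + 1e-9, scenario.read_interval_min)
    jitter = rng.uniform(
        -scenario.exhaustion_jitter_min, scenario.exhaustion_jitter_min,
        size=scenario.n_replicates,
    )
    # distinct exhaustion times across replicates, guaranteed by spreading ties
    exhaustion = scenario.exhaustion_time_min + jitter
    mu = loss_rate(loss)

    replicates = []
    for r in range(scenario.n_replicates):
        ex = float(exhaustion[r])
        pulse = replace(scenario.crp_pulse, onset_min=ex + scenario.crp_pulse.onset_min)
        rise = replace(scenario.arac_rise, onset_min=ex + scenario.arac_rise.onset_min)
        c_true = crp_activity_pulse(times, pulse)
        a_true = arac_activity_rise(times, rise)
        s_true = np.full_like(times, scenario.sigma_level)
        profile = ActivityProfile(index=times, a_star=a_true, c_star=c_true, sigma=s_true)

        prod0 = forward_expression(a_true[0], c_true[0], s_true[0], truth)
        b0 = prod0 / mu if mu > 0 else 0.0
        b = integrate_expression(profile, truth, loss, b0=b0)

        reporters = pd.DataFrame(
            {
                "synARA": repression_forward(a_true, cal_A),
                "synCRP": repression_forward(c_true, cal_C),
                "synRNAPs70": s_true,
            },
            index=pd.Index(times, name="time_min"),
        )
        od = _diauxic_od(times, ex, scenario.tau_min)
        if noise.od_gaussian_sd > 0:
            od = np.clip(od + rng.normal(0.0, noise.od_gaussian_sd, od.shape), 1e-4, None)
        if noise.lum_lognormal_sigma > 0:
            b_obs = b * rng.lognormal(0.0, noise.lum_lognormal_sigma, b.shape)
            reporters = reporters * rng.lognormal(
                0.0, noise.lum_lognormal_sigma, reporters.shape
            )
        else:
            b_obs = b
        replicates.append(
            DiauxicReplicate(
                times=times,
                truth_profile=profile,
                promoter_expression=b_obs,
                reporter_expression=reporters,
                od=od,
                exhaustion_min=ex,
            )
        )
    return DiauxicDataset(replicates=replicates, truth=truth, loss=loss, scenario=scenario)
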