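"""Normalisation of raw plate data and transcription-factor activity inference.

A repression reporter is a constitutive promoter with a transcription-factor
operator immediately downstream: the more active the factor, the more the
reporter is repressed.  With activation span ``alpha_rep`` and basal level
``basal_T`` its expression at factor activity ``a`` is

    S(a) = alpha_rep / (1 + a) + basal_T

so the activity is recovered by inverting this curve, clamping negative
solutions to zero (readings above the fully-unrepressed level) and capping the
divergence as expression approaches the basal plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ReporterCalibration",
    "PlateTimeSeries",
    "GradientLayout",
    "ActivityProfile",
    "normalize_to_od",
    "repression_forward",
    "infer_activity",
    "calibrate_reporter",
    "RepressionReporter",
]

#: OD readings at or below this are treated as missing, not divided by.
DEFAULT_OD_FLOOR = 0.01

#: Default upper clamp for inferred activities; the inversion diverges as
#: expression approaches the basal plateau, and a finite cap keeps downstream
#: fits well-posed.
DEFAULT_ACTIVITY_CAP = 50.0


@dataclass(frozen=True)
class ReporterCalibration:
    """Activation span and basal level of one repression reporter.

    Parameters
    ----------
    alpha_rep : float
        Fully-unrepressed minus fully-repressed expression (CPS/OD), > 0.
    basal_T : float
        Fully-repressed plateau (CPS/OD), >= 0.
    activity_cap : float
        Upper clamp for inferred activities (dimensionless), > 0.
    """

    alpha_rep: float
    basal_T: float = 0.0
    activity_cap: float = DEFAULT_ACTIVITY_CAP

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha_rep) or self.alpha_rep <= 0:
            raise ValueError(f"alpha_rep must be finite and > 0, got {self.alpha_rep}")
        if not np.isfinite(self.basal_T) or self.basal_T < 0:
            raise ValueError(f"basal_T must be finite and >= 0, got {self.basal_T}")
        if self.activity_cap <= 0:
            raise ValueError(f"activity_cap must be > 0, got {self.activity_cap}")


@dataclass
class PlateTimeSeries:
    """Per-well OD600 and luminescence on a shared, strictly increasing grid.

    ``od`` and ``lum`` are DataFrames indexed by time (minutes) with one
    column per well; ``reporter_id`` maps each well to its reporter.
    """

    od: pd.DataFrame
    lum: pd.DataFrame
    reporter_id: pd.Series

    def __post_init__(self) -> None:
        times = np.asarray(self.od.index, dtype=float)
        if times.size and not np.all(np.diff(times) > 0):
            raise ValueError("time grid must be strictly increasing")
        if list(self.od.columns) != list(self.lum.columns):
            raise ValueError("od and lum must cover the same wells")
        if not self.od.index.equals(self.lum.index):
            raise ValueError("od and lum must share the time grid")
        missing = set(self.od.columns) - set(self.reporter_id.index)
        if missing:
            raise ValueError(f"wells without reporter_id: {sorted(missing)}")
        if (self.lum.to_numpy() < 0).any():
            raise ValueError("luminescence must be >= 0")

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.od.index, dtype=float)

    @property
    def wells(self) -> list[str]:
        return list(self.od.columns)

    def expression(self, od_floor: float = DEFAULT_OD_FLOOR) -> pd.DataFrame:
        """CPS/OD per well and time; OD at/below the floor yields NaN."""
        return pd.DataFrame(
            normalize_to_od(self.lum.to_numpy(float), self.od.to_numpy(float), od_floor),
            index=self.od.index,
            columns=self.od.columns,
        )


@dataclass
class GradientLayout:
    """Map well -> (arabinose % w/v, cAMP mM) for a gradient plate."""

    table: pd.DataFrame  # index well, columns arabinose_percent, camp_mM

    def __post_init__(self) -> None:
        need = {"arabinose_percent", "camp_mM"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"layout must have columns {sorted(need)}")
        ara = self.table["arabinose_percent"]
        camp = self.table["camp_mM"]
        if (ara < 0).any() or (ara > 0.2).any():
            raise ValueError("arabinose_percent must lie in [0, 0.2]")
        if (camp < 0).any() or (camp > 1.0).any():
            raise ValueError("camp_mM must lie in [0, 1]")

    def condition(self, well: str) -> tuple[float, float]:
        row = self.table.loc[well]
        return float(row["arabinose_percent"]), float(row["camp_mM"])


@dataclass
class ActivityProfile:
    """Measured activities A*, C* and polymerase signal sigma on an index.

    The index is either time (minutes) for diauxic-shift series or an
    arbitrary condition label for gradient plates.
    """

    index: np.ndarray
    a_star: np.ndarray
    c_star: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.index)
        for name in ("a_star", "c_star", "sigma"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
        if np.nanmin(self.a_star, initial=0.0) < 0 or np.nanmin(self.c_star, initial=0.0) < 0:
            raise ValueError("activities must be >= 0")
        if (np.asarray(self.sigma, dtype=float) <= 0).any():
            raise ValueError("sigma must be > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"A_star": self.a_star, "C_star": self.c_star, "sigma": self.sigma},
            index=pd.Index(self.index, name="index"),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ActivityProfile":
        return cls(
            index=np.asarray(df.index),
            a_star=df["A_star"].to_numpy(float),
            c_star=df["C_star"].to_numpy(float),
            sigma=df["sigma"].to_numpy(float),
        )


def normalize_to_od(lum, od, od_floor: float = DEFAULT_OD_FLOOR):
    """Per-cell expression (CPS/OD) = luminescence / OD600.

    Readings with OD at or below ``od_floor`` are flagged missing (NaN),
    never silently divided.  Scalars in, scalar out.
    """
    scalar = np.isscalar(lum) and np.isscalar(od)
    lum_a, od_a = np.broadcast_arrays(
        np.atleast_1d(np.asarray(lum, dtype=float)),
        np.atleast_1d(np.asarray(od, dtype=float)),
    )
    if np.any(lum_a[np.isfinite(lum_a)] < 0):
        raise ValueError("luminescence must be >= 0")
    valid = np.isfinite(od_a) & (od_a > od_floor) & np.isfinite(lum_a)
    out = np.full(lum_a.shape, np.nan)
    out[valid] = lum_a[valid] / od_a[valid]
    return float(out[0]) if scalar else out


def repression_forward(activity, cal: ReporterCalibration):
    """Reporter expression at a given factor activity: alpha/(1+a) + T.

    Strictly decreasing in activity; range (basal_T, basal_T + alpha_rep].
    """
    a = np.asarray(activity, dtype=float)
    if np.any(~np.isfinite(a)) or np.any(a < 0):
        raise ValueError("activity must be finite and >= 0")
    out = cal.alpha_rep / (1.0 + a) + cal.basal_T
    return float(out) if np.isscalar(activity) else out


def infer_activity(expression, cal: ReporterCalibration):
    """Invert the repression curve: a = alpha_rep/(S - basal_T) - 1.

    Negative solutions (expression above the fully-unrepressed level) are
    clamped to 0; expression at or below the basal plateau maps to the
    activity cap with a warning, since the inversion diverges there.  NaN
    (missing) readings propagate as NaN.
    """
    s = np.asarray(expression, dtype=float)
    if np.any(np.isinf(s)):
        raise ValueError("expression must be finite (or NaN for missing)")
    flat = s.ravel() if s.ndim else s.reshape(1)
    out = np.full(flat.shape, np.nan)
    valid = np.isfinite(flat)
    above = valid & (flat > cal.basal_T)
    below = valid & ~above
    out[above] = cal.alpha_rep / (flat[above] - cal.basal_T) - 1.0
    if below.any():
        warnings.warn(
            f"{int(below.sum())} expression value(s) at or below the basal level; "
            "activity set to the cap",
            stacklevel=2,
        )
        out[below] = cal.activity_cap
    out[valid] = np.clip(out[valid], 0.0, cal.activity_cap)
    return float(out[0]) if np.isscalar(expression) else out.reshape(s.shape)


def calibrate_reporter(
    values: Sequence[float],
    trim_q: float = 0.0,
    activity_cap: float = DEFAULT_ACTIVITY_CAP,
) -> ReporterCalibration:
    """Estimate (alpha_rep, basal_T) from expression spanning the full range.

    basal_T is the robust minimum (quantile ``trim_q``) — the fully-repressed
    plateau — and alpha_rep the robust maximum minus basal_T: the activation
    span is by definition the difference between fully-unrepressed and
    fully-repressed expression.  Requires a real dynamic range.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least two finite expression values")
    lo = float(np.quantile(v, trim_q))
    hi = float(np.quantile(v, 1.0 - trim_q))
    if hi <= lo:
        raise ValueError("calibration failure: no dynamic range (max <= min)")
    return ReporterCalibration(alpha_rep=hi - lo, basal_T=lo, activity_cap=activity_cap)


class RepressionReporter(TransformerMixin, BaseEstimator):
    """Repression-reporter calibration and activity inference as a transformer.

    ``fit`` learns the activation span and basal level from expression values
    spanning uninduced and fully induced conditions (or accepts them as
    parameters); ``transform`` maps expression to clamped factor activity and
    ``inverse_transform`` maps activity back to expression.

    Parameters
    ----------
    alpha_rep, basal_T : float or None
        If both given, ``fit`` validates and stores them without estimation.
    activity_cap : float
        Upper clamp for inferred activity.
    trim_q : float
        Quantile used for the robust min/max during calibration.

    Attributes
    ----------
    calibration_ : ReporterCalibration
    alpha_rep_, basal_T_ : float
    """

    def __init__(
        self,
        alpha_rep: float | None = None,
        basal_T: float | None = None,
        activity_cap: float = DEFAULT_ACTIVITY_CAP,
        trim_q: float = 0.0,
    ):
        self.alpha_rep = alpha_rep
        self.basal_T = basal_T
        self.activity_cap = activity_cap
        self.trim_q = trim_q

    def fit(self, X, y=None):
        values = np.asarray(X, dtype=float).ravel()
        if self.alpha_rep is not None:
            cal = ReporterCalibration(
                alpha_rep=self.alpha_rep,
                basal_T=0.0 if self.basal_T is None else self.basal_T,
                activity_cap=self.activity_cap,
            )
        else:
            cal = calibrate_reporter(values, trim_q=self.trim_q, activity_cap=self.activity_cap)
        self.calibration_ = cal
        self.alpha_rep_ = cal.alpha_rep
        self.basal_T_ = cal.basal_T
        return self

    def transform(self, X):
        self._check_fitted()
        shape = np.asarray(X, dtype=float).shape
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = infer_activity(np.asarray(X, dtype=float), self.calibration_)
        return np.asarray(out).reshape(shape)

    def inverse_transform(self, X):
        self._check_fitted()
        return repression_forward(np.asarray(X, dtype=float), self.calibration_)

    def _check_fitted(self) -> None:
        if not hasattr(self, "calibration_"):
            raise AttributeError("RepressionReporter is not fitted yet; call fit first")
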