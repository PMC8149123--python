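"""FRAP normalization, two-phase association fitting, and derived metrics.

The recovery of a photobleached actin cap is normalized against unbleached
reference caps and a background level:

    Y(X) = ((bleached intensity - background) * bleached area)
           / mean_refs((reference intensity - background) * reference area)

and fitted to a two-phase association with the intensity immediately after
the bleach, Y0 = Y(0), held fixed:

    Y = Y0 + SpanFast * (1 - exp(-KFast * X)) + SpanSlow * (1 - exp(-KSlow * X))
    SpanFast = (Plateau - Y0) * (pctFast / 100)
    SpanSlow = (Plateau - Y0) * (100 - pctFast) / 100

Derived readouts:

    t50            = ln 2 / KFast                      (fast half-time)
    PlateauFast    = 2 * SpanFast * (1 - exp(-KFast * t50)) + Y0
                   (algebraically identical to Y0 + SpanFast; the two-term
                    form is evaluated verbatim and asserted against the
                    identity as an internal consistency check)
    immobile frac. = (Y_-1 - PlateauFast) / (Y_-1 - Y0)

where Y_-1 is the normalized intensity one second before the bleach. The fast
component is read as turnover of the surrounding G-actin pool; the slow
component absorbs residual cap growth over the acquisition.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .errors import FitError, MetricError, NormalizationError, ParameterError

__all__ = [
    "two_phase_association",
    "FrapTrace",
    "NormalizedFrap",
    "FrapFit",
    "FrapMetrics",
    "normalize_frap",
    "fit_two_phase",
    "derive_metrics",
]


def two_phase_association(x, y0, plateau, pct_fast, k_fast, k_slow):
    """Evaluate the two-phase association model at times ``x`` (seconds)."""
    x = np.asarray(x, dtype=float)
    span = plateau - y0
    span_fast = span * pct_fast * 0.01
    span_slow = span * (100.0 - pct_fast) * 0.01
    return (y0
            + span_fast * (1.0 - np.exp(-k_fast * x))
            + span_slow * (1.0 - np.exp(-k_slow * x)))


@dataclass
class FrapTrace:
    """Raw FRAP series: a prebleach row at t = -1 s and postbleach rows from 0 s.

    ``data`` columns: ``time_s``, ``bleach_int``, ``bleach_area``,
    ``ref{i}_int``/``ref{i}_area`` for i = 1..n_ref, ``background``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"time_s", "bleach_int", "bleach_area", "background"}
        missing = required - set(self.data.columns)
        if missing:
            raise ParameterError(f"FRAP trace missing columns {sorted(missing)}")
        if self.n_ref < 1:
            raise ParameterError("FRAP trace needs at least one reference cap")
        post = self.data[self.data["time_s"] >= 0]
        x = post["time_s"].to_numpy(float)
        if len(x) < 2 or not np.all(np.diff(x) > 0) or abs(x[0]) > 1e-9:
            raise ParameterError("postbleach times must strictly increase from 0")
        areas = [self.data["bleach_area"]] + [self.data[f"ref{i}_area"]
                                             for i in range(1, self.n_ref + 1)]
        if any((a.to_numpy(float) <= 0).any() for a in areas):
            raise ParameterError("all cap areas must be > 0")

    @property
    def n_ref(self) -> int:
        i = 1
        while f"ref{i}_int" in self.data.columns and f"ref{i}_area" in self.data.columns:
            i += 1
        return i - 1

    @property
    def prebleach(self) -> pd.Series | None:
        pre = self.data[self.data["time_s"] < 0]
        return None if pre.empty else pre.iloc[-1]

    @classmethod
    def from_csv(cls, path) -> "FrapTrace":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class NormalizedFrap:
    """Normalized recovery curve: times X (s, from bleach) and Y(X)."""

    x: np.ndarray
    y: np.ndarray
    y_minus1: float


def _norm_products(rows: pd.DataFrame, n_ref: int) -> tuple[np.ndarray, np.ndarray]:
    bg = rows["background"].to_numpy(float)
    num = (rows["bleach_int"].to_numpy(float) - bg) * rows["bleach_area"].to_numpy(float)
    refs = [
        (rows[f"ref{i}_int"].to_numpy(float) - bg) * rows[f"ref{i}_area"].to_numpy(float)
        for i in range(1, n_ref + 1)
    ]
    return num, np.mean(refs, axis=0)


def normalize_frap(trace: FrapTrace, *, rescale_prebleach: bool = False) -> NormalizedFrap:
    """Apply reference-cap normalization to a raw FRAP trace.

    The denominator is the mean over reference caps of
    (intensity - background) * area; Y_-1 is computed identically from the
    prebleach row. With ``rescale_prebleach`` the whole series is divided by
    Y_-1 so that the prebleach level is 1.
    """
    post = trace.data[trace.data["time_s"] >= 0]
    num, den = _norm_products(post, trace.n_ref)
    bad = np.flatnonzero(den <= 0)
    if bad.size:
        raise NormalizationError(
            f"non-positive reference denominator at frame index {bad[0]} "
            f"(t = {post['time_s'].iloc[bad[0]]} s)")
    y = num / den
    x = post["time_s"].to_numpy(float)

    pre = trace.prebleach
    if pre is None:
        raise NormalizationError("FRAP trace has no prebleach (t < 0) row")
    pre_num, pre_den = _norm_products(pre.to_frame().T, trace.n_ref)
    if pre_den[0] <= 0:
        raise NormalizationError("non-positive reference denominator at prebleach frame")
    y_minus1 = float(pre_num[0] / pre_den[0])

    if rescale_prebleach:
        if y_minus1 <= 0:
            raise NormalizationError("cannot rescale: prebleach value <= 0")
        y = y / y_minus1
        y_minus1 = 1.0
    return NormalizedFrap(x=x, y=y, y_minus1=y_minus1)


@dataclass(frozen=True)
class FrapFit:
    """Fitted two-phase association parameters (Y0 fixed to Y at X = 0)."""

    y0: float
    plateau: float
    pct_fast: float
    k_fast: float
    k_slow: float
    residual_norm: float
    converged: bool
    single_phase: bool = False

    @property
    def span_fast(self) -> float:
        return (self.plateau - self.y0) * self.pct_fast * 0.01

    @property
    def span_slow(self) -> float:
        return (self.plateau - self.y0) * (100.0 - self.pct_fast) * 0.01

    @property
    def t50(self) -> float:
        """Half-time of the fast component, ln 2 / KFast (seconds)."""
        return math.log(2.0) / self.k_fast if np.isfinite(self.k_fast) else math.nan

    @property
    def plateau_fast(self) -> float:
        """2 * SpanFast * (1 - exp(-KFast * t50)) + Y0, evaluated verbatim."""
        if not np.isfinite(self.k_fast):
            return self.y0 + self.span_fast
        return 2.0 * self.span_fast * (1.0 - math.exp(-self.k_fast * self.t50)) + self.y0

    def predict(self, x) -> np.ndarray:
        if not np.isfinite(self.k_fast):
            return np.full_like(np.asarray(x, float), self.y0)
        return two_phase_association(x, self.y0, self.plateau, self.pct_fast,
                                     self.k_fast, self.k_slow)

    def to_dict(self) -> dict:
        return {
            "y0": self.y0, "plateau": self.plateau, "pct_fast": self.pct_fast,
            "k_fast": self.k_fast, "k_slow": self.k_slow,
            "span_fast": self.span_fast, "span_slow": self.span_slow,
            "t50_s": self.t50, "plateau_fast": self.plateau_fast,
            "residual_norm": self.residual_norm, "converged": self.converged,
            "single_phase": self.single_phase,
        }


# fixed multi-start grid: log-spaced fast rates crossed with rate ratios
_KFAST_STARTS = np.geomspace(0.02, 1.0, 5)
_RATIO_STARTS = (1.0 / 3.0, 0.1, 1.0 / 30.0)


def fit_two_phase(x, y, *, min_samples: int = 8, min_pct_fast: float = 50.0,
                  min_rate_ratio: float = 10.0) -> FrapFit:
    """Fit the two-phase association to a normalized recovery curve.

    Y0 is held fixed at Y(0). The remaining parameters (Plateau, pctFast,
    KFast, KSlow) are estimated by bounded least squares from a fixed
    multi-start grid; deterministic (no randomness).

    Two nearly equal rate constants make the decomposition unidentifiable, so
    the model is made identifiable by construction: the fast component must
    carry at least ``min_pct_fast`` percent of the recovery (the slow phase
    represents *minor* residual cap growth) and KFast/KSlow >=
    ``min_rate_ratio``, enforced by fitting KSlow as KFast times a bounded
    ratio. Set ``min_pct_fast=0`` / ``min_rate_ratio=1`` to lift the
    constraints.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ParameterError("x and y must be 1D arrays of equal length")
    if len(x) < min_samples:
        raise ParameterError(f"need >= {min_samples} samples, got {len(x)}")
    if abs(x[0]) > 1e-9 or not np.all(np.diff(x) > 0):
        raise ParameterError("x must strictly increase from 0")
    if not 0 <= min_pct_fast <= 100 or min_rate_ratio < 1:
        raise ParameterError("need 0 <= min_pct_fast <= 100 and min_rate_ratio >= 1")
    y0 = float(y[0])

    if np.ptp(y) < 1e-12 * max(1.0, abs(y0)):
        # constant data: flagged single-phase fallback, no recovery
        return FrapFit(y0=y0, plateau=y0, pct_fast=100.0, k_fast=math.nan,
                       k_slow=math.nan, residual_norm=0.0, converged=True,
                       single_phase=True)

    span_guess = max(float(np.max(y) - y0), 1e-6)
    span_hi = max(10.0 * span_guess, 10.0)

    def resid(theta):
        span, frac, kf, rho = theta
        model = (y0 + span * (frac * (1.0 - np.exp(-kf * x))
                              + (1.0 - frac) * (1.0 - np.exp(-kf * rho * x))))
        return model - y

    best = None
    f_lo = min_pct_fast / 100.0
    lower = np.array([0.0, f_lo, 1e-4, 1e-6])
    upper = np.array([span_hi, 1.0, 50.0, 1.0 / min_rate_ratio])
    for kf0 in _KFAST_STARTS:
        for rho0 in _RATIO_STARTS:
            theta0 = np.clip(np.array([span_guess, max(0.75, f_lo), kf0, rho0]),
                             lower, upper)
            try:
                res = least_squares(resid, theta0, bounds=(lower, upper),
                                    method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                    max_nfev=5000)
            except Exception:  # numerical failure from this start; try next
                continue
            # iteration-limited runs (flat directions) still carry their best
            # point; rank every start by cost and report convergence honestly
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise FitError("two-phase fit failed to converge from every start")

    span, frac, kf, rho = best.x
    ks = kf * rho
    # a slow component contributing nothing over the observation window is
    # unidentifiable; collapse it so pctFast reflects the identifiable model
    slow_contrib = span * (1.0 - frac) * (1.0 - math.exp(-ks * x[-1]))
    if slow_contrib <= 1e-6 * max(span, 1e-6):
        frac = 1.0
    converged = bool(best.success or best.cost <= 1e-12 * len(x))
    return FrapFit(y0=y0, plateau=y0 + float(span), pct_fast=100.0 * float(frac),
                   k_fast=float(kf), k_slow=float(ks),
                   residual_norm=float(np.linalg.norm(best.fun)),
                   converged=converged)


@dataclass(frozen=True)
class FrapMetrics:
    """Derived FRAP readouts."""

    t50_s: float
    plateau_fast: float
    immobile_fraction: float
    t_half_total_s: float

    def to_dict(self) -> dict:
        return {"t50_s": self.t50_s, "plateau_fast": self.plateau_fast,
                "immobile_fraction": self.immobile_fraction,
                "t_half_total_s": self.t_half_total_s}


def derive_metrics(fit: FrapFit, y_minus1: float) -> FrapMetrics:
    """Compute t50, PlateauFast and the immobile fraction from a fit.

    Also emits the secondary half-time at which the *total* recovery reaches
    half of (Plateau - Y0).
    """
    if y_minus1 <= fit.y0:
        raise MetricError(
            f"prebleach Y_-1 ({y_minus1:.4g}) must exceed Y0 ({fit.y0:.4g})")
    plateau_fast = fit.plateau_fast
    identity = fit.y0 + fit.span_fast
    if abs(plateau_fast - identity) > 1e-12 * max(1.0, abs(identity)):
        raise MetricError("PlateauFast identity violated; fit parameters inconsistent")
    immobile = (y_minus1 - plateau_fast) / (y_minus1 - fit.y0)

    if fit.single_phase and not np.isfinite(fit.k_fast):
        t_half_total = math.nan
    else:
        target = fit.y0 + 0.5 * (fit.plateau - fit.y0)
        if fit.plateau - fit.y0 <= 0:
            t_half_total = math.nan
        else:
            hi = 10.0 / max(fit.k_slow, 1e-9)
            t_half_total = float(brentq(lambda t: float(fit.predict(t)) - target,
                                        0.0, hi, xtol=1e-12))
    return FrapMetrics(t50_s=fit.t50, plateau_fast=plateau_fast,
                       immobile_fraction=float(immobile),
                       t_half_total_s=t_half_total)
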