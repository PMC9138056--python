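"""First-order one-compartment isotope incorporation models and derived metrics.

After a diet switch, the isotopic composition of consumer tissue relaxes from
its initial value ``delta_i`` toward equilibrium with the new diet
(``delta_eq``).  Two standard parameterizations of this relaxation are
implemented as pure functions on typed parameters:

* **Model G** (growth-based): ``delta = delta_eq + a * W_R ** c`` where ``W_R``
  is the fold-increase in body mass since the switch.  ``c = -1`` corresponds
  to pure growth dilution (old tissue diluted by new); ``c < -1`` indicates an
  additional metabolic contribution to turnover.
* **Model D** (time-based): ``delta = delta_eq + a * exp(-(m + k) * t)`` where
  ``t`` is days since the switch, ``k`` the exponential growth rate and ``m``
  the metabolic turnover constant.

From fitted parameters the module derives turnover milestones (``G_50``,
``G_95`` in fold biomass; ``D_50``, ``D_95`` in days), the growth/metabolism
partition of turnover (``P_g``, ``P_m``), and diet-tissue discrimination
factors (``delta_eq - delta_diet``).  All deltas are per-mil (permil)
values relative to VPDB (carbon) or atmospheric N2 (nitrogen).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("isoturn")

ISOTOPES = ("d13C", "d15N")

#: Loose plausibility windows (permil) for flagging, not rejecting, values.
PLAUSIBLE_RANGE = {"d13C": (-60.0, 10.0), "d15N": (-20.0, 40.0)}

DEFAULT_ALPHA_LEVELS = (50.0, 95.0)


class ImplausibleIsotopeWarning(UserWarning):
    """A delta value lies outside the loose plausibility window for its isotope."""


@dataclass(frozen=True)
class IsotopeValue:
    """A delta value (permil) tagged with its isotope system.

    Values outside the plausible window are flagged with a warning but kept:
    unusual samples (e.g. lipid-rich or contaminated tissue) are a data-quality
    question, not a hard error.
    """

    value: float
    isotope: str

    def __post_init__(self) -> None:
        if self.isotope not in ISOTOPES:
            raise ValueError(f"unknown isotope {self.isotope!r}; expected one of {ISOTOPES}")
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite {self.isotope} value: {self.value!r}")
        lo, hi = PLAUSIBLE_RANGE[self.isotope]
        if not lo <= self.value <= hi:
            warnings.warn(
                f"{self.isotope} = {self.value:.2f} permil outside plausible range [{lo}, {hi}]",
                ImplausibleIsotopeWarning,
                stacklevel=2,
            )


@dataclass
class ModelGParams:
    """Growth-based model parameters: ``delta = delta_eq + a * W_R ** c``.

    ``a = delta_i - delta_eq`` is the initial offset from equilibrium and
    ``c`` the metabolic decay constant (``c < 0`` for a system approaching
    equilibrium; ``c = -1`` is pure dilution).
    """

    delta_eq: float
    a: float
    c: float
    se_delta_eq: float = math.nan
    se_c: float = math.nan
    r2: float = math.nan

    def __post_init__(self) -> None:
        if self.c >= 0:
            raise ValueError(f"model G requires c < 0 (equilibrium approach); got c={self.c}")


@dataclass
class ModelDParams:
    """Time-based model parameters: ``delta = delta_eq + a * exp(-(m + k) t)``.

    ``k`` (per day) is computed from dry-weight change and held fixed during
    fitting; only ``m`` is a free kinetic parameter.
    """

    delta_eq: float
    a: float
    m: float
    k: float
    se_delta_eq: float = math.nan
    se_m: float = math.nan
    r2: float = math.nan

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"growth rate k must be >= 0; got {self.k}")
        if self.m + self.k <= 0:
            raise ValueError(f"model D requires m + k > 0; got m+k={self.m + self.k}")


@dataclass(frozen=True)
class WeightRatio:
    """Dry weight at sampling relative to dry weight at the diet switch."""

    w_i: float  # mg at switch
    w_t: float  # mg at sampling
    w_r: float = field(init=False)

    def __post_init__(self) -> None:
        if self.w_i <= 0 or self.w_t <= 0:
            raise ValueError(f"weights must be positive; got w_i={self.w_i}, w_t={self.w_t}")
        object.__setattr__(self, "w_r", self.w_t / self.w_i)


@dataclass
class TurnoverMetrics:
    """Turnover milestones and the growth/metabolism partition for one fit."""

    g50: float
    g95: float
    d50: float
    d95: float
    p_g: float
    p_m: float
    alpha_levels: tuple[float, float] = DEFAULT_ALPHA_LEVELS


@dataclass
class DiscriminationResult:
    """Diet-tissue discrimination factor ``delta_eq - delta_diet`` (permil)."""

    delta_delta: float
    delta_eq_used: float
    delta_diet: float
    isotope: str
    model_tag: str = ""
    average_across_models: tuple[float, float] | None = None  # (mean, sd)


# --- model predictions -------------------------------------------------------

def predict_model_g(params: ModelGParams, w_r):
    """Predicted delta (permil) at relative mass increase ``w_r`` (model G)."""
    w_r = np.asarray(w_r, dtype=float)
    if np.any(w_r <= 0):
        raise ValueError("w_r must be positive (fractional power of non-positive base)")
    out = params.delta_eq + params.a * w_r ** params.c
    return float(out) if out.ndim == 0 else out


def predict_model_d(params: ModelDParams, t):
    """Predicted delta (permil) at ``t`` days after the diet switch (model D)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0: the model is undefined before the switch")
    out = params.delta_eq + params.a * np.exp(-(params.m + params.k) * t)
    return float(out) if out.ndim == 0 else out


# --- closed-form derived quantities -----------------------------------------

def growth_rate_k(w_i: float, w_t: float, t: float) -> float:
    """Exponential growth rate ``k = ln(w_t / w_i) / t`` (per day)."""
    if w_i <= 0 or w_t <= 0:
        raise ValueError(f"weights must be positive; got w_i={w_i}, w_t={w_t}")
    if t <= 0:
        raise ValueError(f"elapsed time must be positive; got t={t}")
    return math.log(w_t / w_i) / t


def _check_alpha(alpha: float) -> None:
    if not 0 < alpha < 100:
        raise ValueError(f"alpha must be a percentage in (0, 100); got {alpha}")


def turnover_weight_fold(c: float, alpha: float = 50.0) -> float:
    """Fold biomass increase at which alpha% of the isotopic shift is complete.

    ``G_alpha = exp(ln(1 - alpha/100) / c)`` for model G; equals 2 at
    alpha = 50 under pure dilution (c = -1).
    """
    if c >= 0:
        raise ValueError(f"c must be negative for an equilibrium approach; got {c}")
    _check_alpha(alpha)
    return math.exp(math.log(1.0 - alpha / 100.0) / c)


def turnover_days(m: float, k: float, alpha: float = 50.0) -> float:
    """Days after the switch at which alpha% of the isotopic shift is complete.

    ``D_alpha = |ln(1 - alpha/100)| / (m + k)`` for model D.  The absolute
    value makes the time positive (the log of a fraction is negative).
    """
    if m + k <= 0:
        raise ValueError(f"m + k must be positive; got {m + k}")
    _check_alpha(alpha)
    return abs(math.log(1.0 - alpha / 100.0)) / (m + k)


def partition_turnover(g50: float) -> tuple[float, float]:
    """Growth (``P_g``) and metabolic (``P_m``) fractions of tissue turnover.

    ``P_g = 2 (G_50 - 1) / G_50`` and ``P_m = (2 - G_50) / G_50``.  Under pure
    dilution G_50 = 2 and turnover is all growth; G_50 > 2 gives a raw
    negative P_m, which is clipped to 0 (no metabolic contribution) with
    ``P_g = 1 - P_m`` so the fractions always sum to 1.
    """
    if g50 < 1:
        raise ValueError(f"g50 must be >= 1 (no turnover before any growth); got {g50}")
    p_m = (2.0 - g50) / g50
    p_m = min(max(p_m, 0.0), 1.0)
    return 1.0 - p_m, p_m


def discrimination_factor(
    delta_eq: float | IsotopeValue,
    delta_diet: float | IsotopeValue,
    isotope: str | None = None,
    model_tag: str = "",
) -> DiscriminationResult:
    """Diet-tissue discrimination factor ``Delta-delta = delta_eq - delta_diet``.

    Accepts plain floats (with ``isotope`` supplied) or :class:`IsotopeValue`
    pairs, which must agree on the isotope system.
    """
    iso_eq = delta_eq.isotope if isinstance(delta_eq, IsotopeValue) else isotope
    iso_diet = delta_diet.isotope if isinstance(delta_diet, IsotopeValue) else isotope
    if iso_eq is None or iso_diet is None:
        raise ValueError("isotope must be given when passing bare floats")
    if iso_eq != iso_diet:
        raise ValueError(f"isotope mismatch: equilibrium is {iso_eq}, diet is {iso_diet}")
    eq = delta_eq.value if isinstance(delta_eq, IsotopeValue) else float(delta_eq)
    diet = delta_diet.value if isinstance(delta_diet, IsotopeValue) else float(delta_diet)
    if not (math.isfinite(eq) and math.isfinite(diet)):
        raise ValueError("delta values must be finite")
    return DiscriminationResult(
        delta_delta=eq - diet,
        delta_eq_used=eq,
        delta_diet=diet,
        isotope=iso_eq,
        model_tag=model_tag,
    )


# --- weight-fold <-> chronological conversion --------------------------------

class GrowthCurve:
    """Weight-vs-time relationship used to convert turnover between scales.

    Model G expresses turnover on a weight-fold axis and model D on a day
    axis; comparing them requires the batch's growth trajectory.  Two
    interpolants are supported:

    * ``"linear-log"`` (default): monotone piecewise-linear interpolation of
      ``ln(weight)`` against day through the observed mean weights;
    * ``"exponential"``: the closed form ``W(t) = W(switch) * exp(k t)`` with
      ``k`` taken from the curve's endpoints, so
      ``days = ln(fold) / k`` exactly.

    Queries beyond the observed day range are answered by extrapolating the
    terminal segment and flagged with a warning.
    """

    def __init__(self, days, weights, switch_day: float, kind: str = "linear-log"):
        days = np.asarray(days, dtype=float)
        weights = np.asarray(weights, dtype=float)
        if days.size == 0:
            raise ValueError("empty growth curve")
        if days.size != weights.size:
            raise ValueError("days and weights must have equal length")
        if np.any(weights <= 0):
            raise ValueError("weights must be positive")
        order = np.argsort(days)
        self.days = days[order]
        self.log_w = np.log(weights[order])
        if np.any(np.diff(self.log_w) <= 0):
            raise ValueError("growth curve must be strictly increasing in weight")
        self.switch_day = float(switch_day)
        if not (self.days[0] <= switch_day <= self.days[-1]):
            raise ValueError("switch day outside the observed day range")
        if kind not in ("linear-log", "exponential"):
            raise ValueError(f"unknown interpolant kind {kind!r}")
        self.kind = kind
        self._log_w_switch = float(np.interp(switch_day, self.days, self.log_w))
        # endpoint growth rate, used by the exponential interpolant
        self.k = (self.log_w[-1] - self._log_w_switch) / (self.days[-1] - switch_day)

    @classmethod
    def exponential(cls, w0: float, k: float, switch_day: float, final_day: float) -> "GrowthCurve":
        """Pure-exponential curve from an initial weight and growth rate."""
        if k <= 0:
            raise ValueError("exponential curve needs k > 0")
        days = np.array([switch_day, final_day], dtype=float)
        return cls(days, w0 * np.exp(k * (days - switch_day)), switch_day, kind="exponential")

    def _warn_extrapolation(self, day: float) -> None:
        if not (self.days[0] <= day <= self.days[-1]):
            warnings.warn(
                f"day {day:.1f} outside observed range [{self.days[0]:.0f}, {self.days[-1]:.0f}]; extrapolating",
                UserWarning,
                stacklevel=3,
            )

    def weight_fold_to_days(self, fold: float) -> float:
        """Days after the switch to reach a given fold-increase in weight."""
        if fold < 1:
            raise ValueError(f"fold must be >= 1; got {fold}")
        if self.kind == "exponential":
            return math.log(fold) / self.k
        target = self._log_w_switch + math.log(fold)
        if target > self.log_w[-1]:  # extrapolate terminal segment
            slope = (self.log_w[-1] - self.log_w[-2]) / (self.days[-1] - self.days[-2])
            day = self.days[-1] + (target - self.log_w[-1]) / slope
        else:
            day = float(np.interp(target, self.log_w, self.days))
        self._warn_extrapolation(day)
        return day - self.switch_day

    def days_to_weight_fold(self, days_after_switch: float) -> float:
        """Fold-increase in weight attained a given number of days after the switch."""
        if days_after_switch < 0:
            raise ValueError(f"days must be >= 0; got {days_after_switch}")
        if self.kind == "exponential":
            return math.exp(self.k * days_after_switch)
        day = self.switch_day + days_after_switch
        self._warn_extrapolation(day)
        if day > self.days[-1]:
            slope = (self.log_w[-1] - self.log_w[-2]) / (self.days[-1] - self.days[-2])
            log_w = self.log_w[-1] + slope * (day - self.days[-1])
        else:
            log_w = float(np.interp(day, self.days, self.log_w))
        return math.exp(log_w - self._log_w_switch)


def convert_turnover_scale(curve: GrowthCurve, value: float, direction: str) -> float:
    """Convert a turnover milestone between weight-fold and chronological scales.

    ``direction`` is ``"weight->days"`` (a ``G_alpha`` fold becomes days after
    the switch) or ``"days->weight"`` (a ``D_alpha`` day count becomes a
    fold).  The round trip is the identity up to interpolation tolerance.
    """
    if direction == "weight->days":
        return curve.weight_fold_to_days(value)
    if direction == "days->weight":
        return curve.days_to_weight_fold(value)
    raise ValueError(f"direction must be 'weight->days' or 'days->weight'; got {direction!r}")


def turnover_metrics_model_g(
    params: ModelGParams,
    curve: GrowthCurve | None = None,
    alpha_levels: tuple[float, float] = DEFAULT_ALPHA_LEVELS,
) -> TurnoverMetrics:
    """All turnover milestones and the partition from a model G fit.

    Chronological milestones require a growth curve; without one they are NaN.
    """
    a_half, a_full = alpha_levels
    g50 = turnover_weight_fold(params.c, a_half)
    g95 = turnover_weight_fold(params.c, a_full)
    if curve is not None:
        d50 = convert_turnover_scale(curve, g50, "weight->days")
        d95 = convert_turnover_scale(curve, g95, "weight->days")
    else:
        d50 = d95 = math.nan
    p_g, p_m = partition_turnover(g50)
    return TurnoverMetrics(g50, g95, d50, d95, p_g, p_m, alpha_levels)


def turnover_metrics_model_d(
    params: ModelDParams,
    curve: GrowthCurve | None = None,
    alpha_levels: tuple[float, float] = DEFAULT_ALPHA_LEVELS,
) -> TurnoverMetrics:
    """All turnover milestones and the partition from a model D fit.

    Weight-fold milestones are obtained through the growth curve; if none is
    given, a pure-exponential curve with the fit's own ``k`` is implied, so
    ``G_alpha = exp(k * D_alpha)``.  The partition uses the half-life fold.
    """
    a_half, a_full = alpha_levels
    d50 = turnover_days(params.m, params.k, a_half)
    d95 = turnover_days(params.m, params.k, a_full)
    if curve is None:
        g50 = math.exp(params.k * d50)
        g95 = math.exp(params.k * d95)
    else:
        g50 = convert_turnover_scale(curve, d50, "days->weight")
        g95 = convert_turnover_scale(curve, d95, "days->weight")
    p_g, p_m = partition_turnover(g50)
    return TurnoverMetrics(g50, g95, d50, d95, p_g, p_m, alpha_levels)
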