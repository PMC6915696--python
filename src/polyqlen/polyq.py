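"""PolyQ-length calibration: ratio-vs-Q regression, inversion, propagation.

The polyQ-antibody / total-antibody signal ratio grows with the length of the
polyglutamine tract because bivalent polyQ-targeting antibodies bind more
epitopes on longer tracts (avidity bias).  Calibrating ratio against known Q
with purified standards gives a monotone curve r = f(Q); inverting it maps a
measured ratio (with its SD) to an average polyQ length estimate for a mixed
protein population measured in the assay's linear range.

Four candidate regression families are fitted by least squares on the ratio
scale and the one with the highest R^2 is kept:

    linear       r = a + b*Q
    exponential  r = a * exp(b*Q)
    logarithmic  r = a + b*ln(Q)
    power        r = a * Q^b

Each family has a closed-form inverse Q = f^-1(r); measurement uncertainty is
propagated to the length estimate by the delta method,
sd_Q = sd_r * |dQ/dr|, with an optional Monte-Carlo inversion for nonlinear
families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml
from scipy.optimize import least_squares

from .fourpl import FourPLFitResult, FourPLParams

__all__ = [
    "CalibrationModel",
    "PolyQCalibrator",
    "PolyQEstimate",
    "ParamTrendModel",
    "FAMILIES",
    "select_regression_model",
    "estimate_average_polyq",
    "propagate_ratio_sd",
    "predict_fold_increase",
    "fit_param_trends",
    "predict_curve_for_q",
]

FAMILIES = ("linear", "logarithmic", "power", "exponential")  # tie-break order


def _family_eval(family: str, a: float, b: float, q):
    q = np.asarray(q, dtype=float)
    if family == "linear":
        return a + b * q
    if family == "exponential":
        return a * np.exp(b * q)
    if family == "logarithmic":
        return a + b * np.log(q)
    if family == "power":
        return a * np.power(q, b)
    raise ValueError(f"unknown family {family!r}")


def _family_invert(family: str, a: float, b: float, r: float) -> float:
    if family == "linear":
        return (r - a) / b
    if family == "exponential":
        if r / a <= 0:
            raise ValueError(f"ratio {r} not invertible under exponential model")
        return math.log(r / a) / b
    if family == "logarithmic":
        return math.exp((r - a) / b)
    if family == "power":
        if r / a <= 0:
            raise ValueError(f"ratio {r} not invertible under power model")
        return (r / a) ** (1.0 / b)
    raise ValueError(f"unknown family {family!r}")


def _inverse_derivative(family: str, a: float, b: float, r: float, q: float) -> float:
    """dQ/dr at the inverse point (delta-method factor)."""
    if family == "linear":
        return 1.0 / b
    if family == "exponential":
        return 1.0 / (b * r)
    if family == "logarithmic":
        return q / b
    if family == "power":
        return q / (b * r)
    raise ValueError(f"unknown family {family!r}")


@dataclass
class CalibrationModel:
    """A fitted ratio-vs-polyQ-length regression with its closed-form inverse."""

    family: str
    a: float
    b: float
    r_squared: float
    q_domain: tuple[float, float]
    ratio_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.b == 0:
            raise ValueError("degenerate model: b = 0 is not monotone in Q")

    def __call__(self, q):
        return _family_eval(self.family, self.a, self.b, q)

    def inverse(self, ratio: float) -> float:
        return _family_invert(self.family, self.a, self.b, ratio)

    # -- lossless text round trip (YAML-compatible key-value) --------------
    def to_yaml(self) -> str:
        doc = {
            "family": self.family,
            "a": float(self.a),
            "b": float(self.b),
            "r_squared": float(self.r_squared),
            "q_domain": [float(v) for v in self.q_domain],
            "ratio_range": [float(v) for v in self.ratio_range],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CalibrationModel":
        doc = yaml.safe_load(text)
        return cls(
            family=doc["family"],
            a=float(doc["a"]),
            b=float(doc["b"]),
            r_squared=float(doc["r_squared"]),
            q_domain=tuple(doc["q_domain"]),
            ratio_range=tuple(doc["ratio_range"]),
        )


@dataclass
class PolyQEstimate:
    q_mean: float
    q_sd: float
    extrapolated: bool

    def __post_init__(self) -> None:
        if self.q_sd < 0:
            raise ValueError("q_sd must be >= 0")


def _fit_family(family: str, q: np.ndarray, r: np.ndarray) -> tuple[float, float, float]:
    """Least-squares fit of one family on the response scale; returns (a, b, sse)."""
    if family == "linear":
        X = np.column_stack([np.ones_like(q), q])
        coef, *_ = np.linalg.lstsq(X, r, rcond=None)
        a, b = float(coef[0]), float(coef[1])
    elif family == "logarithmic":
        X = np.column_stack([np.ones_like(q), np.log(q)])
        coef, *_ = np.linalg.lstsq(X, r, rcond=None)
        a, b = float(coef[0]), float(coef[1])
    else:
        # log-linear closed form as the start, then response-scale refinement
        lr = np.log(r)
        x = q if family == "exponential" else np.log(q)
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, lr, rcond=None)
        a0, b0 = float(np.exp(coef[0])), float(coef[1])

        def resid(theta):
            return _family_eval(family, theta[0], theta[1], q) - r

        sol = least_squares(resid, np.array([a0, b0]), max_nfev=1000)
        a, b = float(sol.x[0]), float(sol.x[1])
    sse = float(np.sum((_family_eval(family, a, b, q) - r) ** 2))
    return a, b, sse


class DegenerateDataError(ValueError):
    """Responses have no variance; no family can be selected."""


class PolyQCalibrator:
    """Scikit-learn style estimator for the ratio = f(Q) calibration.

    ``fit(Q, ratio)`` fits all candidate families by least squares and keeps
    the one with the highest R^2 (ties within ``tie_tol`` broken by the order
    linear > logarithmic > power > exponential).  ``predict(Q)`` evaluates the
    calibration; ``estimate(ratio, ratio_sd)`` inverts it to an average polyQ
    length with delta-method (or Monte-Carlo) uncertainty.

    Attributes after fit: ``model_`` (CalibrationModel), ``family_``,
    ``r_squared_``, ``candidate_r_squared_`` (per-family dict).
    """

    def __init__(self, tie_tol: float = 1e-9, mc_inversion: bool = False,
                 mc_draws: int = 100_000, random_state: int | None = 0):
        self.tie_tol = tie_tol
        self.mc_inversion = mc_inversion
        self.mc_draws = mc_draws
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "tie_tol": self.tie_tol,
            "mc_inversion": self.mc_inversion,
            "mc_draws": self.mc_draws,
            "random_state": self.random_state,
        }

    def set_params(self, **kw) -> "PolyQCalibrator":
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "PolyQCalibrator":
        q = np.asarray(X, dtype=float).ravel()
        r = np.asarray(y, dtype=float).ravel()
        if q.shape != r.shape:
            raise ValueError("Q and ratio arrays must have equal length")
        if len(set(q.tolist())) < 3:
            raise ValueError("calibration requires >= 3 distinct Q values")
        if np.any(q <= 0):
            raise ValueError("Q values must be > 0 (log/power families)")
        sstot = float(np.sum((r - r.mean()) ** 2))
        if sstot == 0:
            raise DegenerateDataError("zero response variance across Q")

        self.candidate_r_squared_ = {}
        fits = {}
        for family in FAMILIES:
            if family in ("exponential", "power") and np.any(r <= 0):
                continue  # positive-response families
            try:
                a, b, sse = _fit_family(family, q, r)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if b == 0 or not (np.isfinite(a) and np.isfinite(b)):
                continue
            r2 = 1.0 - sse / sstot
            self.candidate_r_squared_[family] = r2
            fits[family] = (a, b, r2)
        if not fits:
            raise DegenerateDataError("no candidate family produced a valid fit")

        best_r2 = max(r2 for _, _, r2 in fits.values())
        # first family (in FAMILIES order) within tie_tol of the best wins
        family = next(f for f in FAMILIES if f in fits and fits[f][2] >= best_r2 - self.tie_tol)
        a, b, r2 = fits[family]
        ratios = _family_eval(family, a, b, q)
        self.model_ = CalibrationModel(
            family=family,
            a=a,
            b=b,
            r_squared=max(0.0, min(1.0, r2)),
            q_domain=(float(q.min()), float(q.max())),
            ratio_range=(float(min(r.min(), ratios.min())), float(max(r.max(), ratios.max()))),
        )
        self.family_ = family
        self.r_squared_ = self.model_.r_squared
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return np.asarray(self.model_(X), dtype=float)

    def estimate(self, ratio: float, ratio_sd: float = 0.0) -> PolyQEstimate:
        self._check_fitted()
        return estimate_average_polyq(
            ratio, ratio_sd, self.model_,
            mc_inversion=self.mc_inversion,
            mc_draws=self.mc_draws,
            random_state=self.random_state,
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("calibrator is not fitted")


def select_regression_model(q_values, responses, tie_tol: float = 1e-9) -> CalibrationModel:
    """Fit the candidate families and return the highest-R^2 model."""
    return PolyQCalibrator(tie_tol=tie_tol).fit(q_values, responses).model_


def estimate_average_polyq(
    ratio: float,
    ratio_sd: float,
    model: CalibrationModel,
    mc_inversion: bool = False,
    mc_draws: int = 100_000,
    random_state: int | None = 0,
) -> PolyQEstimate:
    """Invert the calibration: measured signal ratio -> average polyQ length.

    Uncertainty: first-order (delta-method) by default,
    sd_Q = sd_r * |dQ/dr| at the estimate; ``mc_inversion=True`` instead
    inverts Monte-Carlo draws of the ratio (useful for nonlinear families at
    large relative SDs).
    """
    if ratio_sd < 0:
        raise ValueError("ratio_sd must be >= 0")
    q = model.inverse(ratio)
    lo, hi = model.ratio_range
    extrapolated = not (lo <= ratio <= hi)
    if ratio_sd == 0:
        return PolyQEstimate(q_mean=q, q_sd=0.0, extrapolated=extrapolated)
    if mc_inversion:
        rng = np.random.default_rng(random_state)
        draws = rng.normal(ratio, ratio_sd, size=mc_draws)
        qs = []
        for rv in draws:
            try:
                qs.append(model.inverse(float(rv)))
            except ValueError:
                continue
        qs = np.asarray(qs)
        return PolyQEstimate(q_mean=float(qs.mean()), q_sd=float(qs.std(ddof=1)),
                             extrapolated=extrapolated)
    q_sd = ratio_sd * abs(_inverse_derivative(model.family, model.a, model.b, ratio, q))
    return PolyQEstimate(q_mean=q, q_sd=q_sd, extrapolated=extrapolated)


def propagate_ratio_sd(a: float, sd_a: float, b: float, sd_b: float) -> tuple[float, float]:
    """SD of a ratio A/B from the SDs of A and B.

    sd(A/B) = (A/B) * sqrt((sd_A/A)^2 + (sd_B/B)^2); requires A != 0 when
    sd_A > 0 because the relative error of A is otherwise undefined.
    """
    if b == 0:
        raise ZeroDivisionError("ratio denominator is zero")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be >= 0")
    if a == 0 and sd_a > 0:
        raise ValueError("relative error undefined: numerator is 0 with sd > 0")
    ratio = a / b
    rel_a = (sd_a / a) ** 2 if sd_a > 0 else 0.0
    rel_b = (sd_b / b) ** 2 if sd_b > 0 else 0.0
    return ratio, abs(ratio) * math.sqrt(rel_a + rel_b)


def predict_fold_increase(model: CalibrationModel, q_ref: float, q_values) -> np.ndarray:
    """Predicted signal fold change relative to a reference polyQ length.

    fold(Q) = f(Q) / f(q_ref) at constant protein amount; fold(q_ref) = 1.
    """
    ref = float(model(q_ref))
    if ref <= 0:
        raise ValueError(f"model value at reference Q={q_ref} is not positive ({ref})")
    return np.asarray(model(q_values), dtype=float) / ref


@dataclass
class ConstantTrend:
    """Degenerate Q-trend for a parameter with no length dependence."""

    value: float
    r_squared: float = 1.0

    def __call__(self, q):
        q = np.asarray(q, dtype=float)
        return self.value if q.ndim == 0 else np.full(q.shape, self.value)


@dataclass
class ParamTrendModel:
    """PolyQ-length dependence of the 4PL parameters across standards.

    Bottom and HillSlope are pooled (length-independent plateaus/steepness);
    Top and EC50 are strongly length-dependent and carry their own
    regression models, allowing a full dose-response curve to be predicted
    for any polyQ length in the calibrated domain.
    """

    bottom_pooled: float
    hillslope_pooled: float
    top_model: "CalibrationModel | ConstantTrend"
    ec50_model: "CalibrationModel | ConstantTrend"
    monotone_warning: bool = False


def fit_param_trends(per_q_fits: list[tuple[float, FourPLFitResult]]) -> ParamTrendModel:
    if len(per_q_fits) < 3:
        raise ValueError("parameter-trend fitting requires >= 3 Q values")
    usable = [(q, f) for q, f in per_q_fits if f.converged]
    if len(usable) < 3:
        raise ValueError("parameter-trend fitting requires >= 3 converged fits")
    qs = np.array([q for q, _ in usable], dtype=float)
    bottoms = np.array([f.params.bottom for _, f in usable])
    hills = np.array([f.params.hillslope for _, f in usable])
    tops = np.array([f.params.top for _, f in usable])
    ec50s = np.array([f.params.ec50 for _, f in usable])

    def trend(vals: np.ndarray):
        # a parameter that does not vary with Q gets a constant trend
        if np.ptp(vals) <= 1e-10 * max(1.0, abs(vals.mean())):
            return ConstantTrend(float(vals.mean()))
        return select_regression_model(qs, vals)

    top_model = trend(tops)
    ec50_model = trend(ec50s)
    grid = np.linspace(qs.min(), qs.max(), 101)
    top_grid = np.asarray(top_model(grid))
    warn = bool(np.any(np.diff(top_grid) <= 0) and np.any(np.diff(top_grid) >= 0)) and not (
        np.all(np.diff(top_grid) > 0) or np.all(np.diff(top_grid) < 0)
    )
    return ParamTrendModel(
        bottom_pooled=float(bottoms.mean()),
        hillslope_pooled=float(hills.mean()),
        top_model=top_model,
        ec50_model=ec50_model,
        monotone_warning=warn,
    )


def predict_curve_for_q(trends: ParamTrendModel, q: float) -> FourPLParams:
    """Predicted full 4PL parameter set for an arbitrary polyQ length."""
    return FourPLParams(
        bottom=trends.bottom_pooled,
        top=float(trends.top_model(q)),
        ec50=float(trends.ec50_model(q)),
        hillslope=trends.hillslope_pooled,
    )
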