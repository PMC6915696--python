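"""Four-parameter logistic (4PL) dose-response calibration.

Sandwich-immunoassay standard curves (electrochemiluminescence counts vs
protein concentration) are sigmoidal and are fitted here with the 4PL model

    signal(x) = Bottom + x^Hill * (Top - Bottom) / (x^Hill + EC50^Hill)

using weighted least squares with 1/y^2 weighting, the standard choice for
immunoassays whose measurement error is approximately constant on the
relative scale.  ``FourPLRegressor`` is a scikit-learn style estimator;
:func:`fit_four_pl` is the series-level functional wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponsePoint",
    "DoseResponseSeries",
    "FourPLParams",
    "FourPLFitResult",
    "FourPLRegressor",
    "evaluate_four_pl",
    "fit_four_pl",
]

_VALID_UNITS = ("pM", "ug")


@dataclass(frozen=True)
class DoseResponsePoint:
    """One replicate measurement: concentration (pM or µg load) vs signal."""

    concentration: float
    signal: float
    replicate_id: int = 0
    units: str = "pM"

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")
        if not np.isfinite(self.signal):
            raise ValueError(f"signal must be finite, got {self.signal}")
        if self.units not in _VALID_UNITS:
            raise ValueError(f"units must be one of {_VALID_UNITS}, got {self.units!r}")


@dataclass
class DoseResponseSeries:
    """Replicate signal-vs-concentration measurements for one sample/antibody pair."""

    sample_id: str
    antibody_pair: str
    points: list[DoseResponsePoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        units = {p.units for p in self.points}
        if len(units) > 1:
            raise ValueError(f"mixed units within one series: {sorted(units)}")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([p.concentration for p in self.points], dtype=float)

    @property
    def signals(self) -> np.ndarray:
        return np.array([p.signal for p in self.points], dtype=float)

    def n_distinct_concentrations(self) -> int:
        return len(set(p.concentration for p in self.points))

    @classmethod
    def from_arrays(
        cls,
        concentrations: Sequence[float],
        signals: Sequence[float],
        sample_id: str = "",
        antibody_pair: str = "",
        units: str = "pM",
    ) -> "DoseResponseSeries":
        pts = [
            DoseResponsePoint(float(c), float(s), replicate_id=i, units=units)
            for i, (c, s) in enumerate(zip(concentrations, signals, strict=True))
        ]
        return cls(sample_id=sample_id, antibody_pair=antibody_pair, points=pts)


@dataclass(frozen=True)
class FourPLParams:
    """Bottom/Top plateaus (counts), EC50 (concentration units), HillSlope."""

    bottom: float
    top: float
    ec50: float
    hillslope: float

    def __post_init__(self) -> None:
        vals = (self.bottom, self.top, self.ec50, self.hillslope)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite 4PL parameters: {vals}")
        if self.ec50 <= 0:
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if self.hillslope <= 0:
            raise ValueError(f"hillslope must be > 0, got {self.hillslope}")
        if self.top < self.bottom:
            raise ValueError(f"top ({self.top}) must be >= bottom ({self.bottom})")

    def as_array(self) -> np.ndarray:
        return np.array([self.bottom, self.top, self.ec50, self.hillslope])


@dataclass
class FourPLFitResult:
    params: FourPLParams
    param_sd: np.ndarray  # (bottom, top, ec50, hillslope) standard deviations
    weighted_sse: float
    r_squared: float
    converged: bool
    n_points: int


class InsufficientDataError(ValueError):
    """Fewer distinct concentrations than the 4PL model can support."""


def evaluate_four_pl(params: FourPLParams, x) -> np.ndarray | float:
    """Evaluate the 4PL curve at concentration(s) ``x`` (>= 0).

    At x = 0 the curve equals Bottom (limit for HillSlope > 0).
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("concentration must be >= 0")
    out = _fourpl(x_arr, *params.as_array())
    return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out


def _fourpl(x, bottom, top, ec50, hill):
    # computed in log space to stay stable for large x^hill
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        t = hill * (np.log(x) - np.log(ec50))  # log((x/ec50)^hill); -inf at x=0
    frac = 1.0 / (1.0 + np.exp(-t))  # x^h / (x^h + ec50^h)
    frac = np.where(np.isneginf(t), 0.0, frac)
    return bottom + frac * (top - bottom)


def _start_list(x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Deterministic multi-start heuristics for the 4PL optimizer."""
    b0 = float(np.min(y))
    t0 = float(np.max(y))
    half = b0 + 0.5 * (t0 - b0)
    pos = x[x > 0]
    if pos.size:
        e_half = float(x[np.argmin(np.abs(y - half))])
        if e_half <= 0:
            e_half = float(np.exp(np.mean(np.log(pos))))
        e_geo = float(np.exp(np.mean(np.log(pos))))
    else:  # degenerate: all-zero concentrations rejected upstream
        e_half = e_geo = 1.0
    starts = []
    for ec in (e_half, e_geo):
        for hill in (0.5, 1.0, 2.0):
            starts.append(np.array([b0, t0, max(ec, 1e-12), hill]))
    return starts


class FourPLRegressor:
    """Scikit-learn style 4PL regressor with immunoassay 1/y^2 weighting.

    Parameters
    ----------
    weighting : {"inverse_y_squared", "none"}
        ``inverse_y_squared`` minimizes sum((y - yhat)^2 / y^2) using the
        observed signals as weights; requires all signals > 0.
    max_nfev : int
        Function-evaluation budget per start.

    Attributes (after :meth:`fit`)
    ------------------------------
    params_ : FourPLParams
    param_sd_ : ndarray of shape (4,)
    weighted_sse_ : float
    r_squared_ : float  (weighted R^2, <= 1)
    converged_ : bool
    n_points_ : int
    """

    def __init__(self, weighting: str = "inverse_y_squared", max_nfev: int = 2000):
        self.weighting = weighting
        self.max_nfev = max_nfev

    def get_params(self, deep: bool = True) -> dict:
        return {"weighting": self.weighting, "max_nfev": self.max_nfev}

    def set_params(self, **kw) -> "FourPLRegressor":
        for k, v in kw.items():
            if k not in ("weighting", "max_nfev"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------
    def fit(self, X, y) -> "FourPLRegressor":
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("X and y must have equal length")
        if len(set(x.tolist())) < 5:
            raise InsufficientDataError(
                f"4PL fitting requires >= 5 distinct concentrations, got {len(set(x.tolist()))}"
            )
        if self.weighting not in ("inverse_y_squared", "none"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.weighting == "inverse_y_squared" and np.any(y <= 0):
            raise ValueError("1/y^2 weighting requires all signals > 0")

        # sort for order-independence of the optimizer path
        order = np.lexsort((y, x))
        x, y = x[order], y[order]
        w = 1.0 / y if self.weighting == "inverse_y_squared" else np.ones_like(y)

        def resid(theta):
            return w * (_fourpl(x, *theta) - y)

        lo = np.array([-np.inf, -np.inf, 1e-12, 1e-6])
        hi = np.array([np.inf, np.inf, np.inf, 50.0])
        best = None
        for theta0 in _start_list(x, y):
            theta0 = np.clip(theta0, lo, hi)
            sol = least_squares(resid, theta0, bounds=(lo, hi), max_nfev=self.max_nfev)
            if best is None or sol.cost < best.cost - 1e-15 * max(1.0, best.cost):
                best = sol
        assert best is not None

        b, t, e, h = best.x
        if t < b:  # report in canonical orientation; hill>0 with top>=bottom
            b, t = min(b, t), max(b, t)
        self.params_ = FourPLParams(b, t, e, h)
        self.weighted_sse_ = float(2.0 * best.cost)
        self.converged_ = bool(best.success)
        self.n_points_ = x.size

        # parameter SDs from the Gauss-Newton covariance at the solution
        J = best.jac
        dof = max(x.size - 4, 1)
        s2 = self.weighted_sse_ / dof
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            self.param_sd_ = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            self.param_sd_ = np.full(4, np.nan)

        wss = w * w
        ybar = float(np.sum(wss * y) / np.sum(wss))
        sstot = float(np.sum(wss * (y - ybar) ** 2))
        self.r_squared_ = 1.0 - self.weighted_sse_ / sstot if sstot > 0 else 1.0
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise RuntimeError("regressor is not fitted")
        x = np.asarray(X, dtype=float)
        return _fourpl(x, *self.params_.as_array())

    def result(self) -> FourPLFitResult:
        return FourPLFitResult(
            params=self.params_,
            param_sd=self.param_sd_,
            weighted_sse=self.weighted_sse_,
            r_squared=self.r_squared_,
            converged=self.converged_,
            n_points=self.n_points_,
        )


def fit_four_pl(series: DoseResponseSeries, weighting: str = "inverse_y_squared") -> FourPLFitResult:
    """Fit Eq.-style 4PL to a dose-response series (replicates as individual points)."""
    reg = FourPLRegressor(weighting=weighting)
    reg.fit(series.concentrations, series.signals)
    return reg.result()
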