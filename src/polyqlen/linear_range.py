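"""Linear dynamic range extraction and slope ratios.

In the linear dynamic range a sandwich immunoassay obeys
``signal = concentration * slope`` (after background subtraction), and the
slope of a polyQ-antibody channel divided by the slope of the total-antibody
channel is the polyQ-length-bearing ratio.  The linear range is found by
scanning windows of consecutive standards: a window is accepted when the
weighted through-origin fit (after subtracting the fitted Bottom) has
R^2 >= 0.98 and every point back-calculates to within +/-20% of its nominal
concentration; the widest window wins, ties broken toward lower
concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourpl import DoseResponseSeries, FourPLFitResult

__all__ = [
    "SlopeEstimate",
    "LinearRangeConfig",
    "NoLinearRangeError",
    "determine_linear_range",
    "slope_in_window",
    "slope_ratio",
]


@dataclass(frozen=True)
class LinearRangeConfig:
    """Acceptance criteria for a linear-range window.

    min_r_squared: through-origin weighted R^2 a window must reach.
    max_backcalc_error: relative back-calculated-concentration error allowed
        for every point in the window (0.20 = +/-20% of nominal).
    min_points: minimum number of distinct standards in a window.
    """

    min_r_squared: float = 0.98
    max_backcalc_error: float = 0.20
    min_points: int = 3


@dataclass
class SlopeEstimate:
    slope: float
    slope_sd: float
    window_lo: float
    window_hi: float
    n_points_used: int
    fit_r_squared: float


class NoLinearRangeError(ValueError):
    """No window of standards met the linearity criteria."""


def _through_origin_fit(x: np.ndarray, y: np.ndarray):
    """Weighted (1/y^2 where possible) through-origin slope, SD, uncentered R^2."""
    w = np.where(y > 0, 1.0 / np.square(y), 1.0)
    sxx = float(np.sum(w * x * x))
    slope = float(np.sum(w * x * y) / sxx)
    resid = y - slope * x
    n = x.size
    if n > 1:
        s2 = float(np.sum(w * resid**2) / (n - 1))
        slope_sd = float(np.sqrt(s2 / sxx))
    else:
        slope_sd = 0.0
    ss_tot = float(np.sum(w * y * y))  # uncentered: through-origin convention
    r2 = 1.0 - float(np.sum(w * resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return slope, slope_sd, r2


def determine_linear_range(
    series: DoseResponseSeries,
    fit: FourPLFitResult,
    config: LinearRangeConfig | None = None,
) -> SlopeEstimate:
    """Slope of the standard curve over the widest acceptable linear window.

    Signals are corrected by the fitted Bottom before the through-origin fit,
    so the slope is the proportional response per concentration unit.
    """
    if not fit.converged:
        raise ValueError("linear-range extraction requires a converged 4PL fit")
    config = config or LinearRangeConfig()

    conc = series.concentrations
    sig = series.signals - fit.params.bottom
    levels = np.array(sorted(set(conc[conc > 0].tolist())))
    if levels.size < config.min_points:
        raise NoLinearRangeError(
            f"only {levels.size} positive standards; need >= {config.min_points}"
        )

    best = None  # (width, -lo_index, estimate)
    failures = []
    n_levels = levels.size
    for width in range(n_levels, config.min_points - 1, -1):
        for lo_i in range(0, n_levels - width + 1):
            window = levels[lo_i : lo_i + width]
            mask = np.isin(conc, window)
            x, y = conc[mask], sig[mask]
            slope, slope_sd, r2 = _through_origin_fit(x, y)
            if slope <= 0:
                failures.append(f"[{window[0]:g},{window[-1]:g}]: non-positive slope")
                continue
            if r2 < config.min_r_squared:
                failures.append(f"[{window[0]:g},{window[-1]:g}]: R^2 {r2:.4f} < {config.min_r_squared}")
                continue
            backcalc = y / slope
            rel_err = np.abs(backcalc - x) / x
            if np.max(rel_err) > config.max_backcalc_error:
                failures.append(
                    f"[{window[0]:g},{window[-1]:g}]: back-calculated concentration off by "
                    f"{100 * np.max(rel_err):.1f}% > {100 * config.max_backcalc_error:.0f}%"
                )
                continue
            cand = SlopeEstimate(
                slope=slope,
                slope_sd=slope_sd,
                window_lo=float(window[0]),
                window_hi=float(window[-1]),
                n_points_used=int(mask.sum()),
                fit_r_squared=r2,
            )
            key = (width, -lo_i)  # widest wins; ties toward lower concentrations
            if best is None or key > best[0]:
                best = (key, cand)
        if best is not None:
            break  # windows are scanned widest-first
    if best is None:
        raise NoLinearRangeError(
            "no linear-range window met the criteria; failing windows: " + "; ".join(failures[:5])
        )
    return best[1]


def slope_in_window(
    series: DoseResponseSeries, fit: FourPLFitResult, window_lo: float, window_hi: float
) -> SlopeEstimate:
    """Through-origin slope over an explicitly chosen concentration window.

    Used when one linear range has been established for a whole assay and is
    applied uniformly to every standard, avoiding per-series window jitter.
    """
    conc = series.concentrations
    sig = series.signals - fit.params.bottom
    mask = (conc >= window_lo) & (conc <= window_hi)
    if mask.sum() < 3:
        raise NoLinearRangeError(
            f"window [{window_lo:g}, {window_hi:g}] covers only {int(mask.sum())} points"
        )
    slope, slope_sd, r2 = _through_origin_fit(conc[mask], sig[mask])
    if slope <= 0:
        raise NoLinearRangeError("non-positive slope in the requested window")
    return SlopeEstimate(
        slope=slope,
        slope_sd=slope_sd,
        window_lo=window_lo,
        window_hi=window_hi,
        n_points_used=int(mask.sum()),
        fit_r_squared=r2,
    )


def slope_ratio(numerator: SlopeEstimate, denominator: SlopeEstimate) -> tuple[float, float]:
    """Ratio of linear-range slopes with error-propagated SD."""
    from .polyq import propagate_ratio_sd

    if denominator.slope <= 0:
        raise ValueError(f"denominator slope must be > 0, got {denominator.slope}")
    return propagate_ratio_sd(
        numerator.slope, numerator.slope_sd, denominator.slope, denominator.slope_sd
    )
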