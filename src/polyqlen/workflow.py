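"""High-level calibration workflow: standard curves -> polyQ calibration.

Chains the per-standard steps: 4PL fit of each channel's dose-response
series, linear-range slope extraction, per-Q slope ratio with propagated SD,
and ratio-vs-Q regression family selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourpl import DoseResponseSeries, FourPLFitResult, fit_four_pl
from .linear_range import (
    LinearRangeConfig,
    SlopeEstimate,
    determine_linear_range,
    slope_in_window,
    slope_ratio,
)
from .polyq import PolyQCalibrator

__all__ = ["StandardsFit", "fit_standard_series", "build_calibration"]


@dataclass
class StandardsFit:
    q: float
    fit: FourPLFitResult
    slope: SlopeEstimate


def _q_from_sample_id(sample_id: str) -> float:
    """Parse a polyQ length from ids like 'Q48' / 'q48' / '48'."""
    s = sample_id.strip().lstrip("Qq")
    return float(s)


def fit_standard_series(
    series_list: list[DoseResponseSeries],
    weighting: str = "inverse_y_squared",
    config: LinearRangeConfig | None = None,
    common_window: bool = True,
) -> list[StandardsFit]:
    """Fit every standard's 4PL curve and extract its linear-range slope.

    With ``common_window`` (the default) one linear range is established for
    the whole channel — the overlap of the windows accepted per series — and
    every slope is refitted over it.  All standards of a channel come from
    the same assay and dilution series, so a single linear range applies;
    letting each standard pick its own window makes slopes jump between
    windows with different curvature shrinkage, which inflates the variance
    of slope ratios far beyond the replicate noise.
    """
    out = []
    for series in series_list:
        fit = fit_four_pl(series, weighting=weighting)
        slope = determine_linear_range(series, fit, config)
        out.append(StandardsFit(q=_q_from_sample_id(series.sample_id), fit=fit, slope=slope))
    if common_window and len(out) > 1:
        lo = max(s.slope.window_lo for s in out)
        hi = min(s.slope.window_hi for s in out)
        if lo < hi:
            for i, (series, s) in enumerate(zip(series_list, out)):
                refit = slope_in_window(series, s.fit, lo, hi)
                out[i] = StandardsFit(q=s.q, fit=s.fit, slope=refit)
    return out


def build_calibration(
    polyq_standards: list[StandardsFit],
    total_standards: list[StandardsFit],
    calibrator: PolyQCalibrator | None = None,
) -> tuple[PolyQCalibrator, np.ndarray, np.ndarray]:
    """Fit ratio = f(Q) from matched per-Q standards of the two channels.

    Returns the fitted calibrator plus the training (Q, ratio) arrays.
    Standards are matched on Q; a polyQ-channel standard without a
    total-channel partner at the same Q is an error.
    """
    total_by_q = {s.q: s for s in total_standards}
    qs, ratios = [], []
    for ps in sorted(polyq_standards, key=lambda s: s.q):
        if ps.q not in total_by_q:
            raise ValueError(f"no total-channel standard at Q={ps.q:g}")
        r, _ = slope_ratio(ps.slope, total_by_q[ps.q].slope)
        qs.append(ps.q)
        ratios.append(r)
    calibrator = calibrator or PolyQCalibrator()
    calibrator.fit(qs, ratios)
    return calibrator, np.asarray(qs), np.asarray(ratios)
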