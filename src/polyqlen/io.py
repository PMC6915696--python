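"""Delimited-text I/O: plate-reader exports and fit reports."""

from __future__ import annotations

import pandas as pd

from .fourpl import DoseResponsePoint, DoseResponseSeries, FourPLFitResult
from .linear_range import SlopeEstimate

__all__ = ["read_plate_table", "write_plate_table", "write_fit_report"]

PLATE_COLUMNS = ["sample_id", "antibody_pair", "concentration", "units", "replicate", "signal"]


def read_plate_table(source) -> list[DoseResponseSeries]:
    """Read a plate-reader export (CSV with the standard header columns).

    One series is built per (sample_id, antibody_pair) combination.
    """
    df = pd.read_csv(source)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate table is missing columns: {missing}")
    series = []
    for (sid, pair), grp in df.groupby(["sample_id", "antibody_pair"], sort=False):
        pts = [
            DoseResponsePoint(
                concentration=float(r.concentration),
                signal=float(r.signal),
                replicate_id=int(r.replicate),
                units=str(r.units),
            )
            for r in grp.itertuples()
        ]
        series.append(DoseResponseSeries(sample_id=str(sid), antibody_pair=str(pair), points=pts))
    return series


def write_plate_table(series_list: list[DoseResponseSeries], path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "antibody_pair": s.antibody_pair,
            "concentration": p.concentration,
            "units": p.units,
            "replicate": p.replicate_id,
            "signal": p.signal,
        }
        for s in series_list
        for p in s.points
    ]
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)


def write_fit_report(
    entries: list[tuple[DoseResponseSeries, FourPLFitResult, SlopeEstimate | None]], path
) -> pd.DataFrame:
    """One row per fitted series: 4PL parameters, SDs, diagnostics, slope."""
    rows = []
    for series, fit, slope in entries:
        row = {
            "sample_id": series.sample_id,
            "antibody_pair": series.antibody_pair,
            "bottom": fit.params.bottom,
            "top": fit.params.top,
            "ec50": fit.params.ec50,
            "hillslope": fit.params.hillslope,
            "bottom_sd": fit.param_sd[0],
            "top_sd": fit.param_sd[1],
            "ec50_sd": fit.param_sd[2],
            "hillslope_sd": fit.param_sd[3],
            "weighted_sse": fit.weighted_sse,
            "r_squared": fit.r_squared,
            "converged": fit.converged,
            "n_points": fit.n_points,
            "window_lo": slope.window_lo if slope else None,
            "window_hi": slope.window_hi if slope else None,
            "slope": slope.slope if slope else None,
            "slope_sd": slope.slope_sd if slope else None,
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
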