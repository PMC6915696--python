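"""End-to-end orchestration: QC, normalization, ratios, estimates, correlation.

Given per-sample immunoassay signals for a polyQ-antibody and a
total-antibody channel (measured at the same protein load, in the linear
range), the pipeline applies the detection-limit QC, optional western-blot
normalization and batch correction factors, forms the signal ratio with
propagated SD, converts it to an average polyQ length through a fitted
calibration, computes average CAG repeat lengths from paired DNA traces, and
regresses the protein-level ratio on the DNA-level repeat length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cag import average_cag_from_trace
from .polyq import CalibrationModel, estimate_average_polyq, propagate_ratio_sd
from .simulate import SyntheticCohortSample

__all__ = [
    "SampleRecord",
    "DetectionLimit",
    "RegressionSummary",
    "qc_detection_limit",
    "wb_normalize",
    "concentration_correction_factors",
    "correlate_protein_dna",
    "analyze_cohort",
]


@dataclass
class SampleRecord:
    """One sample's paired-channel measurements for one antibody pair."""

    sample_id: str
    mhtt_signal: float
    mhtt_sd: float
    total_signal: float
    total_sd: float
    antibody_pair: str = "polyq/total"
    tissue: str = ""
    protein_load: float | None = None
    wb_amount: float | None = None
    wb_sd: float = 0.0
    avg_cag_dna: float | None = None

    def __post_init__(self) -> None:
        if self.mhtt_sd < 0 or self.total_sd < 0 or self.wb_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class DetectionLimit:
    """Exclusion threshold: background mean + k standard deviations."""

    background_mean: float
    background_sd: float
    k: float = 3.0

    def __post_init__(self) -> None:
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")
        if self.k <= 0:
            raise ValueError("k must be > 0")

    @property
    def limit(self) -> float:
        return self.background_mean + self.k * self.background_sd


@dataclass
class RegressionSummary:
    antibody_pair: str
    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    n: int


def qc_detection_limit(signal: float, limit: DetectionLimit) -> bool:
    """True iff the signal is strictly above background + k*SD."""
    return signal > limit.limit


def wb_normalize(
    msd_signal: float, msd_sd: float, wb_amount: float, wb_sd: float = 0.0
) -> tuple[float, float]:
    """Divide an immunoassay signal by a western-blot band quantity.

    Removes protein-amount differences between lanes; SD propagated as for
    any ratio of independent measurements.
    """
    if wb_amount <= 0:
        raise ValueError(f"WB amount must be > 0, got {wb_amount}")
    return propagate_ratio_sd(msd_signal, msd_sd, wb_amount, wb_sd)


def concentration_correction_factors(
    band_signals: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Per-batch concentration correction from gel band fluorescence.

    factor(Q) = band_signal(Q) / mean(all band signals); the factors average
    to exactly 1 so correction redistributes but never rescales the set.
    """
    if len(band_signals) < 2:
        raise ValueError("need >= 2 band signals")
    values = np.array([s for _, s in band_signals], dtype=float)
    if np.any(values <= 0):
        raise ValueError("band signals must be > 0")
    mean = values.mean()
    return [(q, float(s / mean)) for (q, _), s in zip(band_signals, values)]


def correlate_protein_dna(
    samples: list[SampleRecord],
    detection_limit: DetectionLimit | None = None,
    require_matched_load: bool = True,
) -> dict[str, RegressionSummary]:
    """OLS of the protein-level signal ratio on the DNA-level average CAG.

    Each antibody pair is regressed independently.  Samples failing the
    detection limit on either channel, or missing the DNA measurement, are
    excluded.  When ``require_matched_load`` is set, all samples of a pair
    must share the same protein load (ratios are only comparable at matched
    loads).
    """
    out: dict[str, RegressionSummary] = {}
    df = pd.DataFrame(
        {
            "pair": [s.antibody_pair for s in samples],
            "mhtt": [s.mhtt_signal for s in samples],
            "total": [s.total_signal for s in samples],
            "cag": [s.avg_cag_dna for s in samples],
            "load": [s.protein_load for s in samples],
        }
    )
    for pair, grp in df.groupby("pair", sort=False):
        loads = grp["load"].dropna().unique()
        if require_matched_load and len(loads) > 1:
            raise ValueError(
                f"antibody pair {pair!r} measured at mismatched protein loads {sorted(loads)}"
            )
        usable = grp[grp["cag"].notna()]
        if detection_limit is not None:
            ok = usable.apply(
                lambda r: qc_detection_limit(r["mhtt"], detection_limit)
                and qc_detection_limit(r["total"], detection_limit),
                axis=1,
            )
            usable = usable[ok] if len(usable) else usable
        if len(usable) < 3:
            raise ValueError(
                f"antibody pair {pair!r}: {len(usable)} usable samples (< 3) after QC"
            )
        ratio = usable["mhtt"].to_numpy() / usable["total"].to_numpy()
        res = stats.linregress(usable["cag"].to_numpy(dtype=float), ratio)
        out[pair] = RegressionSummary(
            antibody_pair=str(pair),
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue**2),
            slope_stderr=float(res.stderr),
            n=len(usable),
        )
    return out


def analyze_cohort(
    cohort: list[SyntheticCohortSample],
    calibration: CalibrationModel,
    threshold_factor: float = 0.05,
) -> pd.DataFrame:
    """Full protein + DNA analysis of a (synthetic) cohort.

    Returns one row per sample: measured average CAG from the trace,
    protein ratio with SD, estimated average polyQ length with SD, and the
    generating truth for validation.
    """
    rows = []
    for s in cohort:
        cag = average_cag_from_trace(s.dna_trace, threshold_factor, n_alleles=1)
        est = estimate_average_polyq(s.protein_ratio, s.protein_ratio_sd, calibration)
        rows.append(
            {
                "sample_id": s.sample_id,
                "true_avg_cag": s.true_avg_cag,
                "avg_cag_dna": cag.combined_average,
                "protein_ratio": s.protein_ratio,
                "protein_ratio_sd": s.protein_ratio_sd,
                "q_mean": est.q_mean,
                "q_sd": est.q_sd,
                "extrapolated": est.extrapolated,
            }
        )
    return pd.DataFrame(rows)
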