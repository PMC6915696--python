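"""Average CAG repeat length from fragment-analysis peak traces.

PCR across an unstable CAG tract yields a cluster of products one repeat
apart; capillary electrophoresis renders them as peaks whose heights track
molecule abundance.  The average repeat length per allele is the
height-weighted mean repeat length after discarding peaks below a relative
threshold (default 5% of the tallest peak in the allele group):

  1. analyze each allele's cluster individually,
  2. threshold at ``threshold_factor`` x max height,
  3. normalize surviving heights to sum to 1,
  4. multiply each normalized height by its repeat length,
  5. sum -> per-allele average,
  6. average the allele averages.

Allele clusters are separated by an explicit repeat-length window pair when
provided, otherwise at the largest gap between consecutive peak positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FragmentPeak",
    "PeakTrace",
    "AverageCagResult",
    "apply_peak_threshold",
    "allele_average_cag",
    "combined_average_cag",
    "split_alleles",
    "average_cag_from_trace",
    "read_peak_table",
]

DEFAULT_THRESHOLD_FACTOR = 0.05


@dataclass(frozen=True)
class FragmentPeak:
    repeat_length: int
    height: float

    def __post_init__(self) -> None:
        if not (isinstance(self.repeat_length, (int, np.integer)) and self.repeat_length >= 1):
            raise ValueError(f"repeat_length must be a positive integer, got {self.repeat_length}")
        if not (np.isfinite(self.height) and self.height > 0):
            raise ValueError(f"height must be finite and > 0, got {self.height}")


@dataclass
class PeakTrace:
    sample_id: str
    peaks: list[FragmentPeak] = field(default_factory=list)
    allele_windows: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        lengths = [p.repeat_length for p in self.peaks]
        if len(set(lengths)) != len(lengths):
            raise ValueError(f"duplicate repeat lengths in trace {self.sample_id!r}")
        if self.allele_windows is not None:
            (a_lo, a_hi), (b_lo, b_hi) = self.allele_windows
            if a_lo > a_hi or b_lo > b_hi:
                raise ValueError("allele windows must be ordered intervals")
            if max(a_lo, b_lo) <= min(a_hi, b_hi):
                raise ValueError("allele windows must be disjoint")


@dataclass
class AverageCagResult:
    allele_averages: list[float]
    combined_average: float
    threshold_used: list[float]
    n_peaks_used: int


class NoPeaksError(ValueError):
    pass


class AmbiguousSplitError(ValueError):
    pass


def apply_peak_threshold(
    peaks: list[FragmentPeak], threshold_factor: float = DEFAULT_THRESHOLD_FACTOR
) -> tuple[list[FragmentPeak], float]:
    """Drop peaks below ``threshold_factor`` x the tallest peak's height.

    Returns the surviving peaks and the threshold value used.  The tallest
    peak always survives, so the result is never empty.
    """
    if not peaks:
        raise NoPeaksError("empty peak set")
    if not (0 < threshold_factor < 1):
        raise ValueError(f"threshold_factor must be in (0, 1), got {threshold_factor}")
    threshold = threshold_factor * max(p.height for p in peaks)
    return [p for p in peaks if p.height >= threshold], threshold


def allele_average_cag(
    peaks: list[FragmentPeak], threshold_factor: float = DEFAULT_THRESHOLD_FACTOR
) -> float:
    """Height-weighted mean repeat length of one allele's peak cluster."""
    surviving, _ = apply_peak_threshold(peaks, threshold_factor)
    heights = np.array([p.height for p in surviving], dtype=float)
    repeats = np.array([p.repeat_length for p in surviving], dtype=float)
    weights = heights / heights.sum()
    assert abs(weights.sum() - 1.0) < 1e-12
    return float(np.sum(weights * repeats))


def combined_average_cag(allele_averages: list[float]) -> float:
    """Mean of the per-allele averages (single-allele passes through)."""
    if not allele_averages:
        raise ValueError("no allele averages provided")
    if len(allele_averages) > 2:
        raise ValueError(f"expected 1 or 2 allele averages, got {len(allele_averages)}")
    return float(np.mean(allele_averages))


def split_alleles(trace: PeakTrace) -> tuple[list[FragmentPeak], list[FragmentPeak]]:
    """Partition a two-allele trace into its allele clusters.

    With explicit ``allele_windows`` peaks are assigned by window membership;
    otherwise the trace is split at the largest gap between consecutive
    repeat lengths, which must be at least 2 repeats to be unambiguous.
    """
    peaks = sorted(trace.peaks, key=lambda p: p.repeat_length)
    if len(peaks) < 2:
        raise ValueError("two-allele split requires >= 2 peaks")
    if trace.allele_windows is not None:
        (a_lo, a_hi), (b_lo, b_hi) = sorted(trace.allele_windows)
        first = [p for p in peaks if a_lo <= p.repeat_length <= a_hi]
        second = [p for p in peaks if b_lo <= p.repeat_length <= b_hi]
        if not first or not second:
            raise ValueError("an allele window contains no peaks")
        return first, second
    gaps = [peaks[i + 1].repeat_length - peaks[i].repeat_length for i in range(len(peaks) - 1)]
    i_max = int(np.argmax(gaps))
    if gaps[i_max] < 2:
        raise AmbiguousSplitError(
            "single contiguous cluster: no gap >= 2 repeats between putative alleles"
        )
    return peaks[: i_max + 1], peaks[i_max + 1 :]


def average_cag_from_trace(
    trace: PeakTrace,
    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR,
    n_alleles: int = 2,
    threshold_scope: str = "per_allele",
) -> AverageCagResult:
    """Run the full six-step procedure on one trace.

    threshold_scope: "per_allele" applies the 5% rule within each allele
    cluster (alleles analyzed individually); "global" thresholds against the
    tallest peak of the whole trace before splitting.
    """
    if n_alleles not in (1, 2):
        raise ValueError("n_alleles must be 1 or 2")
    if threshold_scope not in ("per_allele", "global"):
        raise ValueError(f"unknown threshold_scope {threshold_scope!r}")

    if threshold_scope == "global":
        kept, g_threshold = apply_peak_threshold(trace.peaks, threshold_factor)
        work = PeakTrace(trace.sample_id, kept, trace.allele_windows)
    else:
        work = trace

    groups = [work.peaks] if n_alleles == 1 else list(split_alleles(work))
    averages, thresholds, n_used = [], [], 0
    for grp in groups:
        if threshold_scope == "global":
            surviving, thr = grp, g_threshold
        else:
            surviving, thr = apply_peak_threshold(grp, threshold_factor)
        heights = np.array([p.height for p in surviving])
        repeats = np.array([p.repeat_length for p in surviving], dtype=float)
        averages.append(float(np.sum(heights / heights.sum() * repeats)))
        thresholds.append(thr)
        n_used += len(surviving)
    return AverageCagResult(
        allele_averages=averages,
        combined_average=combined_average_cag(averages),
        threshold_used=thresholds,
        n_peaks_used=n_used,
    )


def read_peak_table(source, flank_length_bp: float = 0.0) -> list[PeakTrace]:
    """Read a genotyping-software style peak export.

    Columns: sample_id, height, and either repeat_length or size_bp
    (converted as repeat = (size_bp - flank_length_bp) / 3, rounded);
    an optional ``allele`` column is ignored for splitting but peaks with
    equal converted repeat length are merged by summing heights.
    """
    df = pd.read_csv(source)
    if "repeat_length" in df.columns:
        df["_repeat"] = df["repeat_length"].astype(int)
    elif "size_bp" in df.columns:
        df["_repeat"] = np.rint((df["size_bp"] - flank_length_bp) / 3.0).astype(int)
    else:
        raise ValueError("peak table needs a repeat_length or size_bp column")
    traces = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        merged = grp.groupby("_repeat", sort=True)["height"].sum()
        peaks = [FragmentPeak(int(rep), float(h)) for rep, h in merged.items()]
        traces.append(PeakTrace(sample_id=str(sample_id), peaks=peaks))
    return traces
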