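"""Protein mixtures and accuracy/precision metrics.

A mixture of purified HTT-exon1 standards with distinct polyQ lengths has a
theoretical average polyQ length equal to the fraction-weighted mean of its
component lengths.  Comparing that ground truth with the length estimated by
the immunoassay ratio method yields the percent relative error (%RE) and, for
replicate estimates, the coefficient of variation (Cv %).  The validation
mixture recipes (five-component blends of Q25/Q38/Q48/Q55/Q72 standards) and
their reported estimates ship as packaged CSV fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .polyq import PolyQEstimate

__all__ = [
    "MixtureSpec",
    "AccuracyReport",
    "theoretical_average_polyq",
    "percent_relative_error",
    "coefficient_of_variation",
    "accuracy_table",
    "load_reference_mixtures",
    "load_reference_results",
    "read_mixture_recipes",
]

_FRACTION_TOL = 1e-6


@dataclass
class MixtureSpec:
    """Components (polyQ length, molar fraction) at a total concentration in pM."""

    components: list[tuple[int, float]]
    total_concentration: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        lengths = [q for q, _ in self.components]
        if len(set(lengths)) != len(lengths):
            raise ValueError(f"duplicate component polyQ lengths in {self.label!r}")
        if any(q <= 0 for q in lengths):
            raise ValueError("polyQ lengths must be positive")
        if any(not (0 <= f <= 1) for _, f in self.components):
            raise ValueError("fractions must lie in [0, 1]")
        total = sum(f for _, f in self.components)
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ValueError(f"fractions must sum to 1 (got {total}) in {self.label!r}")


@dataclass
class AccuracyReport:
    label: str
    theoretical_q: float
    mean_q: float
    sd_q: float
    cv_percent: float
    re_percent: float


def theoretical_average_polyq(mix: MixtureSpec) -> float:
    """Fraction-weighted mean polyQ length of the mixture components."""
    return sum(q * f for q, f in mix.components)


def percent_relative_error(measured: float, theoretical: float) -> float:
    """%RE = 100 * |measured - theoretical| / theoretical."""
    if theoretical <= 0:
        raise ValueError(f"theoretical reference must be > 0, got {theoretical}")
    return 100.0 * abs(measured - theoretical) / theoretical


def coefficient_of_variation(mean: float, sd: float) -> float:
    """Cv % = 100 * sd / mean."""
    if mean <= 0:
        raise ValueError(f"mean must be > 0, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    return 100.0 * sd / mean


def accuracy_table(
    mixtures: list[MixtureSpec], estimates: list[PolyQEstimate]
) -> list[AccuracyReport]:
    """One accuracy/precision report per (mixture, estimate) pair.

    Rendered values are rounded to 2 decimals, matching the reporting
    convention of the reference tables.
    """
    if len(mixtures) != len(estimates):
        raise ValueError(
            f"misaligned inputs: {len(mixtures)} mixtures vs {len(estimates)} estimates"
        )
    reports = []
    for mix, est in zip(mixtures, estimates):
        theo = theoretical_average_polyq(mix)
        reports.append(
            AccuracyReport(
                label=mix.label,
                theoretical_q=round(theo, 2),
                mean_q=round(est.q_mean, 2),
                sd_q=round(est.q_sd, 2),
                cv_percent=round(coefficient_of_variation(est.q_mean, est.q_sd), 2),
                re_percent=round(percent_relative_error(est.q_mean, theo), 2),
            )
        )
    return reports


def read_mixture_recipes(source) -> list[MixtureSpec]:
    """Read mixture recipes from delimited text.

    Expected columns: label, total_concentration_pM, q_length, fraction
    (one row per component; extra columns are carried through untouched).
    """
    df = pd.read_csv(source)
    mixes = []
    for label, grp in df.groupby("label", sort=False):
        conc = float(grp["total_concentration_pM"].iloc[0])
        comps = [(int(q), float(f)) for q, f in zip(grp["q_length"], grp["fraction"])]
        mixes.append(MixtureSpec(components=comps, total_concentration=conc, label=str(label)))
    return mixes


def _data_path(name: str):
    return resources.files("polyqlen.data").joinpath(name)


def load_reference_mixtures(table: int | None = None) -> list[MixtureSpec]:
    """Packaged validation mixture recipes (optionally one reference table 1-3)."""
    with _data_path("mixture_recipes.csv").open() as fh:
        df = pd.read_csv(fh)
    if table is not None:
        df = df[df["table"] == table]
    mixes = []
    for label, grp in df.groupby("label", sort=False):
        comps = [(int(q), float(f)) for q, f in zip(grp["q_length"], grp["fraction"])]
        mixes.append(
            MixtureSpec(
                components=comps,
                total_concentration=float(grp["total_concentration_pM"].iloc[0]),
                label=str(label),
            )
        )
    return mixes


def load_reference_results(table: int | None = None) -> pd.DataFrame:
    """Reported mean/SD/Cv/%RE for the packaged validation mixtures."""
    with _data_path("reported_results.csv").open() as fh:
        df = pd.read_csv(fh)
    return df if table is None else df[df["table"] == table].reset_index(drop=True)
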