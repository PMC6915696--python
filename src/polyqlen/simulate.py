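"""Synthetic assay data: standard curves, mixtures, peak traces, cohorts.

The generator emulates the structure of the real experiments:

* Per-Q standard curves follow the 4PL model.  For the polyQ-antibody
  channel Top grows linearly with polyQ length (avidity bias) while EC50,
  Bottom and HillSlope are length-independent; for the total-antibody
  channel every parameter is length-independent, so its signal reflects
  protein concentration only.  Measurement noise is multiplicative
  log-normal with a fixed coefficient of variation (immunoassay CVs are
  approximately constant on the relative scale), applied per replicate.
* Mixture signals are additive over species in the linear range:
  signal = sum_i fraction_i * total_conc * slope(Q_i) + Bottom.
* Fragment-analysis traces draw molecules from a discretized Gaussian
  repeat-length distribution (multinomial sampling), centered at
  modal_cag + expansion_bias with dispersion ``spread``.
* Cohorts pair a DNA trace with a protein signal ratio generated through
  the same forward calibration, linking the two instability readouts.

Every stochastic output is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .cag import FragmentPeak, PeakTrace
from .fourpl import DoseResponsePoint, DoseResponseSeries, FourPLParams
from .mixtures import MixtureSpec

__all__ = [
    "SimulationConfig",
    "SyntheticCohortSample",
    "simulate_standard_curves",
    "simulate_mixture_signals",
    "simulate_peak_trace",
    "simulate_cohort",
    "true_signal_ratio",
]

#: fraction of EC50 below which the 4PL is proportional to within ~20%
LINEAR_LIMIT_FRACTION = 0.25


@dataclass
class SimulationConfig:
    """Generative parameters for the immunoassay simulator.

    The channel rules give Top(Q) and EC50(Q) as affine coefficient pairs
    (intercept, per-Q slope).  Defaults: polyQ channel Top = 200*Q counts
    with constant EC50 = 500 pM; total channel Top = 10000 counts, EC50 =
    500 pM — signals in counts, concentrations in pM, HillSlope 1, shared
    background (Bottom) of 100 counts, 5% replicate CV, duplicate wells.
    """

    seed: int = 0
    noise_cv: float = 0.05
    q_standards: tuple[int, ...] = (19, 25, 32, 38, 44, 48, 55, 72)
    bottom: float = 100.0
    hillslope: float = 1.0
    top_polyq: tuple[float, float] = (0.0, 200.0)     # Top(Q) = 0 + 200*Q
    ec50_polyq: tuple[float, float] = (500.0, 0.0)    # EC50(Q) = 500
    top_total: tuple[float, float] = (10000.0, 0.0)
    ec50_total: tuple[float, float] = (500.0, 0.0)
    # 2-fold dilution series spanning near-background to >3x EC50, so both
    # 4PL plateaus are anchored by data
    concentrations: tuple[float, ...] = (
        0.78, 1.56, 3.125, 6.25, 12.5, 25.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1600.0,
    )
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not self.concentrations:
            raise ValueError("concentration list must not be empty")
        if self.top_polyq[1] <= 0:
            raise ValueError("polyQ-channel Top(Q) must be strictly increasing")
        if self.top_total[1] != 0:
            raise ValueError("total-channel Top must be length-independent")

    def params_for_q(self, q: float, channel: str) -> FourPLParams:
        if channel == "polyq":
            top_c, ec_c = self.top_polyq, self.ec50_polyq
        elif channel == "total":
            top_c, ec_c = self.top_total, self.ec50_total
        else:
            raise ValueError(f"unknown antibody channel {channel!r}")
        return FourPLParams(
            bottom=self.bottom,
            top=top_c[0] + top_c[1] * q,
            ec50=ec_c[0] + ec_c[1] * q,
            hillslope=self.hillslope,
        )

    def linear_slope(self, q: float, channel: str) -> float:
        """Low-concentration proportional slope (Top - Bottom)/EC50 (Hill = 1)."""
        p = self.params_for_q(q, channel)
        return (p.top - p.bottom) / p.ec50

    def linear_limit(self, q: float, channel: str) -> float:
        return LINEAR_LIMIT_FRACTION * self.params_for_q(q, channel).ec50

    def manifest(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohortSample:
    sample_id: str
    true_avg_cag: float
    dna_trace: PeakTrace
    protein_ratio: float
    protein_ratio_sd: float


_CHANNEL_KEY = {"polyq": 0, "total": 1}


def _channel_rng(seed: int, channel: str) -> np.random.Generator:
    """Independent, deterministic noise stream per antibody channel.

    The two channels are read from separately prepared plates, so their
    measurement noise must be independent — a shared stream would cancel in
    the signal ratio and understate its variance.
    """
    if channel not in _CHANNEL_KEY:
        raise ValueError(f"unknown antibody channel {channel!r}")
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_CHANNEL_KEY[channel],))
    )


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def _fourpl_signal(p: FourPLParams, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    num = np.power(x, p.hillslope, where=x > 0, out=np.zeros_like(x))
    return p.bottom + num * (p.top - p.bottom) / (num + p.ec50**p.hillslope)


def simulate_standard_curves(
    config: SimulationConfig, antibody_channel: str = "polyq"
) -> list[DoseResponseSeries]:
    """One replicate dose-response series per polyQ standard."""
    rng = _channel_rng(config.seed, antibody_channel)
    series = []
    for q in config.q_standards:
        p = config.params_for_q(q, antibody_channel)
        pts = []
        for conc in config.concentrations:
            clean = float(_fourpl_signal(p, np.array([conc]))[0])
            noise = _lognormal_factors(rng, config.noise_cv, config.n_replicates)
            for rep in range(config.n_replicates):
                pts.append(
                    DoseResponsePoint(
                        concentration=float(conc),
                        signal=clean * float(noise[rep]),
                        replicate_id=rep,
                    )
                )
        series.append(
            DoseResponseSeries(
                sample_id=f"Q{q}", antibody_pair=f"{antibody_channel}-channel", points=pts
            )
        )
    return series


def simulate_mixture_signals(
    mix: MixtureSpec, config: SimulationConfig, antibody_channel: str = "polyq"
) -> DoseResponseSeries:
    """Signals for a mixed-species sample measured in the linear range.

    Species contribute additively: each component adds its concentration
    times its per-Q proportional slope; background (Bottom) is shared.  An
    out-of-range warning is recorded on the series when the total
    concentration exceeds the proportional regime of any component.
    """
    rng = _channel_rng(config.seed, antibody_channel)
    clean = config.bottom + sum(
        frac * mix.total_concentration * config.linear_slope(q, antibody_channel)
        for q, frac in mix.components
    )
    limit = min(config.linear_limit(q, antibody_channel) for q, _ in mix.components)
    noise = _lognormal_factors(rng, config.noise_cv, config.n_replicates)
    pts = [
        DoseResponsePoint(
            concentration=mix.total_concentration, signal=clean * float(noise[rep]), replicate_id=rep
        )
        for rep in range(config.n_replicates)
    ]
    series = DoseResponseSeries(
        sample_id=mix.label or "mixture", antibody_pair=f"{antibody_channel}-channel", points=pts
    )
    series.out_of_linear_range = mix.total_concentration > limit  # recorded warning
    return series


def true_signal_ratio(mix_or_q, config: SimulationConfig) -> float:
    """Noise-free background-subtracted polyQ/total signal ratio.

    Accepts a single polyQ length or a MixtureSpec; by linear-range
    additivity a mixture's ratio is the fraction-weighted mean of its
    components' ratios.
    """
    slope_total = config.linear_slope(1.0, "total")  # Q-independent
    if isinstance(mix_or_q, MixtureSpec):
        return (
            sum(f * config.linear_slope(q, "polyq") for q, f in mix_or_q.components)
            / slope_total
        )
    return config.linear_slope(float(mix_or_q), "polyq") / slope_total


def simulate_peak_trace(
    modal_cag: int,
    expansion_bias: float = 0.0,
    spread: float = 3.0,
    n_molecules: int = 2000,
    seed: int = 0,
) -> PeakTrace:
    """Single-allele fragment-analysis trace.

    Molecule repeat lengths are multinomially sampled from a discretized
    Gaussian centered at ``modal_cag + expansion_bias`` (truncated at repeat
    1); peak heights are the molecule counts.
    """
    if modal_cag < 1:
        raise ValueError("modal_cag must be >= 1")
    if expansion_bias < 0:
        raise ValueError("expansion_bias must be >= 0")
    if spread <= 0:
        raise ValueError("spread must be > 0")
    if n_molecules <= 0:
        raise ValueError("n_molecules must be > 0")
    rng = np.random.default_rng(seed)
    center = modal_cag + expansion_bias
    half_width = max(1, int(np.ceil(6 * spread)))
    support = np.arange(max(1, int(np.floor(center)) - half_width),
                        int(np.ceil(center)) + half_width + 1)
    logp = -0.5 * ((support - center) / spread) ** 2
    p = np.exp(logp - logp.max())
    p /= p.sum()
    counts = rng.multinomial(n_molecules, p)
    peaks = [FragmentPeak(int(r), float(c)) for r, c in zip(support, counts) if c > 0]
    return PeakTrace(sample_id=f"sim_cag{modal_cag}", peaks=peaks)


def simulate_cohort(
    n_samples: int,
    instability_range: tuple[float, float],
    config: SimulationConfig,
    seed: int = 0,
    spread: float = 3.0,
    n_molecules: int = 2000,
) -> list[SyntheticCohortSample]:
    """Paired DNA-trace / protein-ratio cohort across an instability range.

    Each sample's true average CAG is drawn uniformly over
    ``instability_range``; its polyQ length is taken equal to the average
    repeat number, the noise-free ratio comes from the forward calibration,
    and the reported ratio is the mean of ``config.n_replicates`` noisy
    replicates.  The attached SD is the model-based standard error of that
    mean (ratio * noise_cv / sqrt(n)): with duplicate wells the empirical
    two-point SD is a very noisy chi^2(1) estimate, whereas the assay's
    replicate CV is a characterized constant of the simulator.
    """
    if n_samples < 3:
        raise ValueError("cohort needs >= 3 samples")
    lo, hi = instability_range
    if hi < lo:
        raise ValueError("instability_range must be ordered")
    rng = np.random.default_rng(seed)
    if hi == lo:
        import warnings

        warnings.warn("degenerate instability range: downstream correlation undefined")
    true_cags = rng.uniform(lo, hi, size=n_samples)
    samples = []
    for i, cag in enumerate(true_cags):
        modal = max(1, int(np.floor(cag)))
        bias = float(cag) - modal  # center the repeat distribution exactly at cag
        trace = simulate_peak_trace(
            modal, expansion_bias=bias, spread=spread, n_molecules=n_molecules,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        trace.sample_id = f"cohort_{i:03d}"
        ratio_true = true_signal_ratio(float(cag), config)
        reps = ratio_true * _lognormal_factors(rng, config.noise_cv, config.n_replicates)
        ratio = float(np.mean(reps))
        ratio_sd = ratio * config.noise_cv / np.sqrt(config.n_replicates)
        samples.append(
            SyntheticCohortSample(
                sample_id=trace.sample_id,
                true_avg_cag=float(cag),
                dna_trace=trace,
                protein_ratio=ratio,
                protein_ratio_sd=ratio_sd,
            )
        )
    return samples
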