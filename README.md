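# polyqlen

Somatic expansion of the CAG repeat in the *HTT* gene produces, within one
tissue, a mosaic of huntingtin (HTT) proteins with different polyglutamine
(polyQ) tract lengths.  Sandwich immunoassays that detect mutant HTT with
polyQ-targeting antibodies (MW1, 1C2, 3B5H10) carry an *avidity bias*: a
bivalent antibody finds more epitopes on a longer tract, so signal per
molecule grows with polyQ length.  `polyqlen` turns that bias from a
nuisance into a measurement.  It is written for labs quantifying somatic
repeat instability who want a protein-level readout to set beside the
standard DNA-level fragment-analysis readout.

## What it computes

**Average polyQ length from signal ratios.**  Standard curves for a
polyQ-antibody channel and a total-HTT-antibody channel are fitted with the
four-parameter logistic model

&nbsp;&nbsp;&nbsp;&nbsp;*y*(*x*) = Bottom + *x*ʰ(Top − Bottom)/(*x*ʰ + EC50ʰ)

using 1/*y*² weighted least squares.  In the linear dynamic range each
channel obeys *y* = slope·*x*, and the ratio of slopes (or of
background-subtracted signals at a matched load) is a monotone function of
polyQ length:

&nbsp;&nbsp;&nbsp;&nbsp;*r* = *f*(Q), &nbsp; Q̂ = *f*⁻¹(*r*), &nbsp;
sd(Q̂) = sd(*r*)·|dQ/d*r*|

where *f* is the best of four candidate regression families (linear,
logarithmic, power, exponential) chosen by R², and ratio SDs follow
sd(A/B) = (A/B)·√((sd_A/A)² + (sd_B/B)²).  For a mixed protein population
measured in the linear range, Q̂ estimates the *fraction-weighted average*
polyQ length.

**Average CAG repeat length from peak traces.**  Fragment-analysis peaks one
repeat apart are reduced per allele: drop peaks below 5 % of the tallest,
normalize heights to weights, take the weighted mean repeat length, then
average the alleles.

**Simulation and validation.**  A seeded generator produces standard
curves, mixture signals, peak traces and paired protein/DNA cohorts with
stated generative rules, and the pipeline module adds detection-limit QC
(background + 3 SD), western-blot normalization, batch correction factors,
and the protein-vs-DNA regression.  Validation mixture recipes
(five-component blends of Q25–Q72 standards) ship as packaged fixtures.

## Worked example

```python
from polyqlen import *

cfg = SimulationConfig(seed=42, noise_cv=0.05)           # 5% replicate CV
polyq = fit_standard_series(simulate_standard_curves(cfg, "polyq"))
total = fit_standard_series(simulate_standard_curves(cfg, "total"))
cal, qs, ratios = build_calibration(polyq, total)
print(f"calibration: family={cal.family_}, R^2={cal.r_squared_:.4f}")

mix = MixtureSpec([(25, 0.18), (38, 0.21), (48, 0.21), (55, 0.20), (72, 0.20)],
                  total_concentration=100.0, label="avgQ48a")
sp = simulate_mixture_signals(mix, cfg, "polyq")
st = simulate_mixture_signals(mix, cfg, "total")
num, den = sp.signals - cfg.bottom, st.signals - cfg.bottom
r, r_sd = propagate_ratio_sd(num.mean(), num.std(ddof=1)/np.sqrt(2),
                             den.mean(), den.std(ddof=1)/np.sqrt(2))
est = estimate_average_polyq(r, r_sd, cal.model_)
print(f"estimated average polyQ: {est.q_mean:.2f} +/- {est.q_sd:.2f}")

trace = simulate_peak_trace(modal_cag=140, expansion_bias=2.5, spread=3.0,
                            n_molecules=2000, seed=42)
print(f"average CAG repeat: {average_cag_from_trace(trace, n_alleles=1).combined_average:.2f}")
```

prints

```
calibration: family=power, R^2=0.9887
estimated average polyQ: 50.65 +/- 0.87
average CAG repeat: 142.42
```

The blend's true fraction-weighted average is 47.96 glutamines, so the
estimate at 5 % measurement noise lands within 5.6 % relative error — inside
the method's validated intra-batch envelope (≤ 13 % relative error, ≤ 4 %
CV).  The peak trace was generated with its repeat distribution centered at
142.5 (modal 140 plus an expansion bias of 2.5), and the thresholded
weighted average recovers it.

A CLI mirrors these steps for file-based work:

```bash
polyqlen simulate --seed 3 --channel polyq --out polyq.csv
polyqlen simulate --seed 3 --channel total --out total.csv
polyqlen calibrate polyq.csv total.csv --out calibration.yaml
polyqlen estimate-polyq calibration.yaml ratios.csv --out estimates.csv
polyqlen avg-cag peaks.csv --out cag.csv
polyqlen correlate samples.csv --out report.csv
```

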