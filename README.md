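# ricenc

Critical nitrogen dilution curves and nitrogen-nutrition diagnostics for
japonica rice, built from multi-rate N fertilizer trials.

## The problem

As a rice crop accumulates aboveground dry matter (DW, t ha⁻¹), the
minimum plant N concentration that still permits maximum growth — the
*critical* N concentration N_C (% of dry weight) — declines, because
structural tissue dilutes the metabolically active N pool. The decline
follows a power law

    N_C = a · DW^(−b)

where *a* is the plant N concentration at DW = 1 t ha⁻¹ and *b* the
dimensionless dilution exponent. The **N nutrition index**

    NNI = N_measured / N_C

diagnoses crop N status at any biomass: NNI = 1 is optimal, > 1 surplus,
< 1 deficient. Curve parameters vary with cultivar, region, year and
management, so a *universal* curve usable at regional scale has to be
distilled from many group-specific curves. `ricenc` implements and
cross-validates the three routes used for japonica rice:

* **SDM** (simple data-mixing): per sampling date, one-way ANOVA splits
  N-rate treatments into N-limiting and non-limiting sets; the critical
  point is the intersection of the linear biomass–N% response (limiting
  treatments) with the plateau biomass (non-limiting treatments); all
  critical points are pooled into one power fit with a bootstrap band.
* **RFA / Average**: the 14 growth, thermal and cultivar indicators
  (LAI, DW, SLR, SLA, AGDD at tillering end and over the vegetative
  period, plus TGW/AC/PH reference values) are screened by univariate
  R²; the top three per parameter feed a random forest (500 trees, mtry
  tuned by leave-one-out RRMSE) or a multiple linear regression; the
  universal parameters are the means of the per-group estimates.
* **BHM**: a Bayesian hierarchical linear-plus-plateau model —
  `DW_ij ~ N(B_j − S_j · max(0, a·B_j^(−b) − N_ij), σ)` with flat priors
  a ∈ (0, 6), b ∈ (0, 1) — sampled by an adaptive Metropolis-within-Gibbs
  MCMC; group posteriors are pooled and summarised by the Mean, the
  Median and the **MPN** (most probable number: the mode of the kernel
  density estimate of the pooled draws).

A universal curve is accepted when the NNI it assigns to each plot
sample agrees (R², RRMSE) with the NNI from that sample's own
group-specific curve.

Because plot-level raw data from real trial series are rarely published,
the package ships a first-class synthetic-trial generator with known
ground truth (population a ~ N(3.56, 0.21), b ~ N(0.34, 0.08), truncated
to the prior supports), so every stage is testable end to end.

## Worked example

```bash
ricenc simulate --seed 7 --out-dir out
ricenc sdm      --samples out/samples.csv --out-dir out
ricenc bhm      --samples out/samples.csv --out-dir out \
                --n-adapt 2000 --n-sample 2000 --n-chains 2 --thin 4 --seed 7
ricenc estimate --features out/features.csv --params out/bhm_specific.csv \
                --out-dir out --rf-ntree 200 --rf-mtry 2 --seed 7
ricenc validate --samples out/samples.csv --curves out/curve_bhm.csv \
                --specific out/bhm_specific.csv --out-dir out
ricenc report   --out-dir out
```

prints (abridged):

```
SDM curve: a=3.8565 b=0.3834 (135 points, 10 dates skipped)
BHM pooled MPN: a=3.4052 b=0.3172 (29 groups)
RFA universal: a=3.4873 b=0.3369 | Average: a=3.4923 b=0.3401
BHM-MPN: R2=0.860 RRMSE=0.131
provenance        a        b  ...
   BHM-MPN 3.405162 0.317193  ...
       RFA 3.487328 0.336888  ...
   Average 3.492287 0.340064  ...
       SDM 3.856525 0.383412  ...
```

The synthetic population mean here is (a, b) = (3.56, 0.34). Averaging
the 29 group posteriors (`Average`, `RFA`) lands close to it; the SDM
mixed curve drifts higher because noisy early-season critical points
enter the pooled fit; and all universal curves reproduce the
group-specific NNI with R² ≈ 0.86 — i.e. any of them would diagnose N
status about as well as knowing each group's own curve. The same
objects are available as a library:

```python
from ricenc import DilutionCurve, critical_n, nni, diagnose

curve = DilutionCurve(a=3.36, b=0.30, provenance="SDM")
critical_n(curve, 2.5)          # 2.552 % N at 2.5 t/ha
diagnose(curve, 2.5, 3.1)       # ('surplus', 1.215)
```

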