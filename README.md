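# defol

Functional growth analysis of plant defoliation responses: spline-based
relative growth rate (RGR) estimation, the RGR = NAR × SLA × LWR
decomposition with growth response coefficients, ontogenetic stage
classification of compensation, permutation tests for ontogenetic
plasticity, and Poisson-GLM fitness tolerance analysis — plus a calibrated
synthetic-experiment generator so the whole pipeline runs without external
data.

## Who this is for

Plant ecophysiologists and evolutionary ecologists analysing
destructive-harvest growth experiments with a damage treatment (simulated
or natural herbivory).  The package answers three linked questions:

1. **How does growth respond over ontogeny?**  RGR is estimated as the
   derivative of a cubic smoothing spline through ln(shoot dry mass), and
   the signed plasticity (X_D − X_C)/X_C tracks how far defoliated plants
   sit below or above controls at each age.
2. **Which trait drives the response?**  RGR factors exactly into net
   assimilation rate (NAR), specific leaf area (SLA) and leaf weight ratio
   (LWR).  The growth response coefficient

       GRC_X = (ln X_D − ln X_C) / (ln RGR_D − ln RGR_C)

   is the share of the RGR change attributable to component X; the three
   GRCs sum to 1 identically.  The post-shock trajectory is segmented into
   buffering (below controls until first equality), steady (parity within
   ±ε) and overcompensatory (above controls) states, and each GRC is
   tested against zero within each state (t-test or exact tie-aware
   Wilcoxon signed-rank).
3. **Does the plant tolerate the damage?**  Total seed number is modelled
   with a log-link Poisson GLM on the ecotype × treatment factorial; the
   tolerance of an ecotype is its fitness slope across environments
   (overtolerance > 0, complete tolerance ≈ 0, undertolerance < 0).

## Worked example

```python
import defol
from defol.datatypes import RunConfig

exp = defol.simulate_experiment(noise_cv=0.0, seed=1)   # two-ecotype preset experiment
result = defol.analyze(exp.observations, exp.seed_counts,
                       RunConfig(n_permutations=0))
print(defol.summarize(result))
```

prints

```
defol analysis summary
======================

PN: buffering duration 99.0 h (t_eq = 1563.0 h)
PN: end-of-experiment RGR plasticity +37 % at 1782 h
PN: pre-defoliation GRCs  NAR +0.37  SLA +0.33  LWR +0.30
SD: buffering duration 122.0 h (t_eq = 1586.0 h)
SD: end-of-experiment RGR plasticity +1895 % at 1782 h
SD: pre-defoliation GRCs  NAR +0.71  SLA +0.15  LWR +0.14

seed-set tolerance (Poisson GLM):
  ecotype: LR chi2 = 1126.45, df = 2, p = 2.49e-245
  treatment: LR chi2 = 102.12, df = 2, p = 6.68e-23
  ecotype:treatment: LR chi2 = 57.59, df = 1, p = 3.23e-14
  PN: mean seeds control 500.0, defoliated 503.3 (+0.7 %)
  SD: mean seeds control 296.7, defoliated 363.6 (+22.6 %)
  letter display: PN:control=a, PN:defoliated=a, SD:control=b, SD:defoliated=c
```

Reading: the fast-growing ecotype (PN) takes 99 h to buffer an immediate
−81 % RGR shock and ends only 37 % above controls, with no seed-set
difference (complete tolerance, shared letter *a*); the slow-growing
ecotype (SD) takes 122 h but ends with massive RGR overcompensation and
~23 % more seeds when defoliated (overtolerance) — the growth-rate /
tolerance trade-off the analysis is built to expose.

The `examples/` directory has one short script per capability
(simulation, GRC decomposition, stage classification, tolerance GLM,
punch defoliation); each prints its numbers with a line on what they mean.
A thin CLI wraps the same pipeline:

```sh
defol simulate --seed 1 --noise-cv 0.05 --out sim/
defol analyze --harvest sim/harvest.csv --seeds sim/seeds.csv --out results/
defol report --results results/
```

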