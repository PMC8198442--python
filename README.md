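# gcdose

Quantitative analysis of glucocorticoid (prednisolone) action on cultured
leukemic cells: dose–time growth/death/size kinetics, glycolytic
stoichiometry, two-channel microarray preprocessing and differential
expression, and unsupervised clustering — plus a synthetic-data generator
that emulates the measured structure of such an experiment so every stage
is testable without access to raw laboratory data.

It is written for computational biologists analysing dose–response
experiments on suspension cell cultures (cell counts, flow-cytometric
viable/apoptotic/necrotic fractions, forward-scatter size, supernatant
biochemistry, cDNA microarrays).

## What it computes

**Kinetics.** For any quantity X(d, t) on the dose × time grid
({−24, 0, 4, 24, 48, 72} h × {0, 0.01, 1.09, 10, 50, 100, 175, 700} μM by
default): interval "velocities" dX/dt, "accelerations" d²X/dt² over
interval midpoints, and the 0→72 h "Total" rate. Doubling time uses the
classical decadic-log formula

&nbsp;&nbsp;&nbsp;&nbsp;t_d = Δt / (3.32 · Δlog₁₀ N).

**Glycolytic efficiency.** Anaerobic glycolysis yields 2 mol lactate per
mol glucose (C₆H₁₂O₆ → 2 CH₃CHOHCOOH). The reaction efficiency

&nbsp;&nbsp;&nbsp;&nbsp;α = C_observed / C_theoretical,&nbsp;&nbsp;
C_theoretical = 2 · Δ[Glc] (molar)

is computed per (dose, time) against either the pre-dosing baseline or the
previous sampled time.

**Microarrays.** Multiplicative background correction (log-background
subtracted from log-foreground, i.e. division by a robust per-array
background estimate), geometric-mean replicate averaging, per-probe mean
log₂ ratios, three normalizations (local-quadratic loess with 10% span,
rank-invariant, quantile), and the simple-loop consistency check
r(0v3) = r(0v1) + r(1v3).

**Statistics & clustering.** Per-probe Student's t-tests with
Benjamini–Hochberg FDR and an AND-rule across experiments; Pearson/Spearman
correlations and a derivative-pair correlation battery; biharmonic
(Green's-function) surface regression; hierarchical clustering; k-means
(squared Euclidean, 100 random restarts, best-of-runs) with
Calinski–Harabasz selection of the cluster number.

## Worked example

```python
from gcdose import StudyDesign, generate_dataset, efficiency
from gcdose.kinetics import doubling_time, finite_differences

series, panel = generate_dataset(StudyDesign(seed=7))
pop = series["population"].data
dt = doubling_time(pop.loc[0.0, 0.0], pop.loc[0.0, 72.0], 72.0)
print(f"control doubling time: {dt.t_d:.1f} h")

eff = efficiency(panel, mode="stepwise")
print(f"median stepwise alpha: {eff.alpha.stack().median():.3f}")

nec = series["necrotic_fraction"].data[72.0]
print(nec.round(3))
```

prints

```
control doubling time: 45.9 h
median stepwise alpha: 0.821
dose_uM
0.00      0.028
0.01      0.033
1.09      0.303
10.00     0.035
50.00     0.034
100.00    0.027
175.00    0.029
700.00    0.030
```

The estimated doubling time sits near the 45.2 h calibration (the 5% CV
measurement noise moves it slightly); the median stepwise efficiency is
below the generating α_true = 0.9 because measurement noise on small
interval yields is asymmetric; and the necrotic fraction at 72 h peaks
sharply at the 1.09 μM dose level — the biphasic threshold — while the
highest dose is indistinguishable from the untreated control.

The same analysis end to end, from the command line:

```sh
gcdose run-all --seed 7 --outdir run7     # all artifacts + summary.json
gcdose simulate --seed 7 --outdir sim7    # synthetic tables only
gcdose kinetics sim7/dose_time_series.csv --quantity population
gcdose metabolism sim7/metabolite_panel.csv --mode stepwise
```

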