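# Methods

## The experimental design being modelled

A glucocorticoid-resistant T-lymphoblastic leukemia suspension culture is
seeded 24 h before dosing (time −24 h) and treated at 0 h with prednisolone
at 0, 0.01, 1.09, 10, 50, 100, 175 and 700 μM. Cell counts, flow-cytometric
viable/apoptotic/necrotic fractions and forward-scatter (FS) size are
measured at −24, 0, 4, 24, 48 and 72 h; supernatant biochemistry (glucose,
lactate in mg/dL; LDH, ALP in IU/L; K⁺, Na⁺, Ca²⁺, Mg²⁺ in mmol/L) on the
same grid. Gene expression is assayed on two-channel cDNA arrays in a
simple-loop design at 4 h — control vs low dose (0v1), low vs high (1v3),
control vs high (0v3), each in triplicate — plus two single reference
hybridizations at 72 h ('4': 22 vs 700 μM; '5': control vs 700 μM). Doses
are carried in μM throughout; no mg/mL conversion is performed anywhere.

## Kinetics

Interval rates are forward differences (X(tᵢ₊₁) − X(tᵢ))/(tᵢ₊₁ − tᵢ),
labelled by the right endpoint ("the rate at 24 h" is the 4→24 h slope).
Accelerations difference consecutive rates over the spacing of interval
*midpoints*, which makes them exact for quadratics on the non-uniform grid.
The "Total" rate is (X(72) − X(0))/72 h, the "Total" acceleration the
first-to-last rate change over the midpoint span (midpoint convention; the
endpoint alternative was considered and rejected because it is not exact on
quadratics). The pre-dosing point (−24 h) is excluded from kinetics by
default: that interval reflects seeding, not drug response. Missing values
propagate only into the rates/accelerations that touch them.

Doubling time is t_d = Δt/(3.32 · Δlog₁₀ N). The constant is kept at the
conventional printed value 3.32 rather than 1/log₁₀2 = 3.3219…, which biases
estimates upward by 0.058%; with the 45.2 h calibration the noiseless 0→72 h
estimate is 45.226 h. A non-growing interval (N_end ≤ N_start) yields
t_d = ∞ with a `growing = False` flag, never a silent negative number.

## Glycolytic efficiency

The lumped reaction C₆H₁₂O₆ → 2 CH₃CHOHCOOH fixes the theoretical yield at
2 mol lactate per mol glucose; cofactors (NAD⁺/NADH, ADP/ATP, Pᵢ, H₃O⁺) are
not tracked. Concentrations are converted to mmol/L (MW glucose 180.16,
lactate 90.08 g/mol) before the 2:1 factor is applied — the factor is
meaningless on mass units, and since MW(lactate) is exactly half
MW(glucose), full conversion means equal *mass* concentrations, a property
the generator exploits and a test guards against unit confusion.

α = C_observed/C_theoretical with C_theoretical = 2·(Glc_ref − Glc_t) and
C_observed = Lac_t − Lac_ref, both molar. Baseline mode references the
grand mean across doses at the earliest (pre-dosing) time, since all flasks
share medium before dosing; stepwise mode references the previous sampled
time per dose. Cells with no net glucose consumption are flagged
`undefined` (not set to 0); α > 1 and α < 0 are retained with flags — the
bound 0 < α < 1 is a modelling assumption about ideal data, not a guarantee.

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

**Growth.** Piecewise-exponential. The control culture has an *effective*
0→72 h doubling time of 45.2 h; within the window the rate follows the
interval weights (1.0, 1.3, 1.0, 0.75) on [0,4], [4,24], [24,48], [48,72] h,
whose time-weighted mean is exactly 1 — velocity rises through 4→24 h and
falls by 72 h while the whole-window calibration stays exact. Doses modify
the rate multiplicatively through a log-normal bump centred at 0.1 μM
(amplitude 0.15, width 1.5 ln-units), encoding the mitogenic effect of
nanomolar–micromolar doses; seeding density is 1100 cells/μL (the middle of
the protocol's 0.9–1.3 × 10³ range).

**Death fractions.** Necrotic fraction = 0.03 + 0.25 · bump(d; centre
1.09 μM, width 0.8 ln-units) · ramp(t), with the ramp reaching 1 at 72 h —
necrosis peaks at the 1.09 μM level late, and the highest dose matches the
control. Apoptotic fraction = (0.04·(1 − anti(d)) + 0.40·d/(d + 50 μM)) ·
ramp(t) with a late-activating ramp (cytotoxicity is a 48–72 h phenomenon)
and a small anti-apoptotic dip at the mitogenic doses; above 10 μM it is
monotone increasing in dose. Viable = 1 − necrotic − apoptotic. Noise
multiplies each fraction log-normally and the triple is renormalised, so
fractions always lie in [0,1] and sum to 1.

**Biochemistry.** Glucose consumption is proportional to the analytically
integrated population, scaled by a dose-dependent uptake-suppression factor
0.25 + 0.75/(1 + d/20 μM) — high doses take up less glucose. Lactate rises
by α_true (default 0.9) times the consumed glucose at 2:1 molar
stoichiometry, so stepwise efficiency recovers α_true exactly at zero
noise. LDH and ALP are baseline plus a term proportional to the necrotic
count; K⁺ is affine in total population (3.8 mmol/L + 4×10⁻⁴ per cell/μL),
making the K⁺–population correlation recoverable; Na⁺/Ca²⁺ follow the
qualitative patterns (not acceptance-bearing); Mg²⁺ is constant plus noise.
Baseline glucose is 180 mg/dL (RPMI-class medium with serum).

**Noise.** All measurement noise is multiplicative log-normal (unit
median), CV 0.05 on counts/fractions/sizes and 0.03 on biochemistry.
Magnitudes are free parameters of the generator — the experiment reports
none — chosen as typical analyzer repeatability.

**Microarrays.** 1200 probes; 10% differentially expressed, split evenly
over four archetypes in (r₀ᵥ₁, r₁ᵥ₃, r₄, r₅) log₂-ratio space: up-low/down-high
(+2, −3, −1.5, −2), its mirror, up-throughout (+1.5, +1, +1, +2.5) and
down-throughout — the biphasic patterns the dose response predicts — with
per-probe jitter SD 0.3; r₀ᵥ₃ = r₀ᵥ₁ + r₁ᵥ₃ exactly by construction. Spot
model: local background = 64 · 2^ε, foreground = background ·
2^(base + ratio + ε′), base ~ N(10, 1.5²) log₂-intensity shared across
arrays, all ε ~ N(0, 0.15²) in log₂. Loop designs in triplicate, reference
designs single.

**What the generator does not emulate** (hence what green tests do not
show about real data): cell-cycle phase structure, event-level flow
cytometry, spatial/print-tip array artefacts, intensity-dependent dye bias
beyond what normalization testing injects explicitly, probe-specific
hybridization efficiency, and any biological coupling between expression
archetypes and the kinetic variables.

## Microarray preprocessing

Order fixed as MBC → replicate averaging → ratio → normalization. The
"robust estimate of background noise" per channel is the per-array median
of local backgrounds (a lower quantile, or per-spot backgrounds, are
options). Corrected intensity is 2^(log₂F − log₂Bl) = F/Bl. Replicates are
averaged by geometric mean per channel (equivalently, arithmetic mean of
log₂ intensities; missing/masked spots shrink the per-probe replicate count
rather than poisoning the product). The mean ratio is (1/j)Σ log₂(Rᵢ/Gᵢ) =
log₂ of the geometric mean of ratios — the red/green orientation follows
Cy5/Cy3.

Normalizations: (a) loess — local *quadratic* regression of M = log₂(R/G)
on A = ½log₂(RG), tricube weights, span 10% of probes (≥ degree+2 points
per window enforced), fitted trend subtracted from M and reapportioned
symmetrically to the channels; (b) rank-invariant — iterative selection of
probes whose within-set red/green ranks differ by < 5% of the set size,
extreme 2% of ranks excluded, convergence when the set stops changing, then
a local-linear curve through the invariant set on the MA plot is
subtracted; (c) quantile — every channel vector across arrays is replaced
by the mean of the order statistics, ties resolved by averaging the tied
order statistics. The loop residual r₀ᵥ₁ + r₁ᵥ₃ − r₀ᵥ₃ (median absolute
value as summary) compares the three on equal terms; which method minimises
it is reported, not presumed.

End-to-end recovery tolerance (derived from the noise model before
implementation): each replicate log₂ ratio carries four independent
N(0, σ²) log₂ terms (two backgrounds, two foregrounds), so a triplicate
contrast has SD 2σ/√3 ≈ 0.173 and a single-replicate contrast 2σ = 0.30 at
σ = 0.15; the replicate-weighted RMSE bound is √((3·0.173² + 2·0.30²)/5) =
0.232, padded ×1.75 for normalization edge effects at the DE tails → 0.40.
The loop-residual scaling check uses the same model: residual SD √3·(2σ/√3)
= 2σ, median |residual| = 0.6745·2σ.

## Statistics

Differential expression: per-probe two-sample Student's t-test (pooled
variance; Welch optional), Benjamini–Hochberg step-up FDR over all probes
(the standard choice where the procedure itself is unspecified), and the
AND rule — significant only if p < 0.05 *and* FDR < 0.05 in every
experiment (thresholds configurable). Probes constant in both groups with
equal means get p = 1 by convention. In the pipeline, each loop contrast's
replicate log₂ ratios are tested against a zero-ratio control group of the
same size (under no differential expression the ratio is centred on 0).

The derivative-pair battery computes the eight unique pairs — first and
second derivatives of the metabolite concentration against the matching
derivatives of population, FS size, necrotic and apoptotic counts —
separately for glucose and lactate, pairing values *across doses at a fixed
interval* (the across-time axis is available by transposing the inputs).
Correlation p-values use the t-approximation with n−2 df; zero-variance
inputs are undefined and flagged.

Biharmonic surface regression solves the Green's-function system
z(q) = Σ wᵢ g(‖q − pᵢ‖) + a₀ + a₁x + a₂y, g(r) = r²(ln r − 1), g(0) = 0,
with orthogonality side conditions Σwᵢ = Σwᵢxᵢ = Σwᵢyᵢ = 0. It interpolates
the data exactly and reproduces affine surfaces through the trend term.
Duplicate sites and collinear point sets are rejected (singular system).

## Clustering

Hierarchical: scipy agglomerative linkage; defaults are
Pearson-correlation distance for genes and Euclidean for samples with
average linkage (standard two-channel-era practice; both configurable),
dendrograms exported as Newick with branch lengths from merge heights.

K-means: Lloyd's algorithm, squared Euclidean distance. Each candidate k
runs 100 restarts; restart r of candidate k draws its initial centroids
(distinct data points) from the child seed (master, k, r), so one master
seed reproduces everything. Assignment ties break to the lowest centroid
index; an emptied cluster is re-seeded from the point currently farthest
from its assigned centroid (distinct points when several clusters empty at
once). The best run minimises the within-cluster sum of squares; the
selected k maximises the Calinski–Harabasz score (B/(k−1))/(W/(n−k)).

## Pipeline

A single pydantic-validated YAML config (unknown keys rejected) drives
generate → kinetics → metabolism → battery → microarray → DEG →
clustering. One master seed fans out to every module; every intermediate
table is written as CSV next to the machine-readable `summary.json`
(doubling times per dose, median stepwise α, DEG counts, loop residual
summary, selected k, CH trace) and the resolved config. The k-means stage
clusters the combined-significant probes when enough survive the AND rule,
otherwise all probes.

## Problem sizes

Tests and the acceptance script use the generator's native sizes: 8 doses ×
6 times, 1200 probes × 11 hybridizations, 1000 random efficiency
trajectories, 10 seeds × (k = 2..10 × 100 restarts) for cluster-number
recovery. A full test run takes well under a minute on one CPU.

## Known limitations

The doubling-time constant 3.32 is kept as conventionally printed (0.06%
bias). The rank-invariant variant is one reasonable member of a family —
threshold, rank-trimming and stopping rule are documented defaults, not a
canonical algorithm. α and the battery are descriptive statistics with no
uncertainty quantification. The generator's archetypes make cluster-number
recovery well-posed by design; real expression data need not separate so
cleanly. Reported correlation p-values ignore multiplicity across the
battery's 56 cells.
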