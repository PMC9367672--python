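# Methods

This note documents the models, numerical choices and known limitations
of dmpkit, in the order the pipeline runs them.

## Enzyme kinetics

Three saturation laws are supported, covering the kinetic phenotypes
seen when one compound is turned over by different species' microsomes:
classic single-site Michaelis–Menten (v = Vmax·S/(Km+S)), two-site
biphasic kinetics (the sum of two saturable phases with distinct
affinities Ks1 < Ks2 — the signature of two isozymes, or of one enzyme
with two substrate molecules bound), and substrate inhibition
(v = Vmax·S/(Ks+S+S²/Ksi), unimodal with its maximum at √(Ks·Ksi)). All
laws give v(0)=0 and non-negative velocities for admissible parameters.

**Objective.** Unweighted nonlinear least squares by default; optional
1/v or 1/v² weighting of the squared residuals. With peak-area-derived
velocities the measurement error is approximately proportional to the
signal, and then 1/v² (relative least squares) is the matched-likelihood
objective; it is what the packaged recovery studies use. Unweighted
fitting with proportional error lets the few near-saturation points
dominate the objective, which both inflates parameter variance and makes
the information criterion prone to rewarding a third parameter that
chases the noise of the top point.

**Initialisation and multi-start.** The Michaelis–Menten start comes
from the Eadie–Hofstee linear regression (intercept → Vmax, −slope → Km;
fallback 1.2·max(v) and median(S) when the regression is degenerate).
The three- and four-parameter laws start from a log-spaced grid spanning
[0.1×, 10×] that start: 5×5 over (Ks, Ksi) for substrate inhibition,
5×5×5 over (Ks1, Ks2, Vmax split ∈ {0.1,…,0.9}) for biphasic. The whole
grid is screened by objective value and the best 10 starts are refined
with the bounded trust-region solver (`scipy.optimize.least_squares`,
lower bound 1e-9 keeping parameters strictly positive, tolerances
1e-12). Enumeration order is fixed, so fits are bit-reproducible. An
exhaustive grid-search oracle (200 log-spaced points per nonlinear
parameter, velocities solved linearly, Nelder–Mead refinement) agrees
with the fitter to well under 1% in rss in the tests.

**Degrees of freedom.** Fitting demands n ≥ max(5, p+1) points for a
p-parameter law, so the four-parameter biphasic model is fittable on a
5-point series (zero residual degrees of freedom are accepted for the
point estimate; standard errors are then reported as NaN). Biphasic fits
are canonicalized to Ks1 < Ks2, since the two phases are exchangeable.

**Model selection.** Candidates are ranked by AICc with k = p + 1
(residual variance counted). When the correction denominator n−k−1 is
non-positive the AICc is +∞ — a four-parameter law simply cannot be
justified on such a design. Ranks within ΔAICc < 2 go to the law with
fewer parameters: atypical kinetics must earn its extra parameters. This
is a sharper, reproducible stand-in for the visual Eadie–Hofstee
judgement traditionally used.

**Intrinsic clearance.** CLint = Vmax/Km (µL/min/mg protein, or per nmol
CYP for recombinant enzymes); Vmax/Ks under substrate inhibition; and
the low-substrate limit Vmax1/Ks1 + Vmax2/Ks2 for biphasic kinetics,
because therapeutic exposures sit far below Ks2 and the origin slope is
the clearance-relevant quantity. Report tables round half-to-even at two
decimals; machine CSVs keep full precision.

## IVIVE (well-stirred model)

Per-metabolite clearances with a shared enzyme source and protein basis
are summed; the scaling factor SF = microsomal protein (mg/g liver) ×
liver weight (g/kg body weight) converts to whole-body terms, with the
single µL→mL conversion applied in `scale_clint`. The well-stirred liver
model CLH = QH·fu·CLint/(QH + fu·CLint) treats the organ as one
well-mixed compartment; CLH is strictly below the blood flow QH and the
algebraic inversion CLint = QH·CLH/(fu·(QH−CLH)) is exact, which the
tests verify to 1e-10 across extraction ratios up to 0.99. fu defaults
to 1 (no binding data), so predictions are upper bounds in the usual
case fu < 1. The built-in physiology table (dog 32 g/kg, 77.9 mg/g,
30.9 mL/(min·kg); rat 40, 44.8, 55.2; human 25.7, 48.8, 20.7) is
user-overridable via CSV. Extraction categories use strict inequalities
(<30% low, >70% high), with the boundaries falling in the intermediate
class. Parallel-tube and dispersion liver models are out of scope.

## Metabolic stability

T1/2 = ln2/(−slope) from OLS on ln(% remaining) versus time, including
the t=0 point (ln 100). Percentages must be strictly positive —
negative noise excursions are rejected rather than clipped, because a
clip would bias the log-linear slope. A non-negative slope raises an
explicit no-depletion status instead of a sentinel half-life.

The packaged 0/30/60/90-min design identifies slow decays only weakly:
for a true half-life of 673 min the parent falls ~9% over the whole
course, comparable to a 5% assay CV. Error propagation through the OLS
slope (noise sd 0.05 on three free points; Sxx = 4500) gives a slope
standard error of 5.5e-4/min against a true rate of 1.03e-3/min, i.e. a
median absolute relative error around one third, and the packaged
recovery study measures ≈32% (200 seeds). Half-life claims at that
design/noise/decay combination should be treated as order-of-magnitude.

## Noncompartmental analysis

Cmax/Tmax are read from the observations (ties to the earliest time);
AUC0–t uses the linear trapezoid over the observed span only — no
back-extrapolation to C0 and no extrapolation to infinity. On the
sparse 9-point trial grid (0, 0.25, …, 8 h) the trapezoid overestimates
a convex mono-exponential decline by ≈4.7%; on dense grids it converges
(0.1% at 2001 points), and AUC is exactly additive over interior splits.
λz comes from log-linear regression on the suffix of post-Tmax points
with the best adjusted r² (minimum three points, longer suffixes winning
exact ties), mirroring common NCA software; concentrations below a
configurable LOQ are dropped with a logged warning first. A profile that
peaks at its last sample raises a no-elimination error; partial results
(e.g. AUC without a terminal phase) are returned with stage-labelled
issues rather than aborting.

## Screening normalizations

Peak-area matrices are normalized per metabolite column to the largest
producing species = 100%; not-detected cells are carried as an explicit
marker, never as zero, since "absent" and "small" are different
observations. The operation is idempotent and scale-invariant per
column. Percent inhibition is 100·(1 − inhibited/control); activation
(inhibited above control) is preserved as a negative value with a logged
warning by default (information-preserving), with an opt-in clip at 0.
Isoform phenotyping sorts by formation activity (alphabetical
tie-break) and reports shares of the total.

## Synthetic data

Generators are pure functions of (parameters, seed): a global seed
expands into per-generator streams via `SeedSequence(seed, spawn_key)`
with fixed stream ids, so adding a generator never perturbs existing
draws. Velocity and depletion noise is proportional Gaussian
(v·(1+ε), ε ~ N(0, cv²)) — the error structure of integrated
chromatographic peaks — with negative draws truncated at zero and
logged; plasma profiles use unit-mean lognormal factors instead, keeping
concentrations positive as a bioanalytical assay reports them. The
default noise CV is 0.05, a typical triplicate-incubation scatter.
Default designs copy the laboratory layouts (8 log-spaced concentrations
over 1–200 µM; 0/30/60/90 min; the 9-point IV schedule) so that recovery
studies probe the identifiability those designs actually have.

What the generators do **not** emulate: chromatographic traces and peak
integration, inter-occasion and inter-animal variability, correlated
replicate errors, multi-phasic depletion, distribution phases in plasma
profiles, or values censored at a quantification limit. Passing recovery
tests therefore demonstrate the estimators are correct and well-behaved
under the stated error model, not that real assays achieve these error
rates.

## Recovery-study conditions

The packaged studies fix their ground truths once: Michaelis–Menten
truth Vmax = 158.26 pmol/min/mg, Km = 121.13 µM (a reported
rat-microsome estimate whose Km lies inside the 1–200 µM design, so the
plateau is actually sampled — a truth with Km above 200 µM, as reported
for human microsomes, is weakly identifiable on this design by
construction); substrate-inhibition truth (100, 50, 200) with
Ksi = 4·Ks; biphasic truth (10, 5, 100, 500). With 5% CV noise and 100
seeds, AICc selection under relative least squares recovers the
generating law in 100% of Michaelis–Menten runs and 89% of
substrate-inhibition runs; the biphasic truth frequently collapses onto
Michaelis–Menten at n = 8 because the AICc small-sample penalty for a
fourth parameter is severe — an honest reflection of what an 8-point
design can support.

## Problem sizes

Stochastic studies use 100 seeds (model selection) and 200 seeds
(half-life recovery); the grid oracle uses 200 points per nonlinear
parameter on 5-point instances; dense-grid AUC checks use 2001 points.
These sizes keep every study's Monte-Carlo error well below the margins
being asserted.
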