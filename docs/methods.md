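# Methods

`leukowalk` implements a complete pipeline for deciding which 3D random-walk
model best describes a population of migrating leukocytes observed by
intravital two-photon imaging: motility metrics, bias-aware statistical
fitting of speed distributions, agent-based simulation of six walk models
under the imaging constraints, multi-objective calibration, and Pareto-front
model selection.

## Track data and motility metrics

A track is a time-ordered sequence of 3D cell-centroid positions (µm)
sampled every Δt seconds.  From each track we derive:

* **translational step speeds** ζ = |d_i| / (Δt/60) in µm/min, where d_i is
  the displacement vector between consecutive observations;
* **turn speeds** ϕ = angle(d_i, d_{i+1}) / (Δt/60) in °/min.  The largest
  measurable angle between consecutive displacements is 180°, so the
  metric has a hard ceiling of 180/(Δt/60): 360 °/min at 30 s sampling and
  240 °/min at 45 s.  A zero-length displacement leaves the angle
  undefined; that observation is skipped and counted, not imputed as zero;
* **meandering index** = net first-to-last displacement / total path
  length, in [0, 1] (1 = straight, 0 = returned to start).

Tracks whose **net** displacement is below 27 µm are excluded before any
profile is built (removing sessile contaminants); the same filter is
applied to simulated data so comparisons are fair.  "Net" (first-to-last,
threshold inclusive: ≥ 27 µm retained) was chosen over path length because
it matches the standard Imaris "track displacement" export.

The **motility profile** pools step speeds, turn speeds and meandering
indices over all surviving tracks — these three distributions are the
calibration objectives.  Per-track medians of both speed types are kept as
diagnostics only.  Two further diagnostics are computed but never used in
calibration: the mean-squared-displacement curve (overlapping windows at
all lags up to 25% of the longest track duration; slope from least-squares
regression of log10 MSD on log10 lag) and the displacement
autocorrelation, reported as per-lag median and IQR of the per-pair cosine
d_i·d_{i+k}/(|d_i||d_{i+k}|).  The cosine normalisation was chosen for
scale invariance and the [−1, 1] contract.

Mixed sampling intervals are supported: each track carries its own Δt and
pooling mixes the units-consistent per-minute quantities.

## Statistical distribution families

Four speed-distribution families are supported: uniform U(λ) on (0, λ];
Lévy L(α, β) via the Chambers–Mallows–Stuck construction (|L| is used —
speeds are magnitudes; heavy-tailed for α < 2, Gaussian-limit at α = 2);
homogeneous Gaussian G(μ, σ); and the hierarchical "heterogeneous
Gaussian" in which each cell draws a personal (μ_i, σ_i) once at creation
from G(μ_M, σ_M) and G(μ_S, σ_S).  Following the field's notation the
second Gaussian parameter is written σ² in places, but it is used as the
standard-deviation argument throughout: in the hierarchical family it is
itself Gaussian-drawn and can come out negative, which is meaningless for
a variance and an SD alike; negative draws are clamped to 0 (a point
mass), keeping the sampler total.  Consumers take |x| wherever a
non-negative magnitude is required.

## Bias-aware distribution fitting

Finite imaging volumes over-represent slow, poorly-directional cells: fast
persistent cells exit quickly, so track length correlates negatively with
median speed (and positively with median turn speed).  To fit a speed
distribution without this confound, candidate distributions are evaluated
through grouped synthetic datasets that reproduce the target's structure:

1. one group per target track, each initially holding max(track counts)
   draws (hetero family: from a bespoke per-group sub-distribution);
2. turn mode clamps draws at each track's measurable ceiling 180/(Δt/60);
3. observation counts are assigned to groups so the Spearman correlation
   between count and group median matches the target's within ±0.05.  The
   assignment mechanism is rank coupling: groups sorted by their full-
   sample median are paired with sorted counts (inverted for negative
   correlations), then a fraction of the assignment is randomly shuffled,
   with the fraction found by bisection.  This separates "which group gets
   which length" (drives the correlation) from "which observations are
   kept" (uniformly random, unbiased);
4. groups are truncated to their assigned counts.

Parameters are fitted by Powell search minimising the two-sample KS
distance between the target's pooled observations and the synthesized
pooled data.  The stochastic objective is tamed with common random
numbers: a fixed battery of three synthesis seeds per fit, averaged, so
Powell sees a deterministic surface; five independent fits use distinct
batteries.  Box bounds come from the data (means within [0, max], spreads
within (0, range]); starts are method-of-moments.  The heterogeneous
family additionally starts from its degenerate homogeneous limit, because
its pooled-KS landscape has a near-flat ridge between collapsed and
heterogeneous solutions; the better optimum wins.

Each fitted distribution is then used to synthesize 100 fresh datasets and
the KS distance between group medians and target track medians is
recorded: 5 fits × 100 datasets = 500 capture scores per family, whose
ECDFs are compared across families.

**Known limitation.**  When the generating process is itself Gaussian, the
pooled data of the heterogeneous family is exactly Gaussian (a Gaussian
mixture of Gaussians), and folding at zero adds only ~0.01 KS of shape
difference at leukocyte-plausible parameters — at the two-sample noise
floor.  Pooled fitting therefore cannot identify the between-/within-cell
variance split from Gaussian-shaped data: the fitted heterogeneity partly
reflects the moment-based start of the optimiser.  The framework reliably
*detects* heterogeneity when present (the heterogeneous family's capture
ECDF strongly dominates), but on truly homogeneous Gaussian data its
heterogeneous fits are not guaranteed to collapse, so the two families'
capture distributions can remain statistically distinguishable.  Real
speed data are strongly non-Gaussian, which is what makes the split
identifiable in practice.

## Random-walk models

Six models, in increasing parameter count (gene-vector arity in
parentheses):

| model | genes | translation | reorientation |
|---|---|---|---|
| Brownian (1) | σ | ζ = \|G(0, σ)\| | fresh uniform-sphere heading each step |
| Lévy walk (4) | α_T, β_T, α_D, β_D | run speed s ~ \|L(α_T, β_T)\| | straight runs of duration d ~ \|L(α_D, β_D)\|, uniform reorientation between runs |
| HomoCRW (4) | μ_P, σ_P, μ_T, σ_T | ζ = \|G(μ_T, σ_T)\| | turn ϕ ~ G(μ_P, σ_P); angle \|ϕ\|·Δt/60 about a random perpendicular axis |
| HeteroCRW (8) | hyper-params of both | per-cell bespoke Gaussians | per-cell bespoke Gaussians |
| IHomoCRW (5) | + β | ζ drawn first | ϕ scaled by (ζ_max^β − ζ^β)/ζ_max^β |
| IHeteroCRW (9) | + β | heterogeneous | heterogeneous + inverse coupling |

ζ_max is fixed at 25 µm/min (empirical in vivo maximum); ζ is clamped at
ζ_max inside the scale factor only, so the factor stays in [0, 1] while
the translation itself is never clamped.  Rotation axes are sampled
uniformly on the circle perpendicular to the current heading
(Gram–Schmidt on an isotropic Gaussian vector), making successive turn
planes uncorrelated.  Turn-speed draws may be negative; rotations use the
magnitude (the random axis already symmetrises direction).  The Lévy walk
keeps an internal run clock updated every 3 s regardless of the recording
interval; runs shorter than 3 s last one internal step.

## Arena simulation and the observation process

Cells are non-overlapping 5 µm-radius spheres (radius and count are not
biologically pinned; defaults 200 cells, configurable) walking through a
simulation domain consisting of the 412×412×100 µm tracked volume padded
by 50 µm on every face.  Domain walls reflect (normal heading component
negated).  Proposed moves are truncated at first sphere contact, resolved
sequentially in a per-step shuffled order with a KD-tree broad phase.
Positions are recorded every 30 s (T-cell schedule, 30 min sessions) or
45 s (neutrophil schedule, 50 min); only positions inside the tracked
volume are recorded.  A cell leaving the volume closes its track and
re-entry opens a new track id, as a real tracking pipeline would see it.
This observation process reproduces the in vivo bias signatures: for
heterogeneous-CRW ensembles, Spearman(observation count, median track
speed) < 0 and Spearman(observation count, median track turn speed) > 0.

## Calibration

A candidate solution is one model's gene vector.  Evaluation runs 10
replicate simulations (derived seeds), pools them, applies the 27 µm
filter and scores three objectives: KS distances between simulated and
target pooled translation speeds, pooled turn speeds and meandering
indices (an MSD variant replaces the third objective with |slope_sim −
slope_target|; the Λ score is refused in that mode because averaging a KS
distance with an unbounded slope difference is meaningless).  Candidates
whose simulated tracks all fall below the filter score worst-case
objectives.

Search is NSGA-II: fast non-dominated sorting, crowding-distance
truncation, binary tournament selection, blended crossover (BLX-α with
α = 0.1) and Gaussian mutation (per-gene rate 1/n_genes, SD 5% of the
gene's box width) within biologically scaled bounds (speed means
[0, 50] µm/min, SDs (0, 30]; turn means [0, 360] °/min, SDs (0, 180];
Lévy α (0.3, 2], β (0, 50]; inverse β (0.1, 10]).  Populations scale with
arity: 20 (Brownian), 50 (Lévy, HomoCRW), 60 (IHomoCRW), 80 (HeteroCRW),
100 (IHeteroCRW); up to 40 generations.

Over-fitting control: target tracks are split 70/30 (by track, seeded)
into training and validation sets.  Selection pressure uses training
scores only; training and validation Pareto fronts are maintained over
*all* evaluated candidates.  The over-fit metric is the fraction of
training-front members (by candidate identity, not parameter equality)
absent from the validation front; calibration stops early above 0.8.
Model assessment uses validation fronts.

## Model comparison

Per model, fronts from three independent calibrations are pooled and
re-filtered for dominance.  Three contrasts follow: (i) the pairwise
non-domination matrix (% of row model's front not dominated by any member
of the column model's front, with front sizes); (ii) the best (lowest) 30
Λ values per front, Λ(m) = α·mean(KS)² + Σ_o (KS_o − mean(KS))² with
α = 1 — low for solutions that do well, and equally well, on all
objectives (the centre of the front); pairwise KS tests between Λ
distributions, masking p > 0.01; (iii) per-objective KS-score
distributions with the same pairwise tests.  Duplicate objective vectors
are retained on fronts (front sizes are reported; deduplication would
distort them).  Λ values are only comparable for a common α, which is
stored alongside every Λ in serialised fronts.

## Synthetic reference data

No public deposits exist for the motivating datasets, so the fixture
module generates reference data by running the arena with a demo
IHeteroCRW generator, hand-tuned once so pooled speed medians land in the
leukocyte-plausible 5–15 µm/min range (turn hyper-parameters
150/90/60/20 °/min, translation 10/5/3/1 µm/min, β = 2) and frozen.
In-vivo-like presets use Δt = 35 s (T-cell-like, 751 tracks) and 45 s
(neutrophil-like, 1017 tracks).  These datasets reproduce the qualitative
bias signatures above and a step-level speed-vs-turn Spearman correlation
of ≈ −0.3, but they are demo values, not estimates of any real cell
population; passing tests on them demonstrates the pipeline's internal
consistency, not fidelity to any particular experiment.

## Evaluation-study problem sizes

The studies in `leukowalk.studies` (shared by the test suite and
`scripts/acceptance.py`) use deliberately scaled sizes chosen to give
clear signals at desk scale:

* bias-fit discrimination: 300 groups of 8–40 observations (pooled
  n ≈ 7000), count-vs-median correlation −0.35, generators
  G(μM=6, σM=4, μS=3, σS=1) and G(6, 5); 5 fits × 100 capture datasets
  per family;
* Brownian σ recovery: σ* = 12 target (150 cells × 10 replicates);
  NSGA-II population 20 for 15 generations, each evaluation 10 replicates
  of 50 cells;
* model selection: IHeteroCRW demo-generator target; Brownian
  (population 20) vs IHeteroCRW (population 40) for 8 generations, each
  evaluation 5 replicates of 50 cells.

## Numerical choices and degenerate inputs

Headings are renormalised after every rotation (unit norm preserved to
1e-9 over 10⁶ steps).  KS p-values use the asymptotic two-sample
distribution.  Spearman correlations use mid-ranks with tie correction;
constant inputs are an error, not 0.  Tracks with fewer than 2 points are
invalid; turn metrics need 3.  A zero-path track has no meandering index
and is excluded with a log count.  Equal objective vectors do not
dominate each other.  All randomness flows from named integer seeds
through `numpy` SeedSequence spawning, so every ensemble, fit and
calibration is exactly reproducible from its recorded seed.
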