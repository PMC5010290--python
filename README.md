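# leukowalk

**3D leukocyte random-walk simulation, bias-aware motility statistics and
multi-objective model selection.**

Intravital two-photon microscopy yields thousands of 3D cell tracks, but
deciding *which* motility model a population follows — Brownian motion, a
Lévy walk, or a correlated random walk (CRW), homogeneous or
heterogeneous, with or without coupling between speed and turning — is
confounded by the observation process itself: fast, directionally
persistent cells leave the finite imaging volume quickly, so slow
meandering cells are over-represented.  `leukowalk` is for immunologists
and modellers who want to (a) quantify cell motility from Imaris-style
track exports, (b) test whether apparent cell-to-cell heterogeneity is
real or a sampling artifact, and (c) select and parameterise a random-walk
model that reproduces their data.

## What it computes

**Motility profile.**  Per-step translational speeds ζ_i = |d_i|/(Δt/60)
(µm/min), turn speeds ϕ_i = ∠(d_i, d_{i+1})/(Δt/60) (°/min, ceiling
180/(Δt/60)), and per-track meandering indices (net displacement / path
length ∈ [0,1]), pooled over tracks after a 27 µm net-displacement filter;
plus MSD log-log slope and displacement-autocorrelation diagnostics.

**Bias-aware distribution fitting.**  A candidate speed distribution D is
fitted to pooled data by Powell search on the two-sample KS statistic,
where samples from D are synthesized into track-like groups reproducing
the target's per-track observation counts and the Spearman correlation
between count and median speed — i.e. the imaging bias.  Capture of the
per-track median distribution (5 fits × 100 synthetic datasets = 500 KS
scores per family) then reveals whether cells are genuinely heterogeneous.

**Six walker models in a simulated imaging volume.**  Brownian, Lévy walk,
and four CRWs (homogeneous/heterogeneous × with/without inverse
speed–turn coupling ϕ ← ϕ·(ζ_max^β − ζ^β)/ζ_max^β, ζ_max = 25 µm/min),
simulated as non-overlapping spheres in a domain around the
412×412×100 µm tracked volume, recorded on the in vivo schedule so that
simulated data carry the same observation bias as real data.

**NSGA-II calibration and Pareto model selection.**  Candidate parameter
vectors are scored by three KS objectives (translation, turn, meandering)
against a 70/30 train/validation split with an over-fitting stop at 0.8.
Models are compared by non-domination percentages between fronts, by the
best-30 Λ scores (Λ = α·mean(KS)² + Σ(KS_o − mean)², α = 1 — low for
balanced, centre-of-front solutions) and by per-objective KS
distributions.

## Worked example

```bash
python examples/01_profile_tracks.py
```

```
dataset: 600 tracks, 10916 spots, mean 18.2 observations/track
displacement filter (27 um): 328 tracks excluded
pooled translational speed median: 11.57 um/min
pooled turn speed median: 86.8 deg/min
meandering index median: 0.563
MSD log-log slope: 1.31  (1 = diffusive, 2 = ballistic)
Spearman(observations, median track speed) = -0.155  (negative: fast cells exit the volume early)
Spearman(observations, median track turn)  = +0.109  (positive: turning cells stay observed)
```

The dataset is synthetic (a heterogeneous inverse-coupled CRW walked
through the imaging volume — no public tracks exist for the motivating
experiments), and it reproduces the hallmarks of real data: a
superdiffusive MSD slope between 1 and 2, and the two bias correlations
whose signs show that fast, persistent cells are observed fewer times.

```bash
python examples/02_fit_distributions.py
```

```
target: 120 tracks, 2910 pooled observations, count-vs-median rho -0.35
homo_gaussian    params [5.92 4.62]  pooled KS 0.016  median-capture KS 0.304
hetero_gaussian  params [6.17 2.07 4.31 0.36]  pooled KS 0.024  median-capture KS 0.192
```

Both families fit the *pooled* speeds equally well (KS ≈ 0.02), but only
the heterogeneous family reproduces how medians vary *between* tracks
(capture KS 0.19 vs 0.30): the population really is heterogeneous, and
the bias correction ensures that conclusion is not an imaging artifact.

Other examples: `03_simulate_models.py` (contrasts Brownian and
IHeteroCRW ensembles and their speed–turn coupling) and
`04_calibrate_and_compare.py` (a small end-to-end NSGA-II calibration and
Pareto front comparison).  A thin CLI mirrors the pipeline:
`leukowalk synth | profile | fitdist | simulate | calibrate | compare`.

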