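"""Multi-objective calibration of walker models and Pareto model selection.

A candidate solution is a gene vector (one model's parameters).  Its
evaluation runs ten replicate arena simulations, pools them into a motility
profile (27 µm displacement filter applied, exactly as for target data) and
scores the KS distance to the target profile on three objectives: pooled
translational speeds, pooled turn speeds and meandering indices.  An MSD
variant replaces the third objective with the absolute difference of
log-log MSD regression slopes.

Calibration uses NSGA-II (non-dominated sorting, crowding-distance
truncation, binary tournament, blended crossover, Gaussian mutation) for up
to 40 generations.  Over-fitting is controlled by splitting target tracks
70/30 into training and validation sets: selection is driven by training
scores alone, two Pareto fronts are maintained over all evaluated
candidates, and calibration stops early when the fraction of training-front
members absent from the validation front exceeds 0.8.

Model comparison contrasts per-model fronts (merged over independent
calibration runs) through (i) pairwise non-domination percentages,
(ii) the best-30 Λ score distributions, and (iii) per-objective KS-score
distributions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .arena import ArenaConfig, NoTracksError, run_ensemble
from .stats import (
    ObjectiveVector,
    ParetoFront,
    ParetoMember,
    ks_two_sample,
    lambda_score,
    nondominated_proportion,
    pareto_filter,
)
from .tracks import (
    EmptyProfileError,
    MotilityProfile,
    Track,
    TrackDataset,
    build_motility_profile,
    msd_curve,
)
from .walkers import MODEL_ARITY, MODEL_GENES, WalkerParams

__all__ = [
    "CalibrationConfig",
    "CalibrationOutcome",
    "DEFAULT_POPULATION",
    "default_gene_bounds",
    "evaluate_candidate",
    "nsga2_calibrate",
    "overfit_metric",
    "merge_fronts",
    "compare_models",
]

#: Candidates per generation, scaled with model arity.
DEFAULT_POPULATION = {
    "brownian": 20,
    "levy": 50,
    "homoCRW": 50,
    "heteroCRW": 80,
    "ihomoCRW": 60,
    "iheteroCRW": 100,
}

#: Penalty for the unbounded MSD objective when a candidate yields no tracks.
MSD_PENALTY = 10.0

_TRANS_MEAN = (0.0, 50.0)   # µm/min
_TRANS_SD = (1e-3, 30.0)
_TURN_MEAN = (0.0, 360.0)   # °/min
_TURN_SD = (1e-3, 180.0)
_INV_BETA = (0.1, 10.0)


def default_gene_bounds(model: str) -> list[tuple[float, float]]:
    """Biologically scaled box constraints per gene."""
    if model == "brownian":
        return [_TRANS_SD]
    if model == "levy":
        return [(0.3, 2.0), (1e-3, 50.0), (0.3, 2.0), (1e-3, 50.0)]
    if model == "homoCRW":
        return [_TURN_MEAN, _TURN_SD, _TRANS_MEAN, _TRANS_SD]
    if model == "heteroCRW":
        return [_TURN_MEAN, _TURN_SD, _TURN_SD, _TURN_SD,
                _TRANS_MEAN, _TRANS_SD, _TRANS_SD, _TRANS_SD]
    if model == "ihomoCRW":
        return default_gene_bounds("homoCRW") + [_INV_BETA]
    if model == "iheteroCRW":
        return default_gene_bounds("heteroCRW") + [_INV_BETA]
    raise ValueError(f"unknown model {model!r}")


@dataclass(frozen=True)
class CalibrationConfig:
    model: str
    arena: ArenaConfig
    generations: int = 40
    population: int | None = None  # default: DEFAULT_POPULATION[model]
    replicates_per_eval: int = 10
    train_fraction: float = 0.7
    overfit_stop: float = 0.8
    gene_bounds: tuple | None = None
    objective_mode: str = "meandering"  # meandering | msd
    filter_um: float = 27.0
    blend_alpha: float = 0.1
    mutation_scale: float = 0.05  # SD as a fraction of each gene's box width
    seed: int = 0

    def __post_init__(self):
        if self.model not in MODEL_ARITY:
            raise ValueError(f"unknown model {self.model!r}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        pop = self.population if self.population is not None else DEFAULT_POPULATION[self.model]
        if pop < 4:
            raise ValueError("population must be >= 4")
        object.__setattr__(self, "population", pop)
        gb = self.gene_bounds if self.gene_bounds is not None else default_gene_bounds(self.model)
        gb = tuple((float(lo), float(hi)) for lo, hi in gb)
        if len(gb) != MODEL_ARITY[self.model] or any(lo >= hi for lo, hi in gb):
            raise ValueError("invalid gene bounds")
        object.__setattr__(self, "gene_bounds", gb)
        if self.objective_mode not in ("meandering", "msd"):
            raise ValueError("objective_mode must be 'meandering' or 'msd'")


@dataclass
class CalibrationOutcome:
    training_front: ParetoFront
    validation_front: ParetoFront
    overfit_trace: list
    terminated_early: bool
    config: CalibrationConfig
    n_evaluated: int


@dataclass
class _Target:
    profile: MotilityProfile
    msd_slope: float | None


def _prepare_target(ds_tracks: list[Track], cfg: CalibrationConfig, label: str) -> _Target:
    ds = TrackDataset(ds_tracks, label=label)
    profile = build_motility_profile(ds, cfg.filter_um)
    slope = None
    if cfg.objective_mode == "msd":
        slope = msd_curve(ds)[2]
    return _Target(profile=profile, msd_slope=slope)


def _objectives_vs_target(sim_profile, sim_slope, target: _Target, mode: str) -> ObjectiveVector:
    d_trans, _ = ks_two_sample(
        sim_profile.pooled_translational_speeds, target.profile.pooled_translational_speeds
    )
    d_turn, _ = ks_two_sample(
        sim_profile.pooled_turn_speeds, target.profile.pooled_turn_speeds
    )
    if mode == "meandering":
        d3, _ = ks_two_sample(
            sim_profile.meandering_indices, target.profile.meandering_indices
        )
        return ObjectiveVector((d_trans, d_turn, d3))
    return ObjectiveVector(
        (d_trans, d_turn, abs(sim_slope - target.msd_slope)), ks_based=False
    )


def _worst_case(mode: str) -> ObjectiveVector:
    if mode == "meandering":
        return ObjectiveVector((1.0, 1.0, 1.0))
    return ObjectiveVector((1.0, 1.0, MSD_PENALTY), ks_based=False)


def evaluate_candidate(
    params: WalkerParams,
    target_train: _Target,
    target_val: _Target,
    cfg: CalibrationConfig,
    seed,
) -> tuple[ObjectiveVector, ObjectiveVector]:
    """Score one candidate against training and validation targets.

    A candidate whose simulated tracks all fall below the displacement
    filter (e.g. near-zero motility) receives worst-case objectives.
    """
    try:
        sim = run_ensemble(params, cfg.arena, cfg.replicates_per_eval, seed)
        profile = build_motility_profile(sim, cfg.filter_um)
        if profile.pooled_turn_speeds.size == 0:
            raise EmptyProfileError("no turn observations")
        slope = msd_curve(sim)[2] if cfg.objective_mode == "msd" else None
    except (NoTracksError, EmptyProfileError, ValueError):
        return _worst_case(cfg.objective_mode), _worst_case(cfg.objective_mode)
    return (
        _objectives_vs_target(profile, slope, target_train, cfg.objective_mode),
        _objectives_vs_target(profile, slope, target_val, cfg.objective_mode),
    )


# ---------------------------------------------------------------------------
# NSGA-II machinery


def _fast_nondominated_sort(objs: np.ndarray) -> list[np.ndarray]:
    n = objs.shape[0]
    dominated_by = [[] for _ in range(n)]
    dom_count = np.zeros(n, dtype=int)
    for i in range(n):
        le = (objs[i] <= objs).all(axis=1)
        lt = (objs[i] < objs).any(axis=1)
        dominates_j = le & lt
        for j in np.nonzero(dominates_j)[0]:
            dominated_by[i].append(j)
        le_j = (objs <= objs[i]).all(axis=1)
        lt_j = (objs < objs[i]).any(axis=1)
        dom_count[i] = int((le_j & lt_j).sum())
    fronts = []
    current = np.nonzero(dom_count == 0)[0]
    while current.size:
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        current = np.array(sorted(set(nxt)), dtype=int)
    return fronts


def _crowding_distance(objs: np.ndarray) -> np.ndarray:
    n, m = objs.shape
    dist = np.zeros(n)
    for k in range(m):
        order = np.argsort(objs[:, k])
        span = objs[order[-1], k] - objs[order[0], k]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0 and n > 2:
            dist[order[1:-1]] += (objs[order[2:], k] - objs[order[:-2], k]) / span
    return dist


def _select_parents(rank, crowd, rng, k):
    """Binary tournament on (rank, crowding distance)."""
    n = len(rank)
    winners = []
    for _ in range(k):
        i, j = rng.integers(n, size=2)
        if (rank[i], -crowd[i]) <= (rank[j], -crowd[j]):
            winners.append(i)
        else:
            winners.append(j)
    return winners


def _blend_crossover(a, b, alpha, rng):
    """BLX-α: children uniform in the parent interval extended by α."""
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    span = hi - lo
    return rng.uniform(lo - alpha * span, hi + alpha * span)


def _mutate(theta, bounds, scale, rate, rng):
    widths = np.array([hi - lo for lo, hi in bounds])
    mask = rng.random(len(theta)) < rate
    theta = theta + mask * rng.normal(size=len(theta)) * scale * widths
    return np.clip(theta, [lo for lo, _ in bounds], [hi for _, hi in bounds])


def overfit_metric(training_front: ParetoFront, validation_front: ParetoFront) -> float:
    """Fraction of training-front solutions absent from the validation
    front (membership by candidate identity, not parameter equality)."""
    val_ids = {m.uid for m in validation_front}
    absent = sum(1 for m in training_front if m.uid not in val_ids)
    return absent / len(training_front)


def nsga2_calibrate(target_ds: TrackDataset, cfg: CalibrationConfig) -> CalibrationOutcome:
    """Calibrate cfg.model against a target track dataset.

    Maintains training and validation Pareto fronts over every evaluated
    candidate; selection pressure comes from training scores only.
    """
    if len(target_ds) < 10:
        raise ValueError("need >= 10 target tracks for a meaningful 70/30 split")
    ss = np.random.SeedSequence(cfg.seed)
    split_rng = np.random.default_rng(ss.spawn(1)[0])
    idx = split_rng.permutation(len(target_ds))
    n_train = int(round(cfg.train_fraction * len(target_ds)))
    train_tracks = [target_ds.tracks[i] for i in idx[:n_train]]
    val_tracks = [target_ds.tracks[i] for i in idx[n_train:]]
    t_train = _prepare_target(train_tracks, cfg, "train")
    t_val = _prepare_target(val_tracks, cfg, "validation")

    bounds = cfg.gene_bounds
    n_genes = len(bounds)
    mut_rate = 1.0 / n_genes
    ga_rng = np.random.default_rng(ss.spawn(1)[0])
    eval_seeds = ss.spawn(1)[0]
    uid_counter = itertools.count()

    archive_train: list[ParetoMember] = []
    archive_val: list[ParetoMember] = []
    n_evaluated = 0

    def evaluate(theta: np.ndarray):
        nonlocal n_evaluated
        params = WalkerParams(cfg.model, tuple(theta))
        seed = eval_seeds.spawn(1)[0]
        obj_tr, obj_va = evaluate_candidate(params, t_train, t_val, cfg, seed)
        uid = next(uid_counter)
        archive_train.append(ParetoMember(params, obj_tr, origin="training", uid=uid))
        archive_val.append(ParetoMember(params, obj_va, origin="validation", uid=uid))
        n_evaluated += 1
        return obj_tr

    pop_theta = [
        np.array([ga_rng.uniform(lo, hi) for lo, hi in bounds])
        for _ in range(cfg.population)
    ]
    pop_obj = [evaluate(th) for th in pop_theta]

    overfit_trace = []
    terminated = False
    for _gen in range(cfg.generations):
        objs = np.array([o.values for o in pop_obj])
        fronts = _fast_nondominated_sort(objs)
        rank = np.empty(len(pop_obj), dtype=int)
        for r, f in enumerate(fronts):
            rank[f] = r
        crowd = np.zeros(len(pop_obj))
        for f in fronts:
            crowd[f] = _crowding_distance(objs[f])

        # offspring
        parents = _select_parents(rank, crowd, ga_rng, 2 * cfg.population)
        off_theta = []
        for i in range(0, len(parents), 2):
            child = _blend_crossover(
                pop_theta[parents[i]], pop_theta[parents[i + 1]], cfg.blend_alpha, ga_rng
            )
            child = _mutate(child, bounds, cfg.mutation_scale, mut_rate, ga_rng)
            off_theta.append(np.clip(child, [b[0] for b in bounds], [b[1] for b in bounds]))
        off_obj = [evaluate(th) for th in off_theta]

        # elitist environmental selection on the combined pool
        all_theta = pop_theta + off_theta
        all_obj = pop_obj + off_obj
        objs = np.array([o.values for o in all_obj])
        fronts = _fast_nondominated_sort(objs)
        chosen: list[int] = []
        for f in fronts:
            if len(chosen) + len(f) <= cfg.population:
                chosen.extend(f.tolist())
            else:
                cd = _crowding_distance(objs[f])
                order = f[np.argsort(-cd)]
                chosen.extend(order[: cfg.population - len(chosen)].tolist())
                break
        pop_theta = [all_theta[i] for i in chosen]
        pop_obj = [all_obj[i] for i in chosen]

        tf = pareto_filter(archive_train)
        vf = pareto_filter(archive_val)
        ov = overfit_metric(tf, vf)
        overfit_trace.append(ov)
        if ov > cfg.overfit_stop:
            terminated = True
            break

    return CalibrationOutcome(
        training_front=pareto_filter(archive_train),
        validation_front=pareto_filter(archive_val),
        overfit_trace=overfit_trace,
        terminated_early=terminated,
        config=cfg,
        n_evaluated=n_evaluated,
    )


# ---------------------------------------------------------------------------
# Model comparison


def merge_fronts(fronts: list[ParetoFront]) -> ParetoFront:
    """Pool independent calibrations' fronts and re-filter for dominance."""
    members = [m for f in fronts for m in f]
    return pareto_filter(members)


def compare_models(
    fronts: dict[str, ParetoFront],
    alpha: float = 1.0,
    best_n: int = 30,
    p_mask: float = 0.01,
) -> dict:
    """Three complementary contrasts of per-model Pareto fronts.

    Returns a report dict with: ``nondomination`` (percentage matrix,
    rows = % of row model's front non-dominated by the column model's,
    with front sizes), ``lambda_best`` (each model's best-``best_n`` Λ
    values) with ``lambda_ks`` pairwise KS tables (entries carry D, p and a
    masked flag for p > ``p_mask``), and ``objective_ks`` pairwise tables
    per objective.  Refuses MSD-mode fronts: Λ mixes scales there.
    """
    if len(fronts) < 2:
        raise ValueError("need at least two fronts to compare")
    for name, f in fronts.items():
        if not all(m.objectives.ks_based for m in f):
            raise ValueError(f"front {name!r} holds MSD-mode objectives; Λ is undefined")
    names = list(fronts)
    matrix = {
        a: {
            b: (None if a == b else nondominated_proportion(fronts[a], fronts[b]))
            for b in names
        }
        for a in names
    }
    sizes = {a: len(fronts[a]) for a in names}

    lam = {
        a: np.sort([lambda_score(m, alpha) for m in fronts[a]])[:best_n] for a in names
    }
    lambda_ks, objective_ks = {}, {o: {} for o in range(3)}
    for a, b in itertools.combinations(names, 2):
        d, p = ks_two_sample(lam[a], lam[b])
        lambda_ks[(a, b)] = {"D": d, "p": p, "masked": p > p_mask}
        oa, ob = fronts[a].objective_array(), fronts[b].objective_array()
        for o in range(3):
            d, p = ks_two_sample(oa[:, o], ob[:, o])
            objective_ks[o][(a, b)] = {"D": d, "p": p, "masked": p > p_mask}

    return {
        "models": names,
        "front_sizes": sizes,
        "nondomination": matrix,
        "lambda_alpha": alpha,
        "lambda_best": lam,
        "lambda_ks": lambda_ks,
        "objective_ks": objective_ks,
    }
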