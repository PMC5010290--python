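"""NSGA-II calibration machinery and model comparison."""

import numpy as np
import pytest

from leukowalk.arena import ArenaConfig, run_ensemble
from leukowalk.calibration import (
    CalibrationConfig,
    _crowding_distance,
    _fast_nondominated_sort,
    _prepare_target,
    compare_models,
    evaluate_candidate,
    merge_fronts,
    nsga2_calibrate,
    overfit_metric,
)
from leukowalk.stats import (
    ObjectiveVector,
    ParetoFront,
    ParetoMember,
    dominates,
    pareto_filter,
)
from leukowalk.walkers import WalkerParams


def mk(vals, uid):
    return ParetoMember(None, ObjectiveVector(tuple(vals)), uid=uid)


def tiny_cfg(model="brownian", **kw):
    """A deliberately small arena/GA for machinery tests; the arena mirrors
    the target's recording schedule (meandering depends on it)."""
    arena = ArenaConfig(record_interval=30.0, duration=900.0, n_cells=15)
    defaults = dict(
        model=model, arena=arena, generations=2, population=6,
        replicates_per_eval=2, seed=5,
    )
    defaults.update(kw)
    return CalibrationConfig(**defaults)


@pytest.fixture(scope="module")
def small_target():
    cfg = ArenaConfig(record_interval=30.0, duration=900.0, n_cells=60)
    return run_ensemble(WalkerParams("brownian", (8.0,)), cfg, 4, seed=77)


class TestOverfitMetric:
    def test_subset_is_zero(self):
        tf = ParetoFront([mk((0.1, 0.2, 0.3), 1), mk((0.3, 0.2, 0.1), 2)])
        vf = ParetoFront([mk((0.1, 0.2, 0.3), 1), mk((0.3, 0.2, 0.1), 2),
                          mk((0.2, 0.1, 0.3), 3)])
        assert overfit_metric(tf, vf) == 0.0

    def test_disjoint_is_one(self):
        tf = ParetoFront([mk((0.1, 0.2, 0.3), 1)])
        vf = ParetoFront([mk((0.1, 0.2, 0.3), 9)])
        assert overfit_metric(tf, vf) == 1.0

    def test_half_shared(self):
        tf = ParetoFront([mk((0.1, 0.2, 0.3), 1), mk((0.3, 0.2, 0.1), 2)])
        vf = ParetoFront([mk((0.1, 0.2, 0.3), 1), mk((0.3, 0.2, 0.15), 5)])
        assert overfit_metric(tf, vf) == 0.5


class TestNsgaInternals:
    def test_nondominated_sort_ranks(self):
        objs = np.array([
            [0.1, 0.1, 0.1],   # rank 0
            [0.2, 0.2, 0.2],   # rank 1 (dominated by 0)
            [0.05, 0.3, 0.3],  # rank 0 (trade-off)
            [0.3, 0.3, 0.3],   # rank 2
        ])
        fronts = _fast_nondominated_sort(objs)
        assert sorted(fronts[0].tolist()) == [0, 2]
        assert fronts[1].tolist() == [1]
        assert fronts[2].tolist() == [3]

    def test_crowding_extremes_infinite(self):
        objs = np.array([[0.1, 0.5, 0.3], [0.2, 0.4, 0.3], [0.3, 0.3, 0.3]])
        cd = _crowding_distance(objs)
        assert np.isinf(cd[0]) and np.isinf(cd[2])
        assert np.isfinite(cd[1])


class TestEvaluateCandidate:
    def test_zero_motility_candidate_worst_case(self, small_target):
        cfg = tiny_cfg()
        t = _prepare_target(list(small_target.tracks), cfg, "t")
        tr, va = evaluate_candidate(
            WalkerParams("brownian", (0.001,)), t, t, cfg,
            np.random.SeedSequence(1),
        )
        assert tr.values == (1.0, 1.0, 1.0)

    def test_deterministic_under_common_seed(self, small_target):
        cfg = tiny_cfg()
        t = _prepare_target(list(small_target.tracks), cfg, "t")
        p = WalkerParams("brownian", (8.0,))
        a = evaluate_candidate(p, t, t, cfg, np.random.SeedSequence(3))
        b = evaluate_candidate(p, t, t, cfg, np.random.SeedSequence(3))
        assert a[0].values == b[0].values and a[1].values == b[1].values

    def test_self_match_scores_low(self):
        """Simulating with the target's own generator parameters scores at
        the two-sample KS noise floor on all three objectives."""
        sigma = 12.0
        target_ds = run_ensemble(
            WalkerParams("brownian", (sigma,)),
            ArenaConfig(record_interval=30.0, duration=900.0, n_cells=150),
            6, seed=77,
        )
        cfg = tiny_cfg(replicates_per_eval=6,
                       arena=ArenaConfig(record_interval=30.0, duration=900.0, n_cells=100))
        t = _prepare_target(list(target_ds.tracks), cfg, "t")
        tr, _ = evaluate_candidate(
            WalkerParams("brownian", (sigma,)), t, t, cfg, np.random.SeedSequence(4)
        )
        assert tr.values[0] < 0.1 and tr.values[1] < 0.1
        # the meandering pool is much smaller (displacement-filtered tracks),
        # so bound it by the 99.9% two-sample KS critical value at its size
        n1 = t.profile.meandering_indices.size
        crit = 1.95 * np.sqrt(2 / n1)
        assert tr.values[2] < crit


class TestCalibrate:
    def test_needs_enough_tracks(self):
        from leukowalk.tracks import Track, TrackDataset

        rng = np.random.default_rng(0)
        ds = TrackDataset(
            [Track(f"t{i}", np.cumsum(rng.normal(0, 3, (5, 3)), axis=0), 30.0)
             for i in range(5)]
        )
        with pytest.raises(ValueError):
            nsga2_calibrate(ds, tiny_cfg())

    def test_zero_generations_fronts_from_initial_population(self, small_target):
        cfg = tiny_cfg(generations=0)
        out = nsga2_calibrate(small_target, cfg)
        assert out.n_evaluated == cfg.population
        assert len(out.training_front) >= 1
        # fronts are the non-dominated subset of everything evaluated
        refiltered = pareto_filter(list(out.training_front))
        assert {m.uid for m in refiltered} == {m.uid for m in out.training_front}

    def test_same_seed_identical_outcome(self, small_target):
        cfg = tiny_cfg(generations=1)
        a = nsga2_calibrate(small_target, cfg)
        b = nsga2_calibrate(small_target, cfg)
        assert [m.uid for m in a.training_front] == [m.uid for m in b.training_front]
        for ma, mb in zip(a.training_front, b.training_front):
            assert ma.objectives.values == mb.objectives.values
        assert a.overfit_trace == b.overfit_trace

    def test_fronts_internally_nondominated(self, small_target):
        out = nsga2_calibrate(small_target, tiny_cfg(generations=1))
        for front in (out.training_front, out.validation_front):
            for m in front:
                assert not any(
                    dominates(o.objectives, m.objectives) for o in front if o is not m
                )


class TestMsdObjectiveMode:
    def test_third_objective_is_slope_difference(self, small_target):
        cfg = tiny_cfg(objective_mode="msd", replicates_per_eval=4)
        t = _prepare_target(list(small_target.tracks), cfg, "t")
        assert t.msd_slope is not None
        tr, _ = evaluate_candidate(
            WalkerParams("brownian", (8.0,)), t, t, cfg, np.random.SeedSequence(6)
        )
        assert not tr.ks_based
        assert tr.values[2] >= 0  # |slope_sim - slope_target|, unbounded

    def test_worst_case_uses_finite_slope_penalty(self, small_target):
        cfg = tiny_cfg(objective_mode="msd")
        t = _prepare_target(list(small_target.tracks), cfg, "t")
        tr, _ = evaluate_candidate(
            WalkerParams("brownian", (0.001,)), t, t, cfg, np.random.SeedSequence(7)
        )
        assert tr.values[:2] == (1.0, 1.0)
        assert np.isfinite(tr.values[2]) and tr.values[2] > 1


class TestCompareModels:
    def test_identical_fronts_all_100_and_masked(self):
        rng = np.random.default_rng(1)
        members = [mk(rng.uniform(0, 1, 3), uid=i) for i in range(30)]
        f = pareto_filter(members)
        rep = compare_models({"A": f, "B": ParetoFront(list(f))})
        assert rep["nondomination"]["A"]["B"] == 100.0
        assert rep["nondomination"]["B"]["A"] == 100.0
        assert rep["lambda_ks"][("A", "B")]["masked"]

    def test_elementwise_superior_front(self):
        good = ParetoFront([mk((0.05, 0.05, 0.05), 0)])
        bad = ParetoFront([mk((0.5, 0.5, 0.5), 1)])
        rep = compare_models({"good": good, "bad": bad})
        assert rep["nondomination"]["good"]["bad"] == 100.0
        assert rep["nondomination"]["bad"]["good"] == 0.0

    def test_three_model_matrix_matches_oracle(self):
        rng = np.random.default_rng(2)
        fronts = {
            name: pareto_filter([mk(rng.uniform(0, 1, 3), uid=i) for i in range(12)])
            for name in ("A", "B", "C")
        }
        rep = compare_models(fronts)
        for a in fronts:
            for b in fronts:
                if a == b:
                    continue
                count = sum(
                    1 for m in fronts[a]
                    if not any(dominates(o.objectives, m.objectives) for o in fronts[b])
                )
                assert rep["nondomination"][a][b] == pytest.approx(
                    100 * count / len(fronts[a])
                )

    def test_msd_mode_front_refused(self):
        f1 = ParetoFront([ParetoMember(None, ObjectiveVector((0.1, 0.1, 2.0), ks_based=False), uid=0)])
        f2 = ParetoFront([mk((0.1, 0.1, 0.1), 1)])
        with pytest.raises(ValueError):
            compare_models({"a": f1, "b": f2})

    def test_merge_refilters_dominance(self):
        f1 = ParetoFront([mk((0.1, 0.3, 0.3), 0)])
        f2 = ParetoFront([mk((0.05, 0.2, 0.2), 1)])  # dominates f1's member
        merged = merge_fronts([f1, f2])
        assert [m.uid for m in merged] == [1]
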