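import numpy as np
import pytest

from netmoa.analysis import (
    FSignalDistribution,
    compare_scenarios,
    ensemble_activity,
    fsignal,
    fsignal_distribution,
    heatmap_matrix,
)
from netmoa.characterization import EffectorSet, Stimulus


EFFS = EffectorSet(process="p", members={"A": 1, "B": 1, "C": -1})


class TestFsignal:
    def test_complete_reversal(self):
        effs = EffectorSet(process="p", members={"A": 1, "B": 1})
        assert fsignal({"A": -1.0, "B": -1.0}, effs) == -1.0

    def test_symmetry_cancels(self):
        effs = EffectorSet(process="p", members={"A": 1, "B": -1})
        assert fsignal({"A": 0.5, "B": 0.5}, effs) == 0.0

    def test_direct_evaluation(self):
        assert fsignal({"A": -0.8, "B": -0.6, "C": 0.4}, EFFS) == pytest.approx(-0.6)

    def test_missing_effector_errors(self):
        with pytest.raises(KeyError):
            fsignal({"A": 0.1}, EFFS)

    def test_attains_bounds(self):
        rng = np.random.default_rng(0)
        members = {f"P{i}": int(s) for i, s in enumerate(rng.choice([-1, 1], 10))}
        effs = EffectorSet(process="p", members=members)
        assert fsignal({p: float(w) for p, w in members.items()}, effs) == 1.0
        assert fsignal({p: float(-w) for p, w in members.items()}, effs) == -1.0

    def test_linearity_mean_of_fsignal_equals_fsignal_of_mean(self):
        rng = np.random.default_rng(1)
        profiles = [
            {p: float(rng.uniform(-1, 1)) for p in EFFS.members} for _ in range(7)
        ]
        per_solution = np.mean([fsignal(pr, EFFS) for pr in profiles])
        mean_profile = {
            p: float(np.mean([pr[p] for pr in profiles])) for p in EFFS.members
        }
        assert per_solution == pytest.approx(fsignal(mean_profile, EFFS), abs=1e-12)


class TestEnsembleActivity:
    def test_mean_and_clamp_invariant(self, small_world, small_ensemble):
        stim = next(iter(small_world.drug_targets.values()))
        ea = ensemble_activity(small_ensemble, small_world.interactome, stim)
        # clamped nodes equal their clamp in every solution and in the mean
        for protein, value in stim.clamps.items():
            assert ea.mean_profile[protein] == float(value)
            for prof in ea.profiles:
                assert prof[protein] == float(value)
        # mean is the arithmetic mean of per-solution profiles
        some = sorted(small_world.interactome.nodes)[:10]
        for p in some:
            assert ea.mean_profile[p] == pytest.approx(
                np.mean([prof[p] for prof in ea.profiles])
            )

    def test_identical_solutions_mean_is_single(self, small_world, small_ensemble):
        from netmoa.training import Ensemble

        stim = next(iter(small_world.drug_targets.values()))
        one = small_ensemble.solutions[0]
        clones = Ensemble(solutions=[one, one, one])
        ea = ensemble_activity(clones, small_world.interactome, stim)
        single = ensemble_activity(
            Ensemble(solutions=[one]), small_world.interactome, stim
        )
        for p in small_world.interactome.nodes:
            assert ea.mean_profile[p] == pytest.approx(single.mean_profile[p])


def _dist(process, scenario, values):
    return FSignalDistribution(process=process, scenario=scenario, values=np.array(values))


class TestCompareScenarios:
    def test_identical_distribution_unflagged(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(-0.5, 0.5, 30)
        dists = {
            ("p", "ref"): _dist("p", "ref", vals),
            ("p", "x"): _dist("p", "x", vals.copy()),
        }
        res = compare_scenarios(dists, "ref")[0]
        assert res.p_value > 0.9
        assert res.flag == ""

    def test_fully_separated_u_statistic(self):
        n = 50
        a = np.linspace(0.5, 0.9, n)
        b = np.linspace(-0.9, -0.5, n)
        dists = {
            ("p", "ref"): _dist("p", "ref", b),
            ("p", "x"): _dist("p", "x", a),
        }
        res = compare_scenarios(dists, "ref")[0]
        # complete separation: U is n^2 (or 0 from the other side)
        assert res.u_statistic in (0.0, float(n * n))
        assert res.p_value < 1e-10
        assert res.flag == "**"  # q < 0.005, mean difference >> 0.1

    def test_flag_rules(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 0.01, 100).clip(-1, 1)
        dists = {
            ("p", "ref"): _dist("p", "ref", base),
            ("p", "small"): _dist("p", "small", (base + 0.05).clip(-1, 1)),
            ("p", "big"): _dist("p", "big", (base + 0.5).clip(-1, 1)),
        }
        res = {r.scenario: r for r in compare_scenarios(dists, "ref")}
        assert res["small"].flag == "*"  # significant but < 0.1 difference
        assert res["big"].flag == "**"

    def test_too_small_ensemble(self):
        dists = {
            ("p", "ref"): _dist("p", "ref", [0.1]),
            ("p", "x"): _dist("p", "x", [0.2]),
        }
        with pytest.raises(ValueError):
            compare_scenarios(dists, "ref")

    def test_missing_reference(self):
        with pytest.raises(KeyError):
            compare_scenarios({("p", "x"): _dist("p", "x", [0.1, 0.2])}, "ref")


class TestHeatmapMatrix:
    SETS = [EffectorSet(process="p", members={"A": 1, "B": 1, "C": -1, "D": 1})]

    def test_row_filter_and_boundary(self):
        profiles = {
            "s1": {"A": 0.05, "B": -0.1, "C": 0.5, "D": 0.0},
            "s2": {"A": -0.08, "B": 0.0, "C": 0.6, "D": 0.09},
            "s3": {"A": 0.02, "B": 0.05, "C": 0.7, "D": 0.0},
            "s4": {"A": 0.0, "B": 0.0, "C": 0.0, "D": 0.0},
        }
        hm = heatmap_matrix(profiles, self.SETS, threshold=0.1)
        kept = {p for _, p in hm.matrix.index}
        assert kept == {"B", "C"}  # A always < 0.1; B hits -0.1 boundary; D below

    def test_duplicate_rows_adjacent_in_order(self):
        sets = [
            EffectorSet(
                process="p",
                members={"A": 1, "B": 1, "C": 1, "D": 1, "E": 1},
            )
        ]
        profiles = {
            "s1": {"A": 0.9, "B": -0.9, "C": 0.9, "D": 0.2, "E": -0.88},
            "s2": {"A": 0.8, "B": -0.8, "C": 0.8, "D": 0.1, "E": -0.79},
        }
        hm = heatmap_matrix(profiles, sets, threshold=0.1)
        order = [hm.matrix.index[i][1] for i in hm.row_order]
        # identical rows A and C must be neighbors after clustering
        assert abs(order.index("A") - order.index("C")) == 1

    def test_empty_matrix_warns(self):
        profiles = {"s1": {"A": 0.01, "B": 0.02, "C": 0.0, "D": 0.03}}
        with pytest.warns(UserWarning):
            hm = heatmap_matrix(profiles, self.SETS, threshold=0.1)
        assert hm.matrix.empty and hm.row_order == []

    def test_fsignal_distribution_roundtrip(self, small_world, small_ensemble):
        stim = next(iter(small_world.drug_targets.values()))
        ea = ensemble_activity(small_ensemble, small_world.interactome, stim)
        effs = small_world.effector_sets[0]
        dist = fsignal_distribution(ea.profiles, effs, scenario=stim.name)
        assert len(dist.values) == small_ensemble.size
        # linearity identity between the two averaging routes
        assert dist.mean == pytest.approx(fsignal(ea.mean_profile, effs), abs=1e-12)
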