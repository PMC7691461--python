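import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aspenscan.demography import DemographicModel, SampleConfig
from aspenscan.coalescent_sim import branch_sfs_tensor, simulate_sfs_counts
from aspenscan.genotype_io import PopulationMap, PolarizedSites
from aspenscan.sfs import JointSFS
from aspenscan.sfs_demography import (
    composite_loglik,
    fit_parameters,
    generations_from_years,
    model_selection_table,
    observed_joint_sfs,
    parametric_bootstrap,
    profile_parameter,
    years_from_generations,
    FitResult,
)
from conftest import make_gm


def sfs1d(values, kind="counts", folded=False):
    v = np.asarray(values, dtype=float)
    return JointSFS(("A",), (len(v) - 1,), v, kind=kind, folded=folded)


class TestCompositeLoglik:
    def test_hand_computed_value(self):
        obs = sfs1d([0, 6, 3, 2, 0])
        exp = sfs1d([0, 6 / 11, 3 / 11, 2 / 11, 0], kind="proportions")
        ll = composite_loglik(obs, exp)
        hand = 6 * np.log(6 / 11) + 3 * np.log(3 / 11) + 2 * np.log(2 / 11)
        assert ll == pytest.approx(hand, abs=1e-9)
        assert hand == pytest.approx(-10.944, abs=1e-3)

    def test_observed_proportions_maximize(self):
        # brute-force grid over 3-class proportion vectors
        obs = sfs1d([0, 10, 5, 3, 0])
        n = obs.data[1:4]
        best_p = n / n.sum()
        ll_best = composite_loglik(obs, sfs1d([0, *best_p, 0], kind="proportions"))
        grid = np.linspace(0.02, 0.96, 25)
        for p1 in grid:
            for p2 in grid:
                p3 = 1 - p1 - p2
                if p3 <= 0.01:
                    continue
                ll = composite_loglik(obs, sfs1d([0, p1, p2, p3, 0], kind="proportions"))
                assert ll <= ll_best + 1e-9

    def test_zero_count_class_contributes_nothing(self):
        obs = sfs1d([0, 5, 0, 0, 0])
        exp = sfs1d([0, 1.0 - 2e-12, 1e-12, 1e-12, 0], kind="proportions")
        assert composite_loglik(obs, exp) == pytest.approx(5 * np.log(1 - 2e-12))

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError):
            composite_loglik(sfs1d([0, 1, 0]), sfs1d([0, 0.5, 0.5, 0], kind="proportions"))


class TestJointSFSContainer:
    def test_fold_maps_complement_classes(self):
        data = np.zeros((5, 5))
        data[3, 4] = 1.0
        sfs = JointSFS(("A", "B"), (4, 4), data)
        folded = sfs.fold()
        assert folded.data[1, 0] == 1.0
        assert folded.data.sum() == pytest.approx(1.0)

    @given(st.integers(0, 4), st.integers(0, 4))
    @settings(deadline=None, max_examples=25)
    def test_fold_enumeration_oracle(self, i, j):
        # every unfolded cell lands on min(cell, complement) lexicographically
        data = np.zeros((5, 5))
        data[i, j] = 1.0
        folded = JointSFS(("A", "B"), (4, 4), data).fold()
        target = min((i, j), (4 - i, 4 - j))
        assert folded.data[target] == pytest.approx(1.0)

    def test_save_load_roundtrip(self, tmp_path):
        data = np.arange(25, dtype=float).reshape(5, 5)
        sfs = JointSFS(("N", "S"), (4, 4), data)
        sfs.save(tmp_path / "s.txt")
        back = JointSFS.load(tmp_path / "s.txt")
        assert back.pops == ("N", "S") and back.n_hap == (4, 4)
        np.testing.assert_array_equal(back.data, data)

    def test_marginal_axis_order(self):
        data = np.zeros((3, 4, 5))
        data[1, 2, 3] = 2.0
        sfs = JointSFS(("N", "C", "S"), (2, 3, 4), data)
        m = sfs.marginal(("S", "N"))
        assert m.pops == ("S", "N")
        assert m.data[3, 1] == 2.0


class TestObservedSFS:
    def test_single_site_entry(self):
        gm = make_gm([[1], [1], [0], [0]])  # pop A derived 2/4, pop B 0/4
        pm = PopulationMap({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        pol = PolarizedSites(
            ancestral_is_ref=np.array([True]), polarizable=np.array([True])
        )
        sfs = observed_joint_sfs(gm, pm, ("A", "B"), pol=pol)
        assert sfs.data[2, 0] == 1.0
        assert sfs.n_sites == 1

    def test_alt_ancestral_flips_derived_count(self):
        gm = make_gm([[1], [1], [2], [2]])
        pm = PopulationMap({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        pol = PolarizedSites(np.array([False]), np.array([True]))
        sfs = observed_joint_sfs(gm, pm, ("A", "B"), pol=pol)
        assert sfs.data[2, 0] == 1.0  # derived = REF now

    def test_missing_population_errors(self):
        gm = make_gm([[1]])
        pm = PopulationMap({"s0": "A"})
        with pytest.raises(ValueError):
            observed_joint_sfs(gm, pm, ("A", "B"), fold=True)

    def test_projection_weights_sum_to_one_site(self):
        # one missing call: hypergeometric projection spreads one unit of mass
        gm = make_gm([[1, 1], [-1, 1], [0, 0], [0, 0]])
        pm = PopulationMap({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        sfs = observed_joint_sfs(gm, pm, ("A", "B"), fold=False,
                                 pol=PolarizedSites(np.array([True, True]),
                                                    np.array([True, True])),
                                 project_to={"A": 2, "B": 4})
        assert sfs.data.sum() == pytest.approx(2.0)

    def test_matches_simulator_expectation(self, two_pop_model):
        cfg = SampleConfig({"A": 4, "B": 4})
        counts = simulate_sfs_counts(two_pop_model, cfg, 5_000, 10_000, seed=3)
        from aspenscan.coalescent_sim import expected_joint_sfs

        exp = expected_joint_sfs(two_pop_model, cfg, 100_000, 4)
        tv = 0.5 * np.abs(counts.normalized().data - exp.data).sum()
        assert tv < 0.02


class TestModelSelection:
    def test_equal_aic_equal_weights(self):
        fits = [
            FitResult("m1", {}, -100.0, 5, True),
            FitResult("m2", {}, -102.0, 3, True),
        ]
        tab = model_selection_table(fits)
        assert tab["AIC"].tolist() == [210.0, 210.0]
        np.testing.assert_allclose(tab["weight"], [0.5, 0.5])

    def test_distant_model_changes_little(self):
        base = [FitResult("a", {}, -100.0, 2, True), FitResult("b", {}, -101.0, 2, True)]
        t1 = model_selection_table(base)
        t2 = model_selection_table(base + [FitResult("c", {}, -110.0, 2, True)])
        w1 = t1.set_index("model")["weight"]
        w2 = t2.set_index("model")["weight"]
        assert abs(w1["a"] / w1["b"] - w2["a"] / w2["b"]) < 1e-9
        assert abs(w1["a"] - w2["a"]) < np.exp(-8)

    def test_weights_sum_to_one_and_shift_invariant(self):
        rng = np.random.default_rng(0)
        lls = rng.uniform(-500, -400, 6)
        f = [FitResult(f"m{i}", {}, ll, 3, True) for i, ll in enumerate(lls)]
        g = [FitResult(f"m{i}", {}, ll + 123.4, 3, True) for i, ll in enumerate(lls)]
        tf = model_selection_table(f).set_index("model")
        tg = model_selection_table(g).set_index("model")
        assert tf["weight"].sum() == pytest.approx(1.0)
        np.testing.assert_allclose(tf["weight"], tg["weight"])
        assert tf["dAIC"].min() == 0.0


class TestYears:
    def test_paper_scale_conversion(self):
        assert years_from_generations(52_836.53, 15) == pytest.approx(792_548, abs=1)
        assert generations_from_years(78_933, 15) == pytest.approx(5_262.2, abs=0.1)

    def test_zero_and_inverse(self):
        assert years_from_generations(0.0) == 0.0
        assert generations_from_years(years_from_generations(123.4)) == pytest.approx(123.4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            years_from_generations(-1.0)


class TestFitting:
    def test_single_ne_recovery(self, two_pop_model):
        # Ne of one deme is identified by the joint spectrum's shape (the
        # within-deme coalescence rate relative to split depth and migration)
        cfg = SampleConfig({"A": 4, "B": 4})
        obs = simulate_sfs_counts(two_pop_model, cfg, 2_000, 10_000, seed=51)
        res = profile_parameter(
            obs, two_pop_model, cfg, "Ne:B", (125.0, 2_000.0),
            n_grid=11, n_reps_per_eval=20_000, seed=52,
        )
        assert res.converged
        assert abs(res.params["Ne:B"] / 500.0 - 1) < 0.10

    def test_split_time_recovery_no_migration(self):
        m = DemographicModel(
            populations=["A", "B"], Ne={"A": 1000.0, "B": 1000.0},
            splits=[(3_000.0, "B", "A")],
        )
        cfg = SampleConfig({"A": 4, "B": 4})
        obs = simulate_sfs_counts(m, cfg, 2_000, 10_000, seed=61)
        res = profile_parameter(
            obs, m, cfg, "Tsplit:B", (1_000.0, 9_000.0),
            n_grid=11, n_reps_per_eval=20_000, seed=62,
        )
        assert abs(res.params["Tsplit:B"] / 3_000.0 - 1) < 0.10

    def test_generating_topology_beats_wrong_topology(self, three_pop_model):
        cfg = SampleConfig({"N": 4, "C": 4, "S": 4})
        obs = simulate_sfs_counts(three_pop_model, cfg, 2_000, 10_000, seed=71)
        wrong = three_pop_model.copy()
        # swap the split order: (N,C) deep and (N,S) shallow
        wrong.splits = [(2000.0, "S", "N"), (12000.0, "N", "C"), (400000.0, "OUT", "C")]
        wrong.size_changes = {"C": [(12000.0, 20000.0)]}
        ll_true = composite_pair_ll(obs, three_pop_model, cfg, seed=72)
        ll_wrong = composite_pair_ll(obs, wrong, cfg, seed=72)
        assert ll_true >= ll_wrong

    def test_coordinate_search_improves(self, two_pop_model):
        cfg = SampleConfig({"A": 4, "B": 4})
        obs = simulate_sfs_counts(two_pop_model, cfg, 1_000, 10_000, seed=81)
        start = two_pop_model.with_param("Ne:B", 150.0)
        res = fit_parameters(
            obs, start, cfg, {"Ne:B": (100.0, 5_000.0)},
            n_reps_per_eval=5_000, optimizer="coordinate", max_cycles=6, seed=82,
        )
        assert res.trace[-1][1] >= res.trace[0][1]
        assert 0.4 < res.params["Ne:B"] / 500.0 < 2.5

    def test_bad_bounds_and_unknown_param(self, one_pop_model):
        cfg = SampleConfig({"A": 4})
        obs = simulate_sfs_counts(one_pop_model, cfg, 50, 10_000, seed=9)
        with pytest.raises(ValueError):
            fit_parameters(obs, one_pop_model, cfg, {"Ne:A": (10.0, 5.0)})
        with pytest.raises(KeyError):
            fit_parameters(obs, one_pop_model, cfg, {"Ne:B": (1.0, 10.0)})


def composite_pair_ll(obs, model, cfg, seed, reps=20_000):
    from aspenscan.sfs_demography import pairwise_composite_loglik

    t = branch_sfs_tensor(model, cfg, reps, seed)
    return pairwise_composite_loglik(obs, t, floor=1.0 / (10 * reps * t.data.size))


class TestParametricBootstrap:
    def test_two_boots_interval_is_minmax(self, two_pop_model):
        cfg = SampleConfig({"A": 4, "B": 4})
        out = parametric_bootstrap(
            two_pop_model, cfg, {"Ne:B": (125.0, 2_000.0)}, n_boot=2,
            n_windows=300, n_reps_per_eval=3_000, n_grid=7, seed=91,
        )
        ests = out["estimates"]["Ne:B"]
        lo, hi = out["intervals"]["Ne:B"]
        assert lo == pytest.approx(min(ests), rel=0.01)
        assert hi == pytest.approx(max(ests), rel=0.01)

    def test_deterministic_under_seed(self, two_pop_model):
        cfg = SampleConfig({"A": 4, "B": 4})
        kw = dict(n_boot=2, n_windows=200, n_reps_per_eval=2_000, n_grid=7, seed=93)
        a = parametric_bootstrap(two_pop_model, cfg, {"Ne:B": (125.0, 2_000.0)}, **kw)
        b = parametric_bootstrap(two_pop_model, cfg, {"Ne:B": (125.0, 2_000.0)}, **kw)
        assert a["intervals"] == b["intervals"]

    def test_truth_covered(self, two_pop_model):
        cfg = SampleConfig({"A": 4, "B": 4})
        out = parametric_bootstrap(
            two_pop_model, cfg, {"Ne:B": (125.0, 2_000.0)}, n_boot=10,
            n_windows=1_000, n_reps_per_eval=8_000, n_grid=9, seed=95,
        )
        lo, hi = out["intervals"]["Ne:B"]
        assert lo <= 500.0 <= hi
        assert out["n_failed"] <= 2

    def test_nboot_validation(self, one_pop_model):
        with pytest.raises(ValueError):
            parametric_bootstrap(one_pop_model, SampleConfig({"A": 4}), {}, n_boot=1,
                                 n_windows=10)
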