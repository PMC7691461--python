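import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aspenscan.demography import SampleConfig
from aspenscan.coalescent_sim import drop_mutations, simulate_dataset, simulate_genealogy
from aspenscan.genotype_io import PopulationMap, read_vcf, make_windows, polarize_sites
from aspenscan.popgen_stats import (
    diversity_stats,
    dxy_rnd_window,
    classify_sites,
    estimate_rho,
    fay_wu_h,
    fst_window,
    fu_li_d,
    genotype_pca,
    ld_stats,
    neutrality_stats,
    pbs,
    tajimas_d,
    window_scan,
)
import oracles


def random_haps(rng, n_hap, n_sites):
    """Random segregating haplotype matrix."""
    h = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.uint8)
    keep = (h.sum(0) > 0) & (h.sum(0) < n_hap)
    return h[:, keep]


def counts_from_haps(h):
    n = np.full(h.shape[1], h.shape[0])
    return n, h.sum(axis=0)


class TestDiversityAgainstBruteForce:
    def test_hand_pi_example(self):
        # 4 haplotypes, one SNP at derived count 2, 10 callable bp
        h = np.array([[1], [1], [0], [0]], dtype=np.uint8)
        pi, _, _ = diversity_stats(*counts_from_haps(h), 10.0)
        assert pi == pytest.approx((4 / 6) / 10, abs=1e-12)

    def test_hand_thetaw_example(self):
        h = np.array([[1, 1, 0], [0, 1, 1], [0, 0, 0], [0, 0, 0]], dtype=np.uint8)
        _, tw, _ = diversity_stats(*counts_from_haps(h), 1.0)
        assert tw == pytest.approx(3 / (1 + 0.5 + 1 / 3), abs=1e-9)
        assert tw == pytest.approx(1.6364, abs=1e-4)

    def test_monomorphic_window(self):
        n = np.full(5, 8)
        d = np.zeros(5)
        assert diversity_stats(n, d, 100.0) == (0.0, 0.0, 0.0)

    def test_bad_length_errors(self):
        with pytest.raises(ValueError):
            diversity_stats(np.array([4]), np.array([1]), 0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        h = random_haps(rng, rng.integers(3, 13), 20)
        if h.shape[1] == 0:
            return
        L = 50.0
        n, d = counts_from_haps(h)
        pi, tw, he = diversity_stats(n, d, L)
        assert pi == pytest.approx(oracles.pi_bruteforce(h, L), abs=1e-12)
        assert tw == pytest.approx(oracles.theta_w_bruteforce(h, L), abs=1e-12)
        assert he == pytest.approx(oracles.he_bruteforce(h), abs=1e-12)


class TestNeutralityStats:
    def test_n2_pi_equals_thetaw(self):
        h = np.array([[1, 0, 1], [0, 1, 0]], dtype=np.uint8)
        pi, tw, _ = diversity_stats(*counts_from_haps(h), 1.0)
        assert pi == pytest.approx(tw, abs=1e-12)

    def test_hand_fay_wu_example(self):
        # n=4, single site at derived count 3: pi=0.5, theta_H=1.5, H=-1
        h = np.array([[1], [1], [1], [0]], dtype=np.uint8)
        assert fay_wu_h(4, h.sum(axis=0)) == pytest.approx(-1.0, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_tajd_and_h_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        h = random_haps(rng, rng.integers(4, 10), 20)
        if h.shape[1] == 0:
            return
        n, d = counts_from_haps(h)
        got = tajimas_d(h.shape[0], d)
        want = oracles.tajimas_d_bruteforce(h)
        assert got == pytest.approx(want, abs=1e-12)
        assert fay_wu_h(h.shape[0], d) == pytest.approx(
            oracles.fay_wu_h_bruteforce(h), abs=1e-12
        )

    def test_tajimas_d_against_tskit(self):
        # independent implementation on msprime output
        import msprime

        ts = msprime.sim_ancestry(
            samples=6, population_size=1_000, sequence_length=10_000,
            ploidy=2, random_seed=5,
        )
        ts = msprime.sim_mutations(ts, rate=5e-7, random_seed=6)
        if ts.num_sites < 3:
            pytest.skip("too few sites")
        g = ts.genotype_matrix()
        bi = np.array([len(s.mutations) == 1 for s in ts.sites()])
        d = g[bi].sum(axis=1)
        ours = tajimas_d(g.shape[1], d)
        theirs = float(ts.Tajimas_D())
        assert ours == pytest.approx(theirs, rel=0.02)

    def test_undefined_cases_are_nan(self):
        assert np.isnan(tajimas_d(8, np.zeros(5)))
        assert np.isnan(tajimas_d(3, np.array([1])))
        assert np.isnan(fu_li_d(8, np.zeros(3)))

    def test_neutral_simulation_means_near_zero(self, one_pop_model):
        # E[pi] = E[thetaW] exactly, so the unnormalized Tajima numerator and
        # Fay & Wu's H are mean-zero; the normalized D has a small negative
        # finite-sample expectation, so it only gets a loose absolute band
        num, fwh, taj = [], [], []
        for seed in range(1_500):
            gen = simulate_genealogy(one_pop_model, SampleConfig({"A": 8}), seed)
            _, haps = drop_mutations(gen, 2e-7, 10_000, seed + 1)
            d = haps.sum(axis=0)
            pi, tw, _ = diversity_stats(*counts_from_haps(haps), 10_000.0)
            num.append(pi - tw)
            h = fay_wu_h(8, d)
            t = tajimas_d(8, d)
            if np.isfinite(h):
                fwh.append(h)
            if np.isfinite(t):
                taj.append(t)
        for vals in (np.array(num), np.array(fwh)):
            se = vals.std() / np.sqrt(len(vals))
            assert abs(vals.mean()) < 3 * se
        assert abs(np.mean(taj)) < 0.15


class TestFst:
    def test_fixed_difference_is_one(self):
        gA = np.full((4, 5), 0, dtype=np.int8)
        gB = np.full((4, 5), 2, dtype=np.int8)
        assert fst_window(gA, gB, "WC") == pytest.approx(1.0)
        assert fst_window(gA, gB, "Hudson") == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=(25, 60)).astype(np.int8)
        for est in ("WC", "Hudson"):
            v = fst_window(g, g.copy(), est)
            assert v >= -0.05 and v < 0.05

    def test_hand_hudson_single_site(self):
        # p1=0.5 (n1=4), p2=0 (n2=4): num=0.25-0.25/3, den=0.5 -> 1/3
        gA = np.array([[1], [1], [0], [0]], dtype=np.int8)  # wait: dosage
        gA = np.array([[1], [1]], dtype=np.int8)  # 2 diploids, p=0.5
        gB = np.array([[0], [0]], dtype=np.int8)
        assert fst_window(gA, gB, "Hudson") == pytest.approx(1 / 3, abs=1e-12)

    def test_unknown_estimator(self):
        with pytest.raises(ValueError):
            fst_window(np.zeros((2, 1), dtype=np.int8), np.zeros((2, 1), dtype=np.int8), "x")

    def test_no_polymorphism_is_nan(self):
        g = np.zeros((3, 4), dtype=np.int8)
        assert np.isnan(fst_window(g, g, "WC"))

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        gA = rng.integers(0, 3, size=(4, 12)).astype(np.int8)
        gB = rng.integers(0, 3, size=(5, 12)).astype(np.int8)
        hA = np.vstack([(gA > 0).astype(int) * 0 + (gA >= 1).astype(int),
                        (gA == 2).astype(int)])
        # build haplotypes consistent with dosages for the Hudson oracle
        hapA = np.concatenate([[(gA[i] >= 1).astype(int), (gA[i] == 2).astype(int)]
                               for i in range(gA.shape[0])])
        hapB = np.concatenate([[(gB[i] >= 1).astype(int), (gB[i] == 2).astype(int)]
                               for i in range(gB.shape[0])])
        want_h = oracles.hudson_fst_bruteforce(np.array(hapA), np.array(hapB))
        got_h = fst_window(gA, gB, "Hudson")
        if np.isfinite(want_h):
            assert got_h == pytest.approx(want_h, abs=1e-12)
        want_wc = oracles.wc_fst_bruteforce(gA, gB)
        got_wc = fst_window(gA, gB, "WC")
        if np.isfinite(want_wc):
            assert got_wc == pytest.approx(want_wc, abs=1e-12)

    def test_wc_and_hudson_agree_on_balanced_design(self, two_pop_model):
        cfg = SampleConfig({"A": 40, "B": 40})
        vals = {"WC": [], "Hudson": []}
        for seed in range(30):
            gen = simulate_genealogy(two_pop_model, cfg, seed)
            _, haps = drop_mutations(gen, 3e-8, 10_000, seed + 7)
            if haps.shape[1] < 2:
                continue
            gA = (haps[0:40:2] + haps[1:40:2]).astype(np.int8)
            gB = (haps[40::2] + haps[41::2]).astype(np.int8)
            for est in vals:
                vals[est].append(fst_window(gA, gB, est))
        wc = np.nanmean(vals["WC"])
        hu = np.nanmean(vals["Hudson"])
        assert abs(wc - hu) < 0.02


class TestDxyRnd:
    def test_hand_examples(self):
        nA = np.array([4]); dA = np.array([0])
        nB = np.array([4]); dB = np.array([4])
        dxy, _, _ = dxy_rnd_window(nA, dA, nB, dB, None, None, 10.0)
        assert dxy == pytest.approx(0.1, abs=1e-12)

    def test_rnd_arithmetic(self):
        nA = np.array([2, 2]); dA = np.array([0, 0])
        nB = np.array([2, 2]); dB = np.array([2, 2])
        nO = np.array([2, 2]); dO = np.array([2, 2])
        # dxy_AB = 2/L; dxy_AO = 2/L -> RND = 1
        _, _, rnd = dxy_rnd_window(nA, dA, nB, dB, nO, dO, 10.0)
        assert rnd == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        hA = rng.integers(0, 2, size=(4, 15))
        hB = rng.integers(0, 2, size=(6, 15))
        L = 30.0
        nA = np.full(15, 4); nB = np.full(15, 6)
        dxy, _, _ = dxy_rnd_window(nA, hA.sum(0), nB, hB.sum(0), None, None, L)
        assert dxy == pytest.approx(oracles.dxy_bruteforce(hA, hB, L), abs=1e-12)

    def test_analytic_expectation_two_pops(self):
        # E[dxy] = (4 Ne_anc + 2 T) * mu per site for an isolation model
        from aspenscan.demography import DemographicModel
        from aspenscan.coalescent_sim import simulate_sfs_counts

        m = DemographicModel(
            populations=["A", "B"], Ne={"A": 500.0, "B": 500.0},
            splits=[(2_000.0, "B", "A")], size_changes={"A": [(2_000.0, 1_000.0)]},
        )
        mu = m.mu_per_gen
        cfg = SampleConfig({"A": 2, "B": 2})
        n_win, L = 8_000, 10_000
        counts = simulate_sfs_counts(m, cfg, n_win, L, seed=77)
        i, j = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
        p1, p2 = i / 2.0, j / 2.0
        w = p1 * (1 - p2) + p2 * (1 - p1)
        dxy = (counts.data * w).sum() / (n_win * L)
        expect = (4 * 1_000 + 2 * 2_000) * mu
        # 3-SE band using the per-window spread implied by total counts
        assert dxy == pytest.approx(expect, rel=0.05)


class TestClassifySites:
    def test_three_trivial_classes(self):
        nA = np.array([4, 4, 4]); nB = np.array([4, 4, 4])
        derA = np.array([4, 2, 2]); derB = np.array([0, 2, 0])
        out = classify_sites(nA, derA, nB, derB)
        assert out["fixed_difference"] == 1
        assert out["shared_polymorphism"] == 1
        assert out["private_A"] == 1

    def test_classes_partition_sites(self):
        rng = np.random.default_rng(3)
        nA = np.full(50, 6); nB = np.full(50, 6)
        derA = rng.integers(0, 7, 50); derB = rng.integers(0, 7, 50)
        out = classify_sites(nA, derA, nB, derB)
        assert sum(out.values()) == 50


class TestLD:
    def test_perfect_ld(self):
        h = np.array([[1, 1], [1, 1], [0, 0], [0, 0]])
        st_ = ld_stats(h, np.array([0, 2_000]), min_pair_dist=1_000)
        assert st_.mean_r2 == pytest.approx(1.0)

    def test_zero_d(self):
        h = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        st_ = ld_stats(h, np.array([0, 2_000]), min_pair_dist=1_000)
        assert st_.mean_r2 == pytest.approx(0.0, abs=1e-12)

    def test_no_eligible_pairs_null(self):
        h = np.array([[1, 0], [0, 1]])
        st_ = ld_stats(h, np.array([0, 10]), min_pair_dist=1_000)
        assert np.isnan(st_.mean_r2)

    def test_r2_matches_definition(self):
        rng = np.random.default_rng(4)
        h = random_haps(rng, 8, 6)
        if h.shape[1] < 2:
            pytest.skip("degenerate draw")
        pos = np.arange(h.shape[1]) * 2_000
        st_ = ld_stats(h, pos, min_pair_dist=1_000)
        # brute force D^2 / p(1-p)q(1-q) over pairs
        vals = []
        for i in range(h.shape[1]):
            for j in range(i + 1, h.shape[1]):
                pa, pb = h[:, i].mean(), h[:, j].mean()
                pab = (h[:, i] & h[:, j]).mean()
                D = pab - pa * pb
                vals.append(D * D / (pa * (1 - pa) * pb * (1 - pb)))
        assert st_.mean_r2 == pytest.approx(np.mean(vals), abs=1e-12)


class TestRho:
    def test_all_perfect_ld_gives_zero(self):
        h = np.tile(np.array([[1], [1], [0], [0], [1], [0], [1], [0], [1], [0]]), (1, 12))
        pos = np.arange(12) * 800
        assert estimate_rho(h, pos, 10_000, min_snps=10) == 0.0

    def test_too_few_snps_is_nan(self):
        h = np.array([[1, 0], [0, 1], [1, 1], [0, 0]])
        assert np.isnan(estimate_rho(h, np.array([0, 5_000]), 10_000, min_snps=10))

    def test_ordering_and_rank_with_true_rho(self):
        # windows simulated at increasing rho: the moment estimator must
        # order the medians and rank-correlate with the truth
        from aspenscan.demography import DemographicModel
        from aspenscan.coalescent_sim import simulate_dataset
        from scipy.stats import spearmanr
        import tempfile, os

        # high mutation rate so each 5-kb window carries ~100 SNPs
        m = DemographicModel(populations=["A"], Ne={"A": 1_000.0}, mu_per_year=4e-7)
        cfg = SampleConfig({"A": 12})
        n_win = 20
        med = {}
        mean_r2 = {}
        truths, ests = [], []
        for rho in (0.0, 20.0, 80.0):
            vals = []
            r2s = []
            with tempfile.TemporaryDirectory() as td:
                simulate_dataset(
                    m, cfg, n_win, os.path.join(td, "w"),
                    window_bp=5_000, recombination_rho=rho, seed=int(rho) + 3,
                )
                gm = read_vcf(os.path.join(td, "w.vcf"))
                ws = make_windows({"chr_sim": n_win * 5_000}, 5_000)
                wi = ws.site_window_index(gm)
                for w in range(n_win):
                    sites = np.nonzero(wi == w)[0]
                    if len(sites) < 10:
                        continue
                    haps = gm.haplotypes[:, sites]
                    st2 = ld_stats(haps, gm.positions[sites] - 1, min_pair_dist=0)
                    if np.isfinite(st2.mean_r2):
                        r2s.append(st2.mean_r2)
                    r = estimate_rho(haps, gm.positions[sites] - 1, 5_000,
                                     min_pair_dist=0)
                    if np.isfinite(r):
                        vals.append(r)
                        truths.append(rho)
                        ests.append(r)
            med[rho] = np.median(vals)
            mean_r2[rho] = np.mean(r2s)
        assert mean_r2[0.0] > mean_r2[20.0] > mean_r2[80.0]
        assert med[0.0] <= med[20.0] <= med[80.0]
        corr = spearmanr(truths, ests).statistic
        assert corr > 0.3


class TestPbs:
    def test_zero_and_closed_form(self):
        assert pbs(0.0, 0.0, 0.0) == 0.0
        assert pbs(0.5, 0.5, 0.0) == pytest.approx(np.log(2), abs=1e-12)

    def test_symmetry_in_other_branches(self):
        assert pbs(0.3, 0.2, 0.1) == pytest.approx(pbs(0.2, 0.3, 0.1), abs=1e-15)

    def test_clamps_fst_one_with_warning(self):
        with pytest.warns(UserWarning):
            v = pbs(1.0, 0.2, 0.1)
        assert np.isfinite(v)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pbs(float("nan"), 0.1, 0.1)


class TestPca:
    def test_two_groups_separate_on_pc1(self):
        from conftest import make_gm

        g = [[0] * 10] * 4 + [[2] * 10] * 4
        gm = make_gm(g)
        coords, frac = genotype_pca(gm)
        assert frac.sum() == pytest.approx(1.0)
        pc1 = coords[:, 0]
        assert (pc1[:4] > 0).all() != (pc1[4:] > 0).all()  # groups on opposite sides

    def test_population_clusters_on_simulated_data(self, sim_run):
        from sklearn.metrics import silhouette_score

        pm = PopulationMap.read_tsv(sim_run["popmap"])
        gm = read_vcf(sim_run["vcf"], pm)
        ingroup = [s for s in gm.sample_ids if pm.mapping[s] != "OUTGROUP"]
        coords, frac = genotype_pca(gm, samples=ingroup)
        labels = [pm.mapping[s] for s in ingroup]
        score = silhouette_score(coords[:, :2], labels)
        assert score > 0.5
        assert frac.sum() == pytest.approx(1.0)


class TestWindowScanDriver:
    def test_scan_columns_and_invariants(self, sim_run):
        pm = PopulationMap.read_tsv(sim_run["popmap"])
        gm = read_vcf(sim_run["vcf"], pm)
        pol = polarize_sites(gm, pm.samples_for("OUTGROUP"))
        ws = make_windows({"chr_sim": 40 * 10_000}, 10_000)
        tab = window_scan(gm, pm, ws, pol=pol, compute_ld=False)
        assert len(tab) == 40
        for col in ("pi_N", "thetaW_S", "fst_N_S", "dxy_N_S", "rnd_N_S", "pbs_N",
                    "fixed_N_S", "shared_N_S"):
            assert col in tab.columns
        assert (tab["pi_N"] >= 0).all()
        assert (tab[["fst_N_S", "fst_N_C", "fst_C_S"]].max() <= 1.0).all()
        finite_rnd = tab["rnd_N_S"].dropna()
        assert (finite_rnd > 0).all()
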