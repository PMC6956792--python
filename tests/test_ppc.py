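import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ppcoal as pc
from ppcoal.ppc import tukey_fivenum
from ppcoal.sumstats import PairwiseFstMatrix


def fst_matrix(species, pair_values):
    k = len(species)
    vals = np.full((k, k), np.nan)
    idx = [(i, j) for i in range(k) for j in range(i + 1, k)]
    for (i, j), v in zip(idx, pair_values):
        vals[i, j] = vals[j, i] = v
    return PairwiseFstMatrix(list(species), vals, np.zeros((k, k), dtype=int))


def degenerate_posterior(tree, n):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pc.PosteriorTreeSet([tree.copy() for _ in range(n)])


class TestTwoTailedPpp:
    def test_worked_example(self):
        # below = 4, above = 6 -> p = 2 * 4 / 10
        p = pc.two_tailed_ppp(5, [1, 2, 3, 4, 6, 7, 8, 9, 10, 11])
        assert p == pytest.approx(0.8)

    def test_empirical_outside_support_zero(self):
        assert pc.two_tailed_ppp(0, [1, 2, 3, 4]) == 0.0
        assert pc.two_tailed_ppp(9, [1, 2, 3, 4]) == 0.0

    def test_all_ties_return_one(self):
        assert pc.two_tailed_ppp(3.0, [3.0, 3.0, 3.0]) == 1.0

    def test_capped_at_one(self):
        assert pc.two_tailed_ppp(5, [4, 6]) == 1.0

    def test_ties_count_in_neither_tail(self):
        # 2 below, 1 tie, 3 above -> p = 2 * 2 / 6
        p = pc.two_tailed_ppp(5, [1, 2, 5, 7, 8, 9])
        assert p == pytest.approx(2 * 2 / 6)

    def test_empty_predictive_rejected(self):
        with pytest.raises(ValueError):
            pc.two_tailed_ppp(1.0, [])

    @given(
        st.integers(-400, 400),
        st.lists(st.integers(-400, 400), min_size=1, max_size=30),
        st.sampled_from(["affine", "exp", "cube"]),
    )
    def test_invariant_under_monotone_transforms(self, emp, pred, kind):
        # integer grid keeps the transforms strictly monotone in floats
        emp = emp / 4.0
        pred = [v / 4.0 for v in pred]
        transform = {
            "affine": lambda x: 3.0 * x + 7.0,
            "exp": lambda x: float(np.exp(x / 50.0)),
            "cube": lambda x: x**3,
        }[kind]
        p0 = pc.two_tailed_ppp(emp, pred)
        p1 = pc.two_tailed_ppp(transform(emp), [transform(v) for v in pred])
        assert p0 == pytest.approx(p1)

    def test_super_uniform_under_null(self):
        """P(p <= alpha) stays near alpha for exchangeable draws.

        With 99 predictive draws the attainable p-values are discrete,
        so the bound carries a discreteness + Monte-Carlo slack.
        """
        rng = np.random.default_rng(2024)
        n_reps, n_pred = 1_000, 99
        draws = rng.normal(size=(n_reps, n_pred + 1))
        pvals = np.array(
            [pc.two_tailed_ppp(row[0], row[1:]) for row in draws]
        )
        for alpha in (0.05, 0.1):
            assert (pvals <= alpha).mean() <= alpha + 0.04


class TestTukeyFivenum:
    def test_matches_r_fivenum_convention(self):
        # R: fivenum(c(0, 0.01, 0.01, 0.02, 0.5)) -> 0.00 0.01 0.01 0.02 0.50
        assert tukey_fivenum([0.01, 0.0, 0.02, 0.01, 0.5]) == pytest.approx(
            (0.0, 0.01, 0.01, 0.02, 0.5)
        )
        # R: fivenum(1:4) -> 1.0 1.5 2.5 3.5 4.0
        assert tukey_fivenum([1, 2, 3, 4]) == pytest.approx(
            (1.0, 1.5, 2.5, 3.5, 4.0)
        )

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40))
    def test_ordered_and_bounded(self, xs):
        mn, q1, med, q3, mx = tukey_fivenum(xs)
        assert mn <= q1 <= med <= q3 <= mx
        assert mn == min(xs) and mx == max(xs)


class TestFstOutlierTest:
    def test_single_large_difference_flagged(self):
        species = ["s1", "s2", "s3", "s4", "s5"]
        # 5 pairs informative: d = {0.01, 0.00, 0.02, 0.01, 0.50}
        emp = fst_matrix(species, [0.51, 0.50, 0.52, 0.51, 1.00] + [np.nan] * 5)
        pred = [fst_matrix(species, [0.5] * 5 + [np.nan] * 5) for _ in range(3)]
        violation, outliers = pc.fst_outlier_test(emp, pred)
        assert violation
        # the fifth informative pair in upper-triangle order is (s2, s3)
        assert outliers == [("s2", "s3")]

    def test_constant_differences_not_flagged(self):
        species = ["s1", "s2", "s3", "s4"]
        emp = fst_matrix(species, [0.4] * 6)
        pred = [fst_matrix(species, [0.3] * 6) for _ in range(4)]
        violation, outliers = pc.fst_outlier_test(emp, pred)
        assert not violation and outliers == []

    def test_empirical_equal_to_predictive_mean_clean(self):
        species = ["s1", "s2", "s3", "s4"]
        emp = fst_matrix(species, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        pred = [
            fst_matrix(species, [0.1 + d, 0.2 + d, 0.3 + d, 0.4 + d, 0.5 + d, 0.6 + d])
            for d in (-0.01, 0.01)
        ]
        violation, _ = pc.fst_outlier_test(emp, pred)
        assert not violation

    def test_relabeling_equivariance(self):
        rng = np.random.default_rng(77)
        species = ["s1", "s2", "s3", "s4", "s5"]
        base = rng.uniform(0.1, 0.9, size=10)
        base[3] += 5.0  # force an outlier pair
        emp = fst_matrix(species, base)
        pred = [fst_matrix(species, rng.uniform(0.1, 0.2, size=10)) for _ in range(3)]
        _, outliers = pc.fst_outlier_test(emp, pred)

        perm = ["s3", "s1", "s5", "s2", "s4"]
        order = [species.index(s) for s in perm]
        emp_p = PairwiseFstMatrix(
            perm, emp.values[np.ix_(order, order)], emp.per_pair_loci
        )
        pred_p = [
            PairwiseFstMatrix(perm, m.values[np.ix_(order, order)], m.per_pair_loci)
            for m in pred
        ]
        _, outliers_p = pc.fst_outlier_test(emp_p, pred_p)
        assert {frozenset(p) for p in outliers} == {
            frozenset(p) for p in outliers_p
        }

    def test_too_few_predictive_rejected(self):
        species = ["s1", "s2", "s3"]
        emp = fst_matrix(species, [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            pc.fst_outlier_test(emp, [emp])


class TestTreeDistanceNull:
    def test_identical_posterior_threshold_zero(self, symmetric4):
        posterior = degenerate_posterior(symmetric4, 10)
        assert pc.tree_distance_null(posterior, "RF", n=100, seed=0) == 0.0
        assert pc.tree_distance_null(posterior, "KF", n=100, seed=0) == 0.0

    def test_deterministic_under_seed(self, symmetric4):
        rng = np.random.default_rng(1)
        trees = []
        for _ in range(10):
            t = symmetric4.copy()
            for nd in t.tree.preorder_node_iter():
                if nd.edge.length is not None:
                    nd.edge.length *= float(rng.lognormal(0, 0.2))
            trees.append(t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            posterior = pc.PosteriorTreeSet(trees)
        a = pc.tree_distance_null(posterior, "KF", n=200, seed=5)
        b = pc.tree_distance_null(posterior, "KF", n=200, seed=5)
        assert a == b > 0

    def test_two_topologies_threshold_is_their_distance(self, symmetric4):
        other = pc.parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            posterior = pc.PosteriorTreeSet([symmetric4, other])
        # members of each sampled pair are forced distinct, so every null
        # comparison is between the two topologies
        thr = pc.tree_distance_null(posterior, "RF", n=50, seed=3)
        assert thr == pytest.approx(pc.rf_distance(symmetric4, other))

    def test_single_tree_rejected(self, symmetric4):
        posterior = degenerate_posterior(symmetric4, 1)
        with pytest.raises(ValueError):
            pc.tree_distance_null(posterior, "RF", n=10, seed=0)


class TestTreeDistancePpp:
    def test_all_below_threshold_no_violation(self, symmetric4):
        posterior = degenerate_posterior(symmetric4, 10)
        pp_sets = [
            (symmetric4, degenerate_posterior(symmetric4, 5)) for _ in range(3)
        ]
        cfg = pc.PPCConfig(n_pp_tree_comparisons=20, n_null_comparisons=50, seed=1)
        res = pc.tree_distance_ppp(posterior, pp_sets, "RF", cfg)
        assert res.p_value == 0.0
        assert not res.violation

    def test_all_above_threshold_violation(self, symmetric4):
        other = pc.parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        posterior = degenerate_posterior(symmetric4, 10)  # null threshold 0
        pp_sets = [(symmetric4, degenerate_posterior(other, 5))]
        cfg = pc.PPCConfig(n_pp_tree_comparisons=20, n_null_comparisons=50, seed=1)
        res = pc.tree_distance_ppp(posterior, pp_sets, "RF", cfg)
        assert res.p_value == 1.0
        assert res.violation

    def test_p_fraction_of_pooled_comparisons(self, symmetric4):
        other = pc.parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        posterior = degenerate_posterior(symmetric4, 10)
        # one clean pp set, one fully discordant: pooled p = 0.5
        pp_sets = [
            (symmetric4, degenerate_posterior(symmetric4, 5)),
            (symmetric4, degenerate_posterior(other, 5)),
        ]
        cfg = pc.PPCConfig(n_pp_tree_comparisons=50, n_null_comparisons=50, seed=1)
        res = pc.tree_distance_ppp(posterior, pp_sets, "RF", cfg)
        assert res.p_value == pytest.approx(0.5)

    def test_p_nonincreasing_in_threshold(self, symmetric4):
        """Raising the null quantile can only lower the exceedance p."""
        rng = np.random.default_rng(9)
        trees = []
        for _ in range(20):
            t = symmetric4.copy()
            for nd in t.tree.preorder_node_iter():
                if nd.edge.length is not None:
                    nd.edge.length *= float(rng.lognormal(0, 0.3))
            trees.append(t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            posterior = pc.PosteriorTreeSet(trees)
        pp_sets = [(trees[0], posterior)]
        previous = 1.1
        for q in (0.5, 0.75, 0.95):
            cfg = pc.PPCConfig(
                n_pp_tree_comparisons=100,
                n_null_comparisons=200,
                null_quantile=q,
                seed=4,
            )
            p = pc.tree_distance_ppp(posterior, pp_sets, "KF", cfg).p_value
            assert p <= previous + 1e-12
            previous = p


class TestRunDataBasedCheck:
    def _setup(self, reference_tree, seed=0, n_snps=100):
        model = pc.build_demography(reference_tree, 100_000.0)
        spm = {sp: 2 for sp in reference_tree.tip_labels}
        empirical = pc.simulate_snp_matrix(
            model, pc.SimulationConfig(n_snps=n_snps, samples_per_species=spm, seed=seed)
        )
        posterior = degenerate_posterior(reference_tree, 30)
        sim_cfg = pc.SimulationConfig(
            n_snps=n_snps, samples_per_species=spm, seed=seed
        )
        return empirical, posterior, sim_cfg

    def test_report_contains_requested_statistics(self, reference_tree):
        empirical, posterior, sim_cfg = self._setup(reference_tree)
        report = pc.run_data_based_check(
            empirical,
            posterior,
            model_builder=lambda t: pc.build_demography(t, 100_000.0),
            config=pc.PPCConfig(seed=1),
            sim_config=sim_cfg,
            n_pp_datasets=10,
        )
        assert set(report.results) == {"FSTA", "FSTR", "PFST"}
        assert 0 <= report.results["FSTA"].p_value <= 1
        assert report.results["PFST"].p_value is None

    def test_deterministic_under_seed(self, reference_tree):
        empirical, posterior, sim_cfg = self._setup(reference_tree)
        kw = dict(
            model_builder=lambda t: pc.build_demography(t, 100_000.0),
            config=pc.PPCConfig(seed=7),
            sim_config=sim_cfg,
            n_pp_datasets=8,
        )
        a = pc.run_data_based_check(empirical, posterior, **kw)
        b = pc.run_data_based_check(empirical, posterior, **kw)
        assert a.to_json() == b.to_json()

    def test_species_outside_posterior_rejected(self, reference_tree):
        empirical, _, sim_cfg = self._setup(reference_tree)
        wrong = degenerate_posterior(
            pc.parse_newick("((x:1,y:1):1,(z:1,w:1):1);"), 5
        )
        with pytest.raises(ValueError, match="missing"):
            pc.run_data_based_check(
                empirical,
                wrong,
                model_builder=lambda t: pc.build_demography(t, 100_000.0),
                config=pc.PPCConfig(),
                sim_config=sim_cfg,
            )


class TestRunInferenceBasedCheck:
    def _posterior_and_log(self, tree, sd=10.0, seed=0, n=30):
        return pc.generate_synthetic_posterior(
            pc.SyntheticPosteriorConfig(
                center_tree=tree,
                n_samples=n,
                length_jitter_cv=0.05,
                likelihood_mean=-1000.0,
                likelihood_sd=sd,
                seed=seed,
            )
        )

    def test_report_contains_exactly_inference_statistics(self, reference_tree):
        posterior, log = self._posterior_and_log(reference_tree)
        pp = [
            (posterior[i], *self._posterior_and_log(posterior[i], seed=i + 1))
            for i in range(5)
        ]
        report = pc.run_inference_based_check(
            posterior, log, pp, pc.PPCConfig(n_null_comparisons=100,
                                             n_pp_tree_comparisons=20, seed=2)
        )
        assert set(report.results) == {"RF", "KF", "MLM", "MLSD"}

    def test_identical_logs_give_tie_pvalue_one(self, reference_tree):
        posterior, log = self._posterior_and_log(reference_tree, seed=5)
        pp = [
            (posterior[i], self._posterior_and_log(posterior[i], seed=i + 1)[0], log)
            for i in range(4)
        ]
        report = pc.run_inference_based_check(
            posterior, log, pp,
            pc.PPCConfig(n_null_comparisons=50, n_pp_tree_comparisons=10, seed=0),
            statistics=("MLM", "MLSD"),
        )
        assert report.results["MLM"].p_value == 1.0
        assert report.results["MLSD"].p_value == 1.0
        assert not report.results["MLSD"].violation

    def test_inflated_posterior_sd_detected(self, reference_tree):
        posterior, log = self._posterior_and_log(reference_tree, sd=300.0, seed=5)
        pp = [
            (posterior[i], *self._posterior_and_log(posterior[i], sd=10.0, seed=i + 1))
            for i in range(10)
        ]
        report = pc.run_inference_based_check(
            posterior, log, pp,
            pc.PPCConfig(n_null_comparisons=50, n_pp_tree_comparisons=10, seed=0),
            statistics=("MLSD",),
        )
        assert report.results["MLSD"].p_value == 0.0
        assert report.results["MLSD"].violation

    def test_empty_pp_rejected(self, reference_tree):
        posterior, log = self._posterior_and_log(reference_tree)
        with pytest.raises(ValueError):
            pc.run_inference_based_check(posterior, log, [], pc.PPCConfig())


class TestReportSerialization:
    def test_json_and_table(self, reference_tree):
        res = pc.StatisticResult("FSTA", p_value=0.2, violation=False)
        report = pc.PPCReport(
            results={"FSTA": res}, config=pc.PPCConfig(), provenance={"x": 1}
        )
        payload = report.to_json()
        assert '"FSTA"' in payload and '"p_value": 0.2' in payload
        table = report.to_table()
        assert "FSTA" in table and "no" in table
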