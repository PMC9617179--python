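"""The intolerance-threshold scan: nested sets, incremental CMH,
permutation empirical p-values and the optimum."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import rvburden as rv
from rvburden.scan import ScanResult, _build_engine, _shuffle_within_clusters


def mini_panel(loeufs, genes=None):
    genes = genes or [f"G{i}" for i in range(len(loeufs))]
    return pd.DataFrame({
        "gene": genes, "loeuf": loeufs,
        "disease_associated": [False] * len(genes),
        "mu_syn": [1e-6] * len(genes), "mu_mis": [1e-6] * len(genes),
        "mu_lof": [1e-7] * len(genes),
    })


class TestNestedGenesets:
    def test_duplicate_scores_collapse(self):
        panel = mini_panel([0.1, 0.1, 0.5])
        sets = rv.nested_genesets(panel, {"G0", "G1", "G2"})
        assert [t for t, _ in sets] == [0.1, 0.5]
        assert [len(s) for _, s in sets] == [2, 3]

    def test_largest_set_is_all_qv_genes(self, small_panel, small_matrix):
        qv = small_matrix.genes_with_qv()
        sets = rv.nested_genesets(small_panel, qv)
        assert sets[-1][1] == qv

    def test_threshold_count_equals_unique_scores(self, rng):
        for _ in range(10):
            loeufs = np.round(rng.uniform(0.05, 2, size=30), 1)
            panel = mini_panel(list(loeufs))
            sets = rv.nested_genesets(panel, set(panel["gene"]))
            assert len(sets) == len(np.unique(loeufs))

    def test_sizes_non_decreasing_and_nested(self, small_panel, small_matrix):
        sets = rv.nested_genesets(small_panel, small_matrix.genes_with_qv())
        for (_, s1), (_, s2) in zip(sets, sets[1:]):
            assert s1 <= s2 and len(s1) <= len(s2)

    def test_empty_input_rejected(self, small_panel):
        with pytest.raises(ValueError):
            rv.nested_genesets(small_panel, set())

    def test_missing_loeuf_named(self, small_matrix):
        panel = mini_panel([0.5], genes=["ONLY"])
        with pytest.raises(ValueError):
            rv.nested_genesets(panel, small_matrix.genes_with_qv())


class TestScanCMH:
    def test_incremental_equals_naive_recompute(self):
        cfg = rv.SimulationConfig(
            n_cases=40, n_controls=120, n_genes=50,
            baseline_carrier_rate=(0.03, 0.04, 0.05), seed=17,
        )
        panel = rv.simulate_gene_panel(cfg)
        cohort = rv.simulate_cohort(cfg, panel)
        m = rv.matrix_from_arrays(cohort.genes, cohort.samples, cohort.X_all)
        thresholds, p_fast = rv.scan_cmh(m, panel, statistic="exact")
        naive = []
        for t, geneset in rv.nested_genesets(panel, m.genes_with_qv()):
            table = rv.collapse_to_table(m, geneset)
            naive.append(rv.cmh_exact_test(table).p_two_sided)
        assert np.allclose(p_fast, naive, atol=1e-12)
        assert np.allclose(thresholds,
                           [t for t, _ in rv.nested_genesets(panel,
                                                             m.genes_with_qv())])

    def test_carrier_free_genes_do_not_enter_the_grid(self, small_cfg,
                                                      small_panel,
                                                      small_cohort):
        m = rv.matrix_from_arrays(small_cohort.genes, small_cohort.samples,
                                  small_cohort.X_all)
        extra = mini_panel([0.321], genes=["EMPTY_GENE"])
        panel2 = pd.concat([small_panel, extra], ignore_index=True)
        t1, p1 = rv.scan_cmh(m, small_panel, statistic="asymptotic")
        t2, p2 = rv.scan_cmh(m, panel2, statistic="asymptotic")
        assert np.array_equal(t1, t2) and np.allclose(p1, p2)


class TestPermutations:
    @staticmethod
    def _null_matrix(seed=23, n_genes=40):
        cfg = rv.SimulationConfig(
            n_cases=30, n_controls=90, n_genes=n_genes, enrichment_or=1.0,
            baseline_carrier_rate=(0.04, 0.05, 0.06), seed=seed,
        )
        panel = rv.simulate_gene_panel(cfg)
        cohort = rv.simulate_cohort(cfg, panel)
        return panel, rv.matrix_from_arrays(cohort.genes, cohort.samples,
                                            cohort.X_all)

    def test_determinism_under_seed(self):
        panel, m = self._null_matrix()
        _, e1 = rv.permutation_empirical(m, panel, 50, seed=3)
        _, e2 = rv.permutation_empirical(m, panel, 50, seed=3)
        assert np.array_equal(e1, e2)

    def test_floor_and_ceiling(self):
        panel, m = self._null_matrix()
        _, emp = rv.permutation_empirical(m, panel, 99, seed=4)
        assert (emp >= 1 / 100).all() and (emp <= 1.0).all()

    def test_plugin_estimator_can_reach_zero(self):
        cfg = rv.SimulationConfig(
            n_cases=100, n_controls=300, n_genes=40, enrichment_or=8.0,
            enrichment_loeuf_max=2.0,
            baseline_carrier_rate=(0.02, 0.03, 0.04), seed=29,
        )
        panel = rv.simulate_gene_panel(cfg)
        cohort = rv.simulate_cohort(cfg, panel)
        m = rv.matrix_from_arrays(cohort.genes, cohort.samples, cohort.X_all)
        _, emp = rv.permutation_empirical(m, panel, 200, seed=5,
                                          estimator="plugin")
        assert emp.min() == 0.0

    def test_within_cluster_shuffles_preserve_margins(self):
        panel, m = self._null_matrix()
        engine = _build_engine(m, panel)
        rng = np.random.default_rng(0)
        members = [np.flatnonzero(engine.cluster_of == k)
                   for k in range(len(engine.cluster_ids))]
        for _ in range(20):
            labels = _shuffle_within_clusters(rng, members, engine)
            for k, idx in enumerate(members):
                assert labels[idx].sum() == engine.n1[k]
            # carrier margins per threshold are label-independent
            a = engine.case_carriers(labels)
            assert (a <= engine.m1).all()

    def test_exact_statistic_agrees_with_asymptotic_ranking(self):
        panel, m = self._null_matrix(n_genes=12)
        _, emp_asym = rv.permutation_empirical(m, panel, 60, seed=6,
                                               statistic="asymptotic")
        _, emp_exact = rv.permutation_empirical(m, panel, 60, seed=6,
                                                statistic="exact")
        assert emp_asym.shape == emp_exact.shape
        # both are valid empirical p-vectors from the same shuffles
        assert (emp_exact >= 1 / 61).all() and (emp_exact <= 1).all()

    def test_null_empirical_p_is_uniform(self):
        """Under the null the empirical p at a fixed threshold is discrete
        uniform; a KS test across replicates should not reject at 1%."""
        vals = []
        for rep in range(150):
            # large enough that ties in the discrete statistic are rare;
            # tiny cohorts make the add-one estimator visibly conservative
            cfg = rv.SimulationConfig(
                n_cases=100, n_controls=400, n_genes=40, enrichment_or=1.0,
                baseline_carrier_rate=(0.04, 0.048, 0.056), seed=40_000 + rep,
            )
            panel = rv.simulate_gene_panel(cfg)
            cohort = rv.simulate_cohort(cfg, panel)
            m = rv.matrix_from_arrays(cohort.genes, cohort.samples,
                                      cohort.X_all)
            _, emp = rv.permutation_empirical(m, panel, 150,
                                              seed=50_000 + rep)
            vals.append(emp[len(emp) // 2])
        # compare against the discrete uniform on {1..n+1}/(n+1)
        grid = np.arange(1, 152) / 151
        cdf = lambda x: np.searchsorted(grid, x, side="right") / 151
        stat = sps.kstest(vals, cdf).pvalue
        assert stat > 0.01


class TestOptimum:
    @staticmethod
    def _result(emp, nominal=None, n_perm=100):
        emp = np.asarray(emp, dtype=float)
        nominal = (np.asarray(nominal, dtype=float)
                   if nominal is not None else emp.copy())
        thresholds = np.linspace(0.1, 1.0, len(emp))
        return ScanResult(thresholds, np.arange(1, len(emp) + 1),
                          nominal, emp, n_perm, 0.05 / len(emp), 0,
                          "asymptotic")

    def test_monotone_vector_picks_first(self):
        scan = self._result([0.01, 0.02, 0.5, 0.9])
        t, p, _ = rv.optimal_threshold(scan)
        assert t == scan.thresholds[0] and p == 0.01

    def test_equal_minima_break_to_smaller_threshold(self):
        scan = self._result([0.02, 0.01, 0.01, 0.9])
        t, _, _ = rv.optimal_threshold(scan)
        assert t == scan.thresholds[1]

    def test_floor_ties_break_by_nominal_p(self):
        emp = [0.01, 0.01, 0.01, 0.5]
        nominal = [1e-3, 1e-8, 1e-5, 0.5]
        scan = self._result(emp, nominal)
        t, _, _ = rv.optimal_threshold(scan)
        assert t == scan.thresholds[1]

    def test_significance_fallback_warns_when_floor_exceeds_bar(self):
        scan = self._result([0.01, 0.5], nominal=[1e-9, 0.5], n_perm=100)
        # bonferroni alpha = 0.025 > floor 1/101: attainable, no fallback
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            t, p, sig = rv.optimal_threshold(scan)
        assert sig
        tight = self._result([0.01] + [0.5] * 999, nominal=[1e-9] + [0.5] * 999,
                             n_perm=100)
        with pytest.warns(UserWarning, match="unattainable"):
            _, _, sig2 = rv.optimal_threshold(tight)
        assert sig2  # nominal 1e-9 < 0.05/1000

    def test_run_scan_end_to_end_recovers_signal_region(self):
        cfg = rv.SimulationConfig(
            n_cases=150, n_controls=600, n_genes=200, enrichment_or=3.0,
            enrichment_loeuf_max=0.6, baseline_carrier_rate=(0.01, 0.012, 0.015),
            seed=61,
        )
        panel = rv.simulate_gene_panel(cfg)
        cohort = rv.simulate_cohort(cfg, panel)
        m = rv.matrix_from_arrays(cohort.genes, cohort.samples, cohort.X_all)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scan = rv.run_scan(m, panel, n_permutations=200, seed=62)
            t, emp, _ = rv.optimal_threshold(scan)
        assert (scan.empirical_p >= 1 / 201).all()
        assert np.all(np.diff(scan.set_sizes) >= 0)
        assert abs(t - 0.6) < 0.25  # optimum lands in the enriched region
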