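import numpy as np
import pytest

import canes
from canes.nulls import _westfall_young_adjust


class TestStandardize:
    def test_hand_worked_example(self):
        null = canes.NullDistribution(
            dataset_id="d", measure="auc", m=1, n=3,
            values=np.array([0.4, 0.5, 0.6]), seed=0,
        )
        res = canes.standardize(0.55, null, mode="as_printed")
        assert null.mean == pytest.approx(0.5)
        assert null.sd == pytest.approx(0.1)
        assert res.z == pytest.approx(0.5)
        assert res.p == pytest.approx(1 / 3)

    def test_observation_at_null_mean_has_zero_z(self):
        null = canes.NullDistribution("d", "auc", 1, 5,
                                      np.array([0.3, 0.4, 0.5, 0.6, 0.7]), 0)
        assert canes.standardize(0.5, null).z == pytest.approx(0.0)

    def test_counting_rule_boundaries(self):
        values = np.linspace(0.01, 0.99, 999)
        assert canes.empirical_p(1.5, values, mode="as_printed") == 0.0
        assert canes.empirical_p(1.5, values, mode="add_one") == pytest.approx(1 / 1000)
        # ties count against the observed set
        assert canes.empirical_p(0.99, values, mode="as_printed") == pytest.approx(1 / 999)

    def test_z_invariant_to_joint_affine_transform(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0.6, 0.05, size=50)
        null = canes.NullDistribution("d", "ba", 2, 50, values, 0)
        z0 = canes.standardize(0.8, null).z
        null2 = canes.NullDistribution("d", "ba", 2, 50, 3 * values - 1, 0)
        z1 = canes.standardize(3 * 0.8 - 1, null2).z
        assert z1 == pytest.approx(z0, abs=1e-9)


class TestBuildNull:
    def test_same_seed_reproduces_values_exactly(self, cldn_ds, svm_only):
        a = canes.build_null(cldn_ds, m=2, n=19, classifiers=svm_only, seed=42)
        b = canes.build_null(cldn_ds, m=2, n=19, classifiers=svm_only, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_m_equal_to_probe_count_is_degenerate(self, svm_only):
        ds = canes.generate_dataset(5, 5, 6, seed=3)
        null = canes.build_null(ds, m=6, n=19, classifiers=svm_only, seed=1)
        # every draw uses the same 6 probes (order may vary) -> degenerate null
        assert null.sd <= 1e-12

    def test_m_beyond_probe_count_is_error(self, cldn_ds, svm_only):
        with pytest.raises(canes.CanesError):
            canes.build_null(cldn_ds, m=500, n=19, classifiers=svm_only, seed=1)

    def test_disk_cache_roundtrip(self, cldn_ds, svm_only, tmp_path):
        a = canes.build_null(cldn_ds, m=1, n=19, classifiers=svm_only, seed=7,
                             cache_dir=tmp_path)
        assert len(list(tmp_path.glob("null_*.json"))) == 1
        b = canes.build_null(cldn_ds, m=1, n=19, classifiers=svm_only, seed=7,
                             cache_dir=tmp_path)
        np.testing.assert_array_equal(a.values, b.values)


class TestInfluence:
    def test_duplicated_probe_has_negligible_influence(self, cldn_ds, svm_only):
        # querying the same probe under two identifiers duplicates the feature
        inf = canes.influence(
            cldn_ds, ["CLDN18", "p_0002", "CLDN1"], "p_0002", classifiers=svm_only
        )
        assert abs(inf) < 0.05

    def test_informative_marker_outranks_noise(self, svm_only):
        wins = 0
        for rep in range(5):
            ds = canes.generate_dataset(15, 15, 40, informative=[(0, 2.5)],
                                        seed=200 + rep)
            info = canes.influence(ds, ["p_0000", "p_0001"], "p_0000",
                                   classifiers=svm_only)
            noise = canes.influence(ds, ["p_0000", "p_0001"], "p_0001",
                                    classifiers=svm_only)
            wins += info > noise
        assert wins >= 4

    def test_single_marker_panel_is_error(self, cldn_ds, svm_only):
        with pytest.raises(canes.CanesError):
            canes.influence(cldn_ds, ["CLDN18"], "CLDN18", classifiers=svm_only)


class TestSubsetSearch:
    def test_three_marker_panel_yields_seven_subsets(self, cldn_ds, svm_only):
        results = canes.subset_search(
            cldn_ds, ["CLDN1", "CLDN4", "CLDN18"], n_null=19,
            classifiers=svm_only, seed=3,
        )
        assert len(results) == 7
        for r in results:
            for m in ("ba", "auc"):
                assert r.adj_p[m] >= r.raw_p[m] - 1e-12
                assert r.adj_p[m] <= 1.0

    def test_singleton_family_adjusted_equals_raw(self, cldn_ds, svm_only):
        results = canes.subset_search(cldn_ds, ["CLDN18"], n_null=49,
                                      classifiers=svm_only, seed=4)
        (r,) = results
        for m in ("ba", "auc"):
            assert r.adj_p[m] == pytest.approx(r.raw_p[m], abs=1e-12)

    def test_full_panel_subset_reproduces_standardize_raw_p(self, cldn_ds, svm_only):
        # the singleton family's raw p must equal the standalone pipeline's
        # empirical p for the same seed and null size
        results = canes.subset_search(cldn_ds, ["CLDN18"], n_null=49,
                                      classifiers=svm_only, seed=11)
        direct = canes.evaluate_with_null(cldn_ds, ["CLDN18"], measure="ba",
                                          n=49, classifiers=svm_only, seed=11)
        assert results[0].raw_p["ba"] == pytest.approx(direct.p, abs=1e-12)

    def test_oversized_panel_refused(self, cldn_ds, svm_only):
        names = [f"p_{i:04d}" for i in range(13)]
        with pytest.raises(canes.CanesError, match="cap"):
            canes.subset_search(cldn_ds, names, n_null=19, classifiers=svm_only)

    def test_label_permutation_unit_runs_and_keeps_monotonicity(self, svm_only):
        ds = canes.generate_dataset(8, 8, 30, informative=[(0, 2.0)], seed=21)
        results = canes.subset_search(ds, ["p_0000", "p_0001"], n_null=19,
                                      classifiers=svm_only, seed=2,
                                      wy_unit="label_permutation")
        assert len(results) == 3
        for r in results:
            assert r.adj_p["ba"] >= r.raw_p["ba"] - 1e-12


class TestWestfallYoungCore:
    def test_adjustment_monotone_in_raw_order(self):
        rng = np.random.default_rng(8)
        t_obs = rng.uniform(0.4, 0.9, size=6)
        null_cols = rng.uniform(0.3, 0.8, size=(200, 6))
        raw, adj = _westfall_young_adjust(t_obs, null_cols, mode="add_one")
        order = np.argsort(raw)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= raw - 1e-12).all()
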