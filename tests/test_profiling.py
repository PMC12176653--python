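"""Feature matrices, embedding/clustering, densities, shifts, drugs."""

import numpy as np
import pytest

from morphomap.morphometry.measure import MorphometricRecord
from morphomap.profiling import (
    choose_k_elbow, cluster, density_overlay, drug_response_summary, embed,
    extract_features_classical, jensen_shannon_divergence, occupancy_shift,
)
from morphomap.profiling.drugs import curve_auc, curve_gi50
from morphomap.synth import generate_dose_response


class TestFeatures:
    def test_identical_records_flagged_zero_variance(self):
        recs = [MorphometricRecord(major_axis_um=100, n_components=1)] * 5
        with pytest.warns(UserWarning, match="zero-variance"):
            fm = extract_features_classical(recs)
        assert np.allclose(fm.values, 0.0)
        assert fm.zero_variance  # every feature is constant

    def test_feature_count_matches_names(self):
        recs = [MorphometricRecord(major_axis_um=v, n_components=1)
                for v in (50, 150, 300)]
        fm = extract_features_classical(recs)
        assert fm.values.shape[1] == len(fm.feature_names)

    def test_missing_record_raises(self):
        with pytest.raises(ValueError, match="organoid 1"):
            extract_features_classical([MorphometricRecord(), None])


class TestEmbedCluster:
    @staticmethod
    def _blobs(seed=0, n=120, centers=((0, 0), (12, 0), (0, 12))):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(size=(n // len(centers), 2)) + c
                       for c in centers])
        y = np.repeat(np.arange(len(centers)), n // len(centers))
        return X, y

    def test_embed_too_few_samples_for_perplexity(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        with pytest.raises(ValueError, match="needs >"):
            embed(X, perplexity=30)

    def test_duplicate_rows_stay_coincident(self):
        X, _ = self._blobs(n=120)
        X[1] = X[0]
        emb = embed(X, pca_dims=2, perplexity=10, seed=0)
        diam = np.ptp(emb.coords, axis=0).max()
        d01 = np.linalg.norm(emb.coords[0] - emb.coords[1])
        assert d01 < 0.01 * diam

    def test_embedding_deterministic(self):
        X, _ = self._blobs(n=120)
        a = embed(X, perplexity=10, seed=3).coords
        b = embed(X, perplexity=10, seed=3).coords
        assert np.array_equal(a, b)

    def test_cluster_structure_survives_embedding(self):
        from sklearn.metrics import adjusted_rand_score

        X, y = self._blobs(n=150)
        emb = embed(X, pca_dims=2, perplexity=10, seed=0)
        ca = cluster(emb.coords, 3, seed=0)
        assert adjusted_rand_score(y, ca.labels) == 1.0

    def test_elbow_three_blobs(self):
        X, _ = self._blobs(n=300)
        k, curve = choose_k_elbow(X, k_max=10, seed=0)
        assert k == 3
        assert list(curve) == list(range(1, 11))

    def test_elbow_single_blob(self):
        X = np.random.default_rng(1).normal(size=(300, 2))
        k, _ = choose_k_elbow(X, k_max=10, seed=0)
        assert k <= 2

    def test_kmeans_trivial_cases(self):
        X, _ = self._blobs(n=90)
        one = cluster(X, 1, seed=0)
        assert one.k == 1 and set(one.labels) == {0}
        assert one.inertia == pytest.approx(((X - X.mean(0)) ** 2).sum())
        masses = np.repeat([[0.0, 0.0], [5.0, 5.0]], 10, axis=0)
        two = cluster(masses, 2, seed=0)
        assert two.inertia == pytest.approx(0.0)
        assert len(set(two.labels)) == 2


class TestDensity:
    def test_integrals_one(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(100, 2))
        maps = density_overlay(coords, np.repeat(["a", "b"], 50))
        for m in maps.values():
            assert m.integral() == pytest.approx(1.0, abs=1e-6)

    def test_tight_group_mass_near_centroid(self):
        rng = np.random.default_rng(1)
        tight = rng.normal(scale=0.05, size=(50, 2))
        wide = rng.normal(scale=3.0, size=(50, 2)) + 10
        coords = np.vstack([tight, wide])
        maps = density_overlay(coords, np.repeat(["t", "w"], 50), grid=200)
        m = maps["t"]
        XX, YY = np.meshgrid(m.xs, m.ys)
        c = tight.mean(0)
        within = np.hypot(XX - c[0], YY - c[1]) <= 3 * max(m.bandwidth, 0.05)
        dx, dy = m.xs[1] - m.xs[0], m.ys[1] - m.ys[0]
        assert (m.density[within].sum() * dx * dy) >= 0.95

    def test_disjoint_groups_have_distinct_modes(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(40, 2))
        b = rng.normal(size=(40, 2)) + 20
        maps = density_overlay(np.vstack([a, b]), np.repeat(["a", "b"], 40))
        assert np.argmax(maps["a"].density) != np.argmax(maps["b"].density)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            density_overlay(np.zeros((3, 2)), ["a", "a", "b"])


class TestOccupancyShift:
    def test_identical_composition(self):
        ph = ["A"] * 50 + ["B"] * 50 + ["A"] * 50 + ["B"] * 50
        cond = ["ctrl"] * 100 + ["treat"] * 100
        s = occupancy_shift(ph, cond)
        assert s.jsd_vs_control["treat"] == pytest.approx(0.0, abs=1e-12)
        assert s.chi2_statistic == pytest.approx(0.0)
        assert s.chi2_p_value == pytest.approx(1.0)

    def test_hand_computed_jsd(self):
        """ctrl {A:50, B:50} vs treated {A:100, B:0}: JSD(base 2) of
        (0.5, 0.5) vs (1, 0) is 0.5*KL(p||m) + 0.5*KL(q||m) with
        m = (0.75, 0.25), computed by hand = 0.311278..."""
        expected = 0.5 * (0.5 * np.log2(0.5 / 0.75) + 0.5 * np.log2(0.5 / 0.25)) \
            + 0.5 * (1.0 * np.log2(1.0 / 0.75))
        ph = ["A"] * 50 + ["B"] * 50 + ["A"] * 100
        cond = ["ctrl"] * 100 + ["treat"] * 100
        s = occupancy_shift(ph, cond, control="ctrl")
        assert s.jsd_vs_control["treat"] == pytest.approx(expected, abs=1e-12)
        assert s.percentages.loc["treat", "A"] == pytest.approx(100.0)
        assert s.percentages.loc["treat", "B"] == pytest.approx(0.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(3)
        ph = rng.choice(list("ABCD"), size=200)
        cond = np.repeat(["c", "t"], 100)
        s = occupancy_shift(ph, cond)
        assert np.allclose(s.percentages.sum(axis=1), 100.0, atol=1e-9)

    def test_removing_a_phenotype_strictly_increases_jsd(self):
        rng = np.random.default_rng(4)
        base = list(rng.choice(list("ABC"), size=300, p=[0.4, 0.4, 0.2]))
        mild = base[:150]
        strong = [p for p in base[:150] if p != "C"]
        s1 = occupancy_shift(base + mild,
                             ["ctrl"] * 300 + ["t"] * len(mild))
        s2 = occupancy_shift(base + strong,
                             ["ctrl"] * 300 + ["t"] * len(strong))
        assert s2.jsd_vs_control["t"] > s1.jsd_vs_control["t"] >= 0

    def test_jsd_bounds(self):
        assert jensen_shannon_divergence([1, 0], [0, 1]) == pytest.approx(1.0)
        assert jensen_shannon_divergence([2, 2], [5, 5]) == pytest.approx(0.0)


class TestDrugs:
    def test_constant_viability(self):
        c = np.logspace(-2, 1, 7)
        assert curve_auc(c, np.ones(7)) == pytest.approx(1.0)
        gi, censored = curve_gi50(c, np.ones(7))
        assert censored and gi == pytest.approx(c[-1])

    def test_sigmoid_gi50_interpolation(self):
        curve = generate_dose_response(gi50=0.37037037, hill=1.0, floor=0.0)
        gi, censored = curve_gi50(curve.concentrations, curve.viability)
        assert not censored
        assert gi == pytest.approx(curve.true_gi50, rel=0.10)

    def test_two_clone_zscores(self):
        c = np.logspace(-2, 1, 7)
        flat = lambda level: (c, np.full(7, level))
        summary = drug_response_summary({
            ("d", "c1"): flat(0.2), ("d", "c2"): flat(0.8),
        })
        assert summary.zscore.loc["d", "c1"] == pytest.approx(-1.0)
        assert summary.zscore.loc["d", "c2"] == pytest.approx(1.0)

    def test_zscore_rows_standardized(self):
        rng = np.random.default_rng(5)
        c = np.logspace(-2, 1, 7)
        curves = {
            ("d1", f"c{i}"): (c, np.clip(rng.uniform(0.1, 1.0) /
                                         (1 + c / rng.uniform(0.1, 5)), 0, 1.2))
            for i in range(5)
        }
        s = drug_response_summary(curves)
        row = s.zscore.loc["d1"].to_numpy()
        assert np.mean(row) == pytest.approx(0.0, abs=1e-12)
        assert np.std(row) == pytest.approx(1.0)

    def test_short_curve_skipped(self):
        with pytest.warns(UserWarning, match="skipped"):
            s = drug_response_summary({
                ("d", "c1"): ([1.0], [0.5]),
                ("d", "c2"): (np.logspace(-2, 1, 7), np.ones(7)),
            })
        assert s.skipped == [("d", "c1")]
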