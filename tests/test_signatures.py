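"""NB differential expression, signature derivation and AUC scoring."""

import math

import numpy as np
import pandas as pd
import pytest

from morphomap.signatures import (
    DEResult, SignatureSet, derive_signatures, phenotype_de, score_auc,
    score_matrix, size_factors,
)
from morphomap.synth import generate_count_matrix


def _bh_reference(pvals):
    """Direct step-up Benjamini-Hochberg reference (O(m log m))."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestSizeFactors:
    def test_identical_columns(self):
        df = pd.DataFrame(np.tile([[5], [10], [3]], (1, 4)),
                          columns=list("abcd"))
        assert np.allclose(size_factors(df), 1.0)

    def test_doubled_column_ratio(self):
        base = np.array([[5.0], [10.0], [3.0], [40.0]])
        df = pd.DataFrame(np.hstack([base, 2 * base]), columns=["a", "b"])
        sf = size_factors(df)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_recovers_generator_depths(self):
        ct = generate_count_matrix(n_genes=3000, planted_per_phenotype=0,
                                   depth_range=(0.5, 2.0), seed=4)
        sf = size_factors(ct.counts)
        truth = ct.library_size_factors
        sf_n = sf / np.exp(np.log(sf).mean())
        tr_n = truth / np.exp(np.log(truth).mean())
        assert np.max(np.abs(sf_n / tr_n - 1)) < 0.05

    def test_all_zero_sample_rejected(self):
        df = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="b"):
            size_factors(df)


@pytest.fixture(scope="module")
def planted():
    return generate_count_matrix(
        n_genes=600, planted_per_phenotype=25, log2fc=3.0,
        dispersion=0.1, seed=6)


class TestPhenotypeDE:

    def test_planted_genes_recovered(self, planted):
        de = phenotype_de(planted.counts, planted.phenotype_labels, "A")
        hits = set(de.significant())
        truth = set(planted.planted_genes["A"])
        recall = len(hits & truth) / len(truth)
        precision = len(hits & truth) / max(len(hits), 1)
        assert recall >= 0.8 and precision >= 0.9

    def test_swapping_contrast_negates_lfc(self, planted):
        labels = planted.phenotype_labels.copy()
        de_a = phenotype_de(planted.counts, labels, "A")
        merged = labels.replace({"B": "rest", "C": "rest"})
        de_r = phenotype_de(planted.counts, merged, "rest")
        common = de_a.table.index.intersection(de_r.table.index)
        assert np.allclose(
            de_a.table.loc[common, "log2_fold_change"],
            -de_r.table.loc[common, "log2_fold_change"], atol=1e-4)

    def test_all_zero_gene_excluded(self):
        ct = generate_count_matrix(n_genes=200, planted_per_phenotype=5, seed=7)
        counts = ct.counts.copy()
        counts.iloc[0] = 0
        de = phenotype_de(counts, ct.phenotype_labels, "A")
        assert counts.index[0] in de.excluded_genes
        assert counts.index[0] not in de.table.index

    def test_bh_matches_reference(self):
        rng = np.random.default_rng(8)
        p = np.concatenate([rng.uniform(size=300), rng.uniform(0, 1e-3, 20)])
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(p, method="fdr_bh")[1]
        ref = _bh_reference(p)
        assert np.allclose(adj, ref)
        assert np.all(np.diff(ref[np.argsort(p)]) >= -1e-15)  # monotone

    def test_padj_not_smaller_than_p(self):
        ct = generate_count_matrix(n_genes=300, planted_per_phenotype=10, seed=9)
        de = phenotype_de(ct.counts, ct.phenotype_labels, "B")
        t = de.table
        assert np.all(t["p_adjusted"] >= t["p_value"] - 1e-15)


class TestDeriveSignatures:
    @staticmethod
    def _fake_de(sig_genes, universe):
        lfc = pd.Series(0.0, index=universe)
        p = pd.Series(0.9, index=universe)
        lfc[sig_genes] = 3.0
        p[sig_genes] = 1e-6
        table = pd.DataFrame({
            "log2_fold_change": lfc, "wald_statistic": 0.0,
            "p_value": p, "p_adjusted": p,
        })
        return DEResult(table, "x vs rest", pd.Series(dtype=float))

    def test_shared_gene_removed_from_both(self):
        uni = [f"g{i}" for i in range(10)]
        des = {
            "A": self._fake_de(["g0", "g1", "g2"], uni),
            "B": self._fake_de(["g2", "g3"], uni),
        }
        sigs = derive_signatures(des)
        assert "g2" not in sigs.signatures["A"]
        assert "g2" not in sigs.signatures["B"]
        assert sigs.removed_shared["A"] == ["g2"]

    def test_no_gene_passing_gives_empty_valid_set(self):
        uni = [f"g{i}" for i in range(5)]
        des = {"A": self._fake_de([], uni), "B": self._fake_de([], uni)}
        with pytest.warns(UserWarning, match="empty"):
            sigs = derive_signatures(des)
        assert sigs.signatures == {"A": [], "B": []}

    def test_gmt_roundtrip(self, tmp_path):
        uni = [f"g{i}" for i in range(6)]
        des = {"A": self._fake_de(["g0"], uni), "B": self._fake_de(["g5"], uni)}
        sigs = derive_signatures(des)
        path = tmp_path / "sigs.gmt"
        sigs.to_gmt(path)
        back = SignatureSet.from_gmt(path)
        assert back.signatures == sigs.signatures


class TestScoreAUC:
    def test_signature_on_top_scores_one(self):
        genes = [f"g{i}" for i in range(100)]
        expr = pd.Series(np.arange(100, 0, -1), index=genes, dtype=float)
        assert score_auc(expr, genes[:4], top_fraction=0.1) == pytest.approx(1.0)

    def test_signature_outside_window_scores_zero(self):
        genes = [f"g{i}" for i in range(100)]
        expr = pd.Series(np.arange(100, 0, -1), index=genes, dtype=float)
        assert score_auc(expr, genes[-5:], top_fraction=0.05) == 0.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(500)]
        expr = pd.Series(rng.uniform(1, 9, size=500), index=genes)
        sig = list(rng.choice(genes, 30, replace=False))
        s1 = score_auc(expr, sig, 0.1)
        s2 = score_auc(np.log(expr) ** 3, sig, 0.1)
        assert s1 == pytest.approx(s2)

    def test_random_expectation_matches_permutation_oracle(self):
        """Mean score of random expression profiles agrees with the
        brute-force expectation over random permutations of gene ranks."""
        rng = np.random.default_rng(11)
        G, S, tau, n_rep = 800, 40, 0.05, 400
        genes = [f"g{i}" for i in range(G)]
        sig = genes[:S]
        T = math.ceil(tau * G)
        max_area = np.minimum(np.arange(1, T + 1), S).sum()
        # oracle: simulate pure rank permutations directly
        oracle = []
        for _ in range(n_rep):
            pos = rng.permutation(G)[:S]  # ranks occupied by signature genes
            hits = np.zeros(T)
            inwin = pos[pos < T]
            for p in inwin:
                hits[p:] += 1
            oracle.append(hits.sum() / max_area)
        oracle = np.array(oracle)
        scores = [
            score_auc(pd.Series(rng.normal(size=G), index=genes), sig, tau)
            for _ in range(n_rep)
        ]
        se = oracle.std() * math.sqrt(2.0 / n_rep)
        assert abs(np.mean(scores) - oracle.mean()) < 3 * se

    def test_disjoint_universe_flagged(self):
        expr = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="intersect"):
            score_auc(expr, ["zzz"], 0.5)


def test_full_recovery_loop():
    """counts -> DE -> signatures -> scores: each phenotype scores higher
    in its own samples than anywhere else."""
    ct = generate_count_matrix(n_genes=600, planted_per_phenotype=25,
                               log2fc=3.0, dispersion=0.1, seed=12)
    des = {ph: phenotype_de(ct.counts, ct.phenotype_labels, ph)
           for ph in ("A", "B", "C")}
    sigs = derive_signatures(des)
    scores = score_matrix(np.log1p(ct.counts), sigs, top_fraction=0.05)
    for ph in ("A", "B", "C"):
        own = scores.loc[ct.phenotype_labels == ph, ph].mean()
        other = scores.loc[ct.phenotype_labels != ph, ph].mean()
        assert own > other
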