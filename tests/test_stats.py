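import itertools

import numpy as np
import pytest

from invadepop.io_formats import MISSING, PopulationMap
from invadepop.stats import (amova, amova_percentages, nucleotide_diversity,
                             pairwise_fst, pca_coordinates, wc_theta)

from conftest import toy_matrix


# ---------------------------------------------------------------------------
# independent Weir & Cockerham (1984) oracle: textbook scalar formulas
# ---------------------------------------------------------------------------

def wc_theta_oracle(geno, groups):
    """Scalar-loop multi-locus theta; geno is dosage (sites x individuals)."""
    A = B = C = 0.0
    r = len(groups)
    for s in range(geno.shape[0]):
        n, p, h = [], [], []
        skip = False
        for cols in groups:
            g = [geno[s, c] for c in cols if geno[s, c] != MISSING]
            if len(g) < 1:
                skip = True
                break
            n.append(len(g))
            p.append(sum(g) / (2.0 * len(g)))
            h.append(sum(1 for x in g if x == 1) / len(g))
        if skip or min(n) < 1:
            continue
        nbar = sum(n) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        if not all(np.isfinite([a, b, c])):
            continue
        A += a
        B += b
        C += c
    return A / (A + B + C)


class TestPairwiseFst:
    def test_fixed_alternative_alleles_give_one(self, two_pop_map):
        g = np.array([[0, 0, 2, 2]] * 5, dtype=np.int8)
        gm = toy_matrix(g)
        pm = two_pop_map(gm, 2)
        fm = pairwise_fst(gm, pm, n_perm=0)
        assert fm.theta[0, 1] == pytest.approx(1.0)

    def test_duplicated_population_near_zero(self):
        rng = np.random.default_rng(2)
        freqs = rng.uniform(0.1, 0.9, size=80)
        half = (rng.random((80, 20, 2)) < freqs[:, None, None]).sum(axis=2).astype(np.int8)
        g = np.hstack([half, half])
        gm = toy_matrix(g)
        pm = PopulationMap(assignments={
            ind: ("L" if k < 20 else "R") for k, ind in enumerate(gm.individual_ids)})
        fm = pairwise_fst(gm, pm, n_perm=99, seed=4)
        assert abs(fm.theta[0, 1]) < 0.05  # may be slightly negative
        assert fm.p_values[0, 1] > 0.2

    def test_eight_diploid_hand_table_matches_oracle(self, two_pop_map):
        g = np.array([
            [0, 1, 2, 1, 0, 0, 1, 2],
            [2, 2, 1, 0, 0, 1, 0, 0],
        ], dtype=np.int8)
        gm = toy_matrix(g)
        pm = two_pop_map(gm, 4)
        fm = pairwise_fst(gm, pm, n_perm=0)
        groups = [list(range(4)), list(range(4, 8))]
        assert fm.theta[0, 1] == pytest.approx(wc_theta_oracle(g, groups), abs=1e-10)

    def test_oracle_agreement_random_tables(self, two_pop_map):
        rng = np.random.default_rng(31)
        for _ in range(5):
            g = rng.integers(0, 3, size=(12, 10)).astype(np.int8)
            gm = toy_matrix(g)
            pm = two_pop_map(gm, 5)
            fm = pairwise_fst(gm, pm, n_perm=0)
            oracle = wc_theta_oracle(g, [list(range(5)), list(range(5, 10))])
            assert fm.theta[0, 1] == pytest.approx(oracle, abs=1e-10)

    def test_invariant_to_individual_order_and_allele_swap(self, two_pop_map):
        rng = np.random.default_rng(7)
        g = rng.integers(0, 3, size=(25, 8)).astype(np.int8)
        base = wc_theta(g, [np.arange(4), np.arange(4, 8)])
        perm_within = np.concatenate([rng.permutation(4), 4 + rng.permutation(4)])
        assert wc_theta(g[:, perm_within], [np.arange(4), np.arange(4, 8)]) == pytest.approx(base, abs=1e-12)
        assert wc_theta((2 - g).astype(np.int8), [np.arange(4), np.arange(4, 8)]) == pytest.approx(base, abs=1e-12)

    def test_small_population_rejected(self):
        gm = toy_matrix(np.zeros((3, 3), dtype=np.int8))
        pm = PopulationMap(assignments={"i0": "A", "i1": "A", "i2": "B"})
        with pytest.raises(ValueError):
            pairwise_fst(gm, pm, n_perm=0)

    def test_permutation_pvalue_range(self, two_pop_map):
        g = np.array([[0, 0, 2, 2]] * 3, dtype=np.int8)
        gm = toy_matrix(g)
        pm = two_pop_map(gm, 2)
        n_perm = 49
        fm = pairwise_fst(gm, pm, n_perm=n_perm, seed=1)
        assert 1 / (n_perm + 1) <= fm.p_values[0, 1] <= 1.0


class TestNucleotideDiversity:
    def test_all_identical_is_zero(self):
        gm = toy_matrix(np.full((4, 5), 2, dtype=np.int8))
        pm = PopulationMap(assignments={f"i{k}": "P" for k in range(5)})
        pi = nucleotide_diversity(gm, pm, total_length=40)
        assert pi["P"] == 0.0

    def test_matches_average_pairwise_difference_oracle(self):
        # 3 diploids = 6 gene copies over a 10 bp stretch
        g = np.array([[1, 0, 2], [0, 1, 1]], dtype=np.int8)
        gm = toy_matrix(g)
        pm = PopulationMap(assignments={f"i{k}": "P" for k in range(3)})
        # brute force: mean pairwise difference over all copy pairs
        def copies(dosage):
            return (max(dosage - 1, 0), min(dosage, 1))
        copy_mat = np.array([[copies(g[s, j])[c] for s in range(2)]
                             for j in range(3) for c in (0, 1)])
        diffs = [np.sum(copy_mat[a] != copy_mat[b])
                 for a, b in itertools.combinations(range(6), 2)]
        expected = np.mean(diffs) / 10.0
        pi = nucleotide_diversity(gm, pm, total_length=10)
        assert pi["P"] == pytest.approx(expected, rel=1e-12)

    def test_per_variant_when_no_length(self):
        g = np.array([[0, 2]], dtype=np.int8)
        gm = toy_matrix(g)
        pm = PopulationMap(assignments={"i0": "P", "i1": "P"})
        # n=4 copies, alt=2: 4 differing pairs of 6 -> pi = 2/3
        assert nucleotide_diversity(gm, pm)["P"] == pytest.approx(2 / 3)


class TestAmova:
    def test_paper_style_percentage_arithmetic(self):
        pct = amova_percentages(84.26, 6.21, 75.78)
        assert pct[0] == pytest.approx(100 * 84.26 / 166.25, abs=1e-9)
        assert round(pct[0], 2) == 50.68
        assert round(pct[1], 2) == 3.74
        assert round(pct[2], 2) == 45.58
        assert sum(pct) == pytest.approx(100.0, abs=0.01)

    def test_two_groups_fixed_differences_near_100(self):
        g = np.vstack([[0, 0, 0, 0, 2, 2, 2, 2]] * 20).astype(np.int8)
        gm = toy_matrix(g)
        pm = PopulationMap(assignments={
            f"i{k}": f"P{k // 2}" for k in range(8)})
        grouping = {"P0": "G1", "P1": "G1", "P2": "G2", "P3": "G2"}
        res = amova(gm, pm, grouping, n_perm=0)
        assert res.percentages["among_groups"] > 95.0

    def test_panmictic_among_group_near_zero(self):
        rng = np.random.default_rng(12)
        among = []
        for rep in range(4):
            freqs = rng.uniform(0.2, 0.8, size=60)
            g = (rng.random((60, 24, 2)) < freqs[:, None, None]).sum(axis=2).astype(np.int8)
            gm = toy_matrix(g)
            pm = PopulationMap(assignments={
                f"i{k}": f"P{k // 6}" for k in range(24)})
            grouping = {"P0": "G1", "P1": "G1", "P2": "G2", "P3": "G2"}
            res = amova(gm, pm, grouping, n_perm=49, seed=rep)
            among.append(res.percentages["among_groups"])
            assert res.p_values["among_groups"] > 0.05
        assert np.mean(among) < 2.0

    def test_percentages_sum_to_100(self, small_fixture):
        gm, pm, _ = small_fixture
        grouping = {p: ("G1" if p in ("DT", "PY", "NY") else "G2") for p in pm.labels}
        res = amova(gm, pm, grouping, n_perm=0)
        assert sum(res.percentages.values()) == pytest.approx(100.0, abs=0.01)

    def test_missing_group_rejected(self):
        gm = toy_matrix(np.zeros((2, 4), dtype=np.int8))
        pm = PopulationMap(assignments={f"i{k}": f"P{k // 2}" for k in range(4)})
        with pytest.raises(ValueError):
            amova(gm, pm, {"P0": "G1"}, n_perm=0)


class TestPca:
    def test_two_clusters_separate_exactly(self):
        g = np.array([[0] * 4 + [2] * 4] * 10, dtype=np.int8)
        gm = toy_matrix(g)
        scores, explained = pca_coordinates(gm)
        pc1 = scores[:, 0]
        assert np.allclose(pc1[:4], pc1[0])
        assert np.allclose(pc1[4:], pc1[4])
        assert not np.isclose(pc1[0], pc1[4])
        assert explained[0] == pytest.approx(1.0)

    def test_matches_brute_force_eigendecomposition(self):
        rng = np.random.default_rng(41)
        g = rng.integers(0, 3, size=(30, 12)).astype(np.int8)
        gm = toy_matrix(g)
        scores, explained = pca_coordinates(gm)
        # oracle: eigen-decomposition of the individual covariance matrix
        x = g.astype(float).T
        x = x - x.mean(axis=0)
        cov = x @ x.T
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        oracle = vecs * np.sqrt(np.maximum(vals, 0.0))
        for k in range(min(5, scores.shape[1])):
            col = oracle[:, k]
            if col[np.argmax(np.abs(col))] < 0:
                col = -col
            assert np.allclose(scores[:, k], col, atol=1e-8)
        assert np.allclose(explained[:5], (vals / vals.sum())[:5], atol=1e-10)

    def test_explained_fractions_sum_at_most_one(self, small_fixture):
        gm, _, _ = small_fixture
        _, explained = pca_coordinates(gm)
        assert explained.sum() <= 1.0 + 1e-9

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            pca_coordinates(toy_matrix(np.zeros((3, 1), dtype=np.int8)))
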