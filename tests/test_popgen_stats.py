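import numpy as np
import pandas as pd
import pytest

from adaptscan import (
    MISSING,
    diversity,
    joint_sfs,
    migration_distance_correlation,
    pairwise_wc_fst,
    pca,
    population_sfs,
    relative_migration,
)
from adaptscan.popgen_stats import MigrationMatrix

from conftest import make_dataset
from oracles import folded_sfs_expectation, nei_oracle, wc_theta_oracle


class TestDiversity:
    def test_alternate_fixation_maximal_differentiation(self):
        g, pm = make_dataset({"A": [[0], [0], [0]], "B": [[2], [2], [2]]})
        d = diversity(g, pm)
        assert d.hs == 0.0
        assert d.ht == pytest.approx(0.5)
        assert d.fst == pytest.approx(1.0)

    def test_identical_hw_populations_null(self):
        # Hardy-Weinberg genotype counts at p=0.5 in both populations
        block = [0] * 50 + [1] * 100 + [2] * 50
        a = np.array(block).reshape(-1, 1)
        g, pm = make_dataset({"A": a, "B": a})
        d = diversity(g, pm)
        # unbiased Hs slightly exceeds Ht in finite samples: fst ~ -1/(2n-1)
        assert d.fst == pytest.approx(0.0, abs=0.01)
        assert d.fis == pytest.approx(0.0, abs=0.01)

    def test_matches_enumeration_oracle(self, two_pop_hand_case):
        g, pm = make_dataset(two_pop_hand_case)
        d = diversity(g, pm)
        exp = nei_oracle(
            {
                pop: [[row[l] for row in rows] for l in range(2)]
                for pop, rows in two_pop_hand_case.items()
            }
        )
        for name in ("ho", "hs", "ht", "fst", "fis"):
            assert getattr(d, name) == pytest.approx(exp[name], abs=1e-10)

    def test_undersampled_population_is_fatal(self):
        g, pm = make_dataset({"A": [[1], [0]], "B": [[MISSING], [1]]})
        with pytest.raises(ValueError, match="B"):
            diversity(g, pm)


class TestPairwiseWcFst:
    def test_alternate_fixation_theta_one(self):
        g, pm = make_dataset({"A": [[0, 0]] * 4, "B": [[2, 2]] * 4})
        per_locus, mean = pairwise_wc_fst(g, pm, "A", "B")
        np.testing.assert_allclose(per_locus, 1.0)
        assert mean == pytest.approx(1.0)

    def test_identical_tables_nonpositive(self):
        block = np.array([0, 1, 1, 2, 0, 1]).reshape(-1, 1)
        g, pm = make_dataset({"A": block, "B": block})
        per_locus, mean = pairwise_wc_fst(g, pm, "A", "B")
        assert mean <= 0.0  # raw estimate, may be negative

    def test_matches_component_oracle(self):
        calls_a = [0, 1, 2, 1, 0, 1]
        calls_b = [2, 2, 1, 2, 2, 1]
        g, pm = make_dataset(
            {"A": np.array(calls_a).reshape(-1, 1),
             "B": np.array(calls_b).reshape(-1, 1)}
        )
        per_locus, mean = pairwise_wc_fst(g, pm, "A", "B")
        exp = wc_theta_oracle(calls_a, calls_b)
        assert per_locus.iloc[0] == pytest.approx(exp, abs=1e-10)
        assert mean == pytest.approx(exp, abs=1e-10)

    def test_monomorphic_pair_is_error(self):
        g, pm = make_dataset({"A": [[0], [0]], "B": [[0], [0]]})
        with pytest.raises(ValueError, match="polymorphic"):
            pairwise_wc_fst(g, pm, "A", "B")


class TestSpectra:
    def test_folded_direct_count(self):
        # 3 loci with minor-allele counts {1, 1, 2} over 4 haplotypes
        a = np.array([[1, 0, 1], [0, 1, 1]])
        g, pm = make_dataset({"A": a, "B": a})
        sfs = population_sfs(g, pm, "A", mode="folded")
        assert list(sfs.index) == [0, 1, 2]
        assert list(sfs) == [0, 2, 1]
        assert sfs.attrs["n_polymorphic"] == 3

    def test_monomorphic_in_class_zero(self):
        a = np.array([[0, 1], [0, 0]])
        g, pm = make_dataset({"A": a, "B": a})
        sfs = population_sfs(g, pm, "A", mode="folded")
        assert sfs[0] == 1
        assert sfs.attrs["n_polymorphic"] == 1

    def test_missing_loci_excluded_and_order_invariant(self):
        a = np.array([[1, MISSING, 1], [0, 1, 1]])
        g, pm = make_dataset({"A": a, "B": a})
        sfs = population_sfs(g, pm, "A")
        assert sfs.attrs["n_loci"] == 2
        perm = g.subset(loci=[2, 0, 1], individuals=[1, 0, 2, 3])
        sfs2 = population_sfs(perm, pm, "A")
        assert list(sfs) == list(sfs2)

    def test_neutral_equilibrium_shape(self):
        # coalescent oracle: folded SFS of a panmictic constant-size sample
        msprime = pytest.importorskip("msprime")
        ts = msprime.sim_ancestry(
            samples=5, population_size=10_000, sequence_length=5e5,
            recombination_rate=1e-8, random_seed=7,
        )
        mts = msprime.sim_mutations(ts, rate=2e-8, random_seed=8)
        geno = mts.genotype_matrix()  # (sites, 10 haplotypes)
        biallelic = geno.max(axis=1) == 1
        dosage = geno[biallelic, 0::2] + geno[biallelic, 1::2]
        g, pm = make_dataset({"A": dosage.T, "B": dosage.T[:1]})
        sfs = population_sfs(g, pm, "A", mode="folded")
        obs = sfs[1:] / sfs[1:].sum()
        exp = folded_sfs_expectation(10)
        assert np.all(np.diff(obs.to_numpy()) <= 0)  # decreasing in class
        np.testing.assert_allclose(obs, exp, atol=0.05)

    def test_joint_sfs_corner_and_diagonal(self):
        a = np.zeros((2, 3), dtype=int)
        b = np.full((2, 3), 2, dtype=int)
        g, pm = make_dataset({"A": a, "B": b})
        grid = joint_sfs(g, pm, "A", "B")
        assert grid.loc[0, 4] == 3  # fixed ref in A, fixed alt in B
        g2, pm2 = make_dataset({"A": [[1, 0], [2, 1]], "B": [[1, 0], [2, 1]]})
        grid2 = joint_sfs(g2, pm2, "A", "B")
        off = grid2.to_numpy() - np.diag(np.diag(grid2.to_numpy()))
        assert off.sum() == 0  # identical groups: all mass on the diagonal


class TestPca:
    def test_two_clusters_pc1(self):
        a = np.tile([0, 0, 2, 2, 0], (4, 1))
        b = np.tile([2, 2, 0, 0, 2], (4, 1))
        g, pm = make_dataset({"A": a, "B": b})
        scores, ev = pca(g, n_axes=3)
        assert ev[0] == pytest.approx(1.0)
        assert np.sign(scores[:4, 0]).tolist() != np.sign(scores[4:, 0]).tolist()

    def test_matches_eigendecomposition(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, (12, 30))
        g, pm = make_dataset({"A": a[:6], "B": a[6:]})
        scores, ev = pca(g, n_axes=5)
        X = a - a.mean(axis=0)
        w, v = np.linalg.eigh(X @ X.T)
        w = w[::-1]
        np.testing.assert_allclose(ev, (w / w.sum())[:5], atol=1e-10)
        exp_scores = X @ X.T @ v[:, ::-1][:, :5] / np.sqrt(w[:5])
        np.testing.assert_allclose(np.abs(scores), np.abs(exp_scores), atol=1e-8)

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 3, (10, 40))
        g, pm = make_dataset({"A": a[:5], "B": a[5:]})
        _, ev = pca(g, n_axes=8)
        assert np.all(np.diff(ev) <= 1e-12)
        assert ev.sum() <= 1 + 1e-9

    def test_constant_matrix_is_error(self):
        g, pm = make_dataset({"A": [[1, 1], [1, 1]], "B": [[1, 1], [1, 1]]})
        with pytest.raises(ValueError):
            pca(g)


class TestRelativeMigration:
    def test_identical_pair_saturates(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 3, (8, 60))
        c = rng.integers(0, 3, (8, 60))
        g, pm = make_dataset({"A": a, "B": a.copy(), "C": c})
        mig = relative_migration(g, pm)
        assert mig.rates.loc["A", "B"] == pytest.approx(1.0)
        assert mig.rates.loc["B", "A"] == pytest.approx(1.0)
        assert mig.rates.loc["A", "C"] < 0.5

    def test_asymmetric_exchange_direction(self):
        # B is an admixture receiving from A; expect rate(A->B) > rate(B->A)
        rng = np.random.default_rng(9)
        n, L = 40, 800
        pA = rng.uniform(0.05, 0.95, L)
        pB0 = rng.uniform(0.05, 0.95, L)
        pC = rng.uniform(0.05, 0.95, L)
        pB = 0.5 * pA + 0.5 * pB0
        g, pm = make_dataset(
            {
                "A": rng.binomial(2, pA, (n, L)),
                "B": rng.binomial(2, pB, (n, L)),
                "C": rng.binomial(2, pC, (n, L)),
            }
        )
        mig = relative_migration(g, pm)
        assert mig.rates.loc["A", "B"] > mig.rates.loc["B", "A"]

    def test_allele_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 3, (10, 50))
        b = rng.integers(0, 3, (10, 50))
        g, pm = make_dataset({"A": a, "B": b})
        flipped, _ = make_dataset({"A": 2 - a, "B": 2 - b})
        m1 = relative_migration(g, pm).rates
        m2 = relative_migration(flipped, pm).rates
        pd.testing.assert_frame_equal(m1, m2)

    def test_monomorphic_is_error(self):
        g, pm = make_dataset({"A": [[0], [0]], "B": [[0], [0]]})
        with pytest.raises(ValueError):
            relative_migration(g, pm)


class TestMigrationDistance:
    def _mig(self, rates):
        return MigrationMatrix(rates=rates)

    def test_linear_decay_perfect_negative(self):
        pops = ["A", "B", "C"]
        d = pd.DataFrame(
            [[0, 10, 20], [10, 0, 30], [20, 30, 0.0]], index=pops, columns=pops
        )
        rates = 1 - d / 40.0
        np.fill_diagonal(rates.values, np.nan)
        r, p = migration_distance_correlation(self._mig(rates), d)
        assert r == pytest.approx(-1.0)

    def test_permuted_distances_null(self):
        rng = np.random.default_rng(6)
        pops = [f"P{i}" for i in range(8)]
        rates = pd.DataFrame(rng.random((8, 8)), index=pops, columns=pops)
        np.fill_diagonal(rates.values, np.nan)
        d = pd.DataFrame(rng.random((8, 8)) * 100, index=pops, columns=pops)
        r, p = migration_distance_correlation(self._mig(rates), d)
        assert abs(r) < 0.5
        assert p > 0.001

    def test_too_few_pairs_is_error(self):
        pops = ["A", "B"]
        rates = pd.DataFrame([[np.nan, 1], [1, np.nan]], index=pops, columns=pops)
        d = pd.DataFrame([[0, 5], [5, 0.0]], index=pops, columns=pops)
        with pytest.raises(ValueError):
            migration_distance_correlation(self._mig(rates), d)
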