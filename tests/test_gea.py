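import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adaptscan import (
    MISSING,
    broad_sense_combine,
    impute_modal,
    ingest_external_gea,
    make_random_env,
    preprocess_env,
    rda_associations,
    rda_full_model_test,
)
from adaptscan.synthetic_data import SimConfig, simulate

from conftest import make_dataset


def _env(values: dict, pops) -> pd.DataFrame:
    return pd.DataFrame(values, index=pd.Index(pops, name="population"))


class TestPreprocessEnv:
    def test_perfectly_correlated_second_dropped(self):
        v = np.arange(8.0)
        env = _env({"a": v, "b": 2 * v + 3}, [f"P{i}" for i in range(8)])
        out, dropped = preprocess_env(env)
        assert list(out.columns) == ["a"]
        assert dropped == ["b"]
        np.testing.assert_allclose(out["a"].mean(), 0, atol=1e-12)
        np.testing.assert_allclose(out["a"].std(ddof=1), 1, atol=1e-12)

    def test_r2_exactly_point7_kept(self):
        # construct exact r^2 = 0.7 via orthonormal components
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20)
        w = rng.standard_normal(20)
        x = (x - x.mean()) / np.linalg.norm(x - x.mean())
        w = w - w.mean()
        w -= (w @ x) * x
        w /= np.linalg.norm(w)
        y = np.sqrt(0.7) * x + np.sqrt(0.3) * w
        env = _env({"a": x, "b": y}, [f"P{i}" for i in range(20)])
        out, dropped = preprocess_env(env, r2_max=0.7)
        assert list(out.columns) == ["a", "b"]  # inclusive threshold
        assert dropped == []

    def test_orthogonal_all_kept_and_priority(self):
        rng = np.random.default_rng(2)
        env = _env(
            {k: rng.standard_normal(12) for k in ("a", "b", "c")},
            [f"P{i}" for i in range(12)],
        )
        out, dropped = preprocess_env(env, priority=["c", "a", "b"])
        assert list(out.columns) == ["c", "a", "b"]
        assert dropped == []

    def test_constant_variable_is_error(self):
        env = _env({"a": np.arange(5.0), "flat": np.ones(5)}, list("PQRST"))
        with pytest.raises(ValueError, match="flat"):
            preprocess_env(env)


class TestImputeModal:
    def test_mode_within_group(self):
        a = np.array([[0], [0], [1], [MISSING]])
        g, pm = make_dataset({"A": a}, groups={"A": "N"})
        out = impute_modal(g, pm)
        assert out.genotypes[3, 0] == 0

    def test_tie_breaks_to_lower_dosage(self):
        a = np.array([[0], [0], [1], [1], [MISSING]])
        g, pm = make_dataset({"A": a})
        out = impute_modal(g, pm)
        assert out.genotypes[4, 0] == 0

    def test_complete_matrix_unchanged(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 3, (6, 8))
        g, pm = make_dataset({"A": a[:3], "B": a[3:]})
        out = impute_modal(g, pm)
        np.testing.assert_array_equal(out.genotypes, g.genotypes)

    def test_group_without_calls_is_error(self):
        a = np.array([[MISSING], [MISSING]])
        b = np.array([[1], [0]])
        g, pm = make_dataset({"A": a, "B": b})
        with pytest.raises(ValueError, match="drop_population_missing_loci"):
            impute_modal(g, pm)


class TestRandomEnv:
    def test_count_and_names(self):
        env = make_random_env([f"P{i}" for i in range(9)], count=100, seed=0)
        assert env.shape == (9, 100)
        assert env.columns[0] == "ranvar_001"
        assert set(env.attrs["provenance"].values()) == {"random"}

    def test_moments_for_many_populations(self):
        env = make_random_env([f"P{i}" for i in range(400)], count=20, seed=1)
        assert np.abs(env.mean()).max() < 0.2
        assert np.abs(env.std(ddof=1) - 1).max() < 0.2

    def test_seed_reproducibility(self):
        pops = list("ABCDE")
        e1 = make_random_env(pops, 10, seed=5)
        e2 = make_random_env(pops, 10, seed=5)
        e3 = make_random_env(pops, 10, seed=6)
        pd.testing.assert_frame_equal(e1, e2)
        assert not np.allclose(e1.to_numpy(), e3.to_numpy())


def _southern_sim(seed=0, n_loci=400, effect=3.0, prop=0.05, f_pop=0.1):
    return simulate(
        SimConfig(n_groups=1, pops_per_group=8, inds_per_pop=8, n_loci=n_loci,
                  prop_adaptive=prop, f_group=0.01, f_pop=f_pop,
                  effect_b=effect, missing_rate=0.0, seed=seed)
    )


class TestRdaFullModel:
    def test_planted_gradient_minimum_p(self):
        g, pm, env, _ = _southern_sim(seed=1, effect=3.0, prop=0.2)
        env2, _ = preprocess_env(env[["latitude"]])
        f, p = rda_full_model_test(g, env2, pm, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)
        assert f > 1

    def test_null_f_moderate_and_seeded(self):
        # exchangeable null: negligible drift so population blocks carry no
        # signal a random population-level variable could pick up
        g, pm, env, _ = _southern_sim(seed=2, prop=0.0, f_pop=0.01)
        ran = make_random_env(env.index, count=1, seed=9)
        f1, p1 = rda_full_model_test(g, ran, pm, n_perm=99, seed=3)
        f2, p2 = rda_full_model_test(g, ran, pm, n_perm=99, seed=3)
        assert (f1, p1) == (f2, p2)
        assert p1 > 0.01  # env orthogonal to genotype variation

    def test_rank_deficient_design_is_error(self):
        g, pm, env, _ = _southern_sim(seed=3)
        bad = env[["latitude"]].copy()
        bad["lat2"] = bad["latitude"] * 2.0
        with pytest.raises(ValueError, match="rank"):
            rda_full_model_test(g, bad, pm, n_perm=9, seed=0)


class TestRdaAssociations:
    def test_planted_clinal_locus_attains_max_z(self):
        g, pm, env, _ = _southern_sim(seed=4, n_loci=300, prop=0.0)
        # plant a locus whose dosage is an exact linear function of latitude
        lat = env["latitude"]
        ranks = lat.rank().astype(int) - 1
        dosage_of_pop = {p: (0 if r < 3 else (1 if r < 5 else 2))
                         for p, r in ranks.items()}
        geno = g.genotypes.copy()
        geno[:, 0] = [dosage_of_pop[pm.population_of(i)] for i in g.individual_ids]
        g2 = type(g)(geno, g.locus_ids, g.tag_ids, g.individual_ids)
        env2, _ = preprocess_env(env[["latitude"]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = rda_associations(g2, env2, pm)
        top = table.loc[table["z"].abs().idxmax()]
        assert top["locus_id"] == "locus_000000"

    def test_null_p_values_uniform(self):
        pvals = []
        for seed in (5, 6):
            g, pm, env, _ = _southern_sim(seed=seed, n_loci=1500, prop=0.0,
                                          f_pop=0.01)
            ran = make_random_env(env.index, count=1, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = rda_associations(g, ran, pm)
            ks = stats.kstest(table["p_value"], "uniform")
            pvals.append(ks.pvalue)
        assert min(pvals) > 0.01

    def test_sign_flip_equivariance(self):
        g, pm, env, _ = _southern_sim(seed=7, n_loci=200)
        env2 = env[["latitude"]].copy()
        env2["env_1"] = make_random_env(env.index, 1, seed=11)["ranvar_001"]
        env2, _ = preprocess_env(env2)
        flipped = env2.copy()
        flipped["env_1"] = -flipped["env_1"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t1 = rda_associations(g, env2, pm)
            t2 = rda_associations(g, flipped, pm)
        z1 = t1[t1.variable == "env_1"]["z"].abs().to_numpy()
        z2 = t2[t2.variable == "env_1"]["z"].abs().to_numpy()
        np.testing.assert_allclose(z1, z2, atol=1e-8)


class TestIngestExternalGea:
    def _write(self, tmp_path, text):
        path = tmp_path / "gea.tsv"
        path.write_text("locus_id\tvariable\tq_value\n" + text)
        return str(path)

    def test_parse_round_trip(self, tmp_path):
        rows = "".join(
            f"L{i}\t{v}\t0.{i + 1}\n" for i in range(3) for v in ("lat", "sst")
        )
        table = ingest_external_gea(self._write(tmp_path, rows), "bayes")
        assert len(table) == 6
        assert set(table["variable"]) == {"lat", "sst"}
        assert (table["method"] == "bayes").all()

    def test_unknown_variable_warns(self, tmp_path):
        rows = "L0\tlat\t0.5\nL0\tmystery\t0.5\n"
        with pytest.warns(UserWarning, match="mystery"):
            table = ingest_external_gea(
                self._write(tmp_path, rows), "bayes", variables=["lat"]
            )
        assert set(table["variable"]) == {"lat"}

    def test_malformed_q_fatal(self, tmp_path):
        with pytest.raises(ValueError, match="outside"):
            ingest_external_gea(self._write(tmp_path, "L0\tlat\t-0.1\n"), "b")

    def test_incomplete_grid_warns(self, tmp_path):
        rows = "L0\tlat\t0.5\nL0\tsst\t0.2\nL1\tlat\t0.1\n"
        with pytest.warns(UserWarning, match="pairs missing"):
            ingest_external_gea(self._write(tmp_path, rows), "bayes")


class TestBroadSenseCombine:
    def _gea(self, qmap):
        rows = [
            {"locus_id": l, "variable": v, "q_value": q}
            for (l, v), q in qmap.items()
        ]
        return pd.DataFrame(rows)

    def test_singleton_set_identity(self):
        env = _env({"lat": np.arange(6.0), "indep": [3, 1, 4, 1, 5, 9.0]},
                   [f"P{i}" for i in range(6)])
        gea = self._gea({("L0", "lat"): 0.02, ("L0", "indep"): 0.9})
        out = broad_sense_combine(gea, "lat", env)
        assert out.attrs["variables"] == ["lat"]
        assert out["q_combined_broad"].iloc[0] == pytest.approx(0.02)

    def test_equal_values_fixed_point(self):
        v = np.arange(6.0)
        env = _env({"lat": v, "c1": 2 * v, "c2": -v}, [f"P{i}" for i in range(6)])
        gea = self._gea({("L0", x): 0.04 for x in ("lat", "c1", "c2")})
        out = broad_sense_combine(gea, "lat", env)
        assert set(out.attrs["variables"]) == {"lat", "c1", "c2"}
        assert out["q_combined_broad"].iloc[0] == pytest.approx(0.04)

    def test_two_value_geometric_mean(self):
        v = np.arange(6.0)
        env = _env({"lat": v, "c1": 3 * v + 1}, [f"P{i}" for i in range(6)])
        gea = self._gea({("L0", "lat"): 0.001, ("L0", "c1"): 0.2})
        out = broad_sense_combine(gea, "lat", env)
        assert out["q_combined_broad"].iloc[0] == pytest.approx(
            np.sqrt(0.0002), abs=1e-12
        )
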