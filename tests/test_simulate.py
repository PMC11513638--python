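"""The synthetic colony generator: pedigrees, breeding values, seasons, counts."""

import numpy as np
import networkx as nx
import pandas as pd
import pytest

from colonyqg.errors import InvalidArgumentError, SchemaError
from colonyqg.simulate import (
    PhenologyParams,
    SimulatedEffects,
    TrueParams,
    default_study_params,
    simulate_breeding_values,
    simulate_colony_season,
    simulate_dataset,
    simulate_pedigree,
    simulate_trait_counts,
)
from colonyqg.traits import ISLAND_LENGTH_M, ISLAND_WIDTH_M

from conftest import recovery_truth


class TestTrueParams:
    def test_negative_variance_rejected(self):
        with pytest.raises(InvalidArgumentError):
            TrueParams(V_A=-0.1)

    def test_non_psd_g2_rejected(self):
        with pytest.raises(InvalidArgumentError):
            TrueParams(G2=[[0.1, 0.5], [0.5, 0.1]])

    def test_g2_defaults_to_pure_intercept(self):
        t = TrueParams(V_A=0.3)
        assert np.array_equal(t.G2, [[0.3, 0.0], [0.0, 0.0]])

    def test_json_round_trip(self):
        t = default_study_params(9)
        back = TrueParams.from_json(t.to_json())
        assert back.seed == 9 and np.allclose(back.G2, t.G2)


class TestSimulatePedigree:
    def test_smallest_trio(self):
        ped = simulate_pedigree(2, 1, 1)
        both_known = sum(
            s >= 0 and d >= 0 for s, d in zip(ped.sire_index, ped.dam_index)
        )
        assert len(ped) == 3 and both_known == 1

    @pytest.mark.parametrize(
        "args", [(3, 1, 1), (10, 0, 1), (4, 2, 0), (0, 1, 1)]
    )
    def test_invalid_arguments(self, args):
        with pytest.raises(InvalidArgumentError):
            simulate_pedigree(*args)

    def test_depth_matches_longest_path_oracle(self):
        ped = simulate_pedigree(20, 5, 2, seed=7)
        g = nx.DiGraph()
        g.add_nodes_from(ped.ids)
        for i in ped.ids:
            for p in ped.parents_of(i):
                if p:
                    g.add_edge(p, i)
        assert nx.dag_longest_path_length(g) == 5
        assert ped.stats()["max_depth"] == 5

    def test_deterministic(self):
        p1 = simulate_pedigree(12, 3, 2, seed=4)
        p2 = simulate_pedigree(12, 3, 2, seed=4)
        assert p1.ids == p2.ids
        assert np.array_equal(p1.sire_index, p2.sire_index)


class TestBreedingValues:
    def test_zero_matrix_gives_zero_values(self):
        ped = simulate_pedigree(8, 2, 2, seed=1)
        bv = simulate_breeding_values(ped, np.zeros((2, 2)), seed=1)
        assert np.all(bv.to_numpy() == 0.0)

    def test_founder_sample_covariance(self):
        from colonyqg.pedigree import Pedigree

        n = 10_000
        ped = Pedigree([f"F{k}" for k in range(n)], [""] * n, [""] * n)
        bv = simulate_breeding_values(ped, np.eye(2), seed=2)
        emp = np.cov(bv.to_numpy().T, ddof=0)
        assert np.all(np.abs(emp - np.eye(2)) < 0.05)

    def test_child_mean_is_parental_midpoint(self):
        from colonyqg.pedigree import Pedigree

        ped = Pedigree(["S", "D", "O"], ["", "", "S"], ["", "", "D"])
        draws = simulate_breeding_values(ped, [[1.0]], seed=3, size=10_000)
        s, d, o = draws[:, 0, 0], draws[:, 1, 0], draws[:, 2, 0]
        dev = o - 0.5 * (s + d)
        assert abs(dev.mean()) < 0.02  # Mendelian deviation has mean zero
        assert np.var(dev) == pytest.approx(0.5, rel=0.1)

    @pytest.mark.parametrize("method", ["mendelian", "cholesky"])
    def test_covariance_matches_a_kron_g2(self, method):
        rng = np.random.default_rng(11)
        ped = simulate_pedigree(8, 2, 2, seed=11)
        G2 = np.array([[0.5, 0.15], [0.15, 0.2]])
        A = ped.a_matrix().values
        target = np.kron(A, G2)
        draws = simulate_breeding_values(ped, G2, seed=13, method=method, size=50_000)
        flat = draws.reshape(draws.shape[0], -1)  # (reps, n*d), kron ordering
        emp = np.cov(flat.T, ddof=0)
        scale = np.sqrt(np.outer(np.diag(target), np.diag(target)))
        assert np.all(np.abs(emp - target) / scale < 0.05)

    def test_unknown_method(self):
        ped = simulate_pedigree(4, 1, 1)
        with pytest.raises(InvalidArgumentError):
            simulate_breeding_values(ped, np.eye(2), method="magic")


class TestColonySeason:
    def test_zero_pairs(self):
        assert len(simulate_colony_season(2000, 0)) == 0

    def test_coordinates_within_island(self):
        df = simulate_colony_season(2001, 500, seed=5)
        assert df.x.between(0, ISLAND_LENGTH_M).all()
        assert df.y.between(0, ISLAND_WIDTH_M).all()
        assert df.island.between(1, 6).all()
        assert df.laying_date.between(1, 366).all()

    def test_negative_phenology_slope_gives_negative_correlation(self):
        df = simulate_colony_season(
            2002, 5000, phenology=PhenologyParams(slope_age=-2.0), seed=6
        )
        r = np.corrcoef(df.age, df.laying_date)[0, 1]
        assert r < -0.1

    def test_invalid_dimensions(self):
        with pytest.raises(InvalidArgumentError):
            simulate_colony_season(2000, 10, island_length=-1.0)

    def test_clustered_placement_concentrates_nests(self):
        from scipy.spatial.distance import cdist

        def mean_nearest_neighbour(df):
            out = []
            for _, g in df.groupby("island"):
                if len(g) < 2:
                    continue
                m = cdist(g[["x", "y"]], g[["x", "y"]])
                np.fill_diagonal(m, np.inf)
                out.append(m.min(axis=1).mean())
            return np.mean(out)

        uniform = simulate_colony_season(2001, 400, seed=5)
        clustered = simulate_colony_season(2001, 400, seed=5, cluster_sd=0.6)
        assert clustered.x.between(0, ISLAND_LENGTH_M).all()
        assert clustered.y.between(0, ISLAND_WIDTH_M).all()
        assert mean_nearest_neighbour(clustered) < mean_nearest_neighbour(uniform)


def flat_effects(female_ids, years=(2000,), islands=range(1, 7)):
    """All-zero random effects for the given females."""
    zeros = pd.DataFrame(
        0.0, index=list(female_ids), columns=["a_int", "a_slope"]
    )
    pe = pd.DataFrame(0.0, index=list(female_ids), columns=["pe_int", "pe_slope"])
    return SimulatedEffects(
        breeding_values=zeros,
        pe_values=pe,
        year_effects={int(y): 0.0 for y in years},
        island_effects={int(i): 0.0 for i in islands},
    )


def bare_table(n, female="F0"):
    return pd.DataFrame(
        {"female_id": female, "year": 2000, "island": 1}, index=range(n)
    )


class TestTraitCounts:
    def test_pure_poisson_five(self):
        truth = TrueParams(
            beta0=np.log(5.0), beta_mean_age=0, beta_delta_age=0,
            beta_age_interaction=0, beta_year=0, beta_colony_density=0,
            beta_island_density=0, V_A=0, V_PE=0, V_year=0, V_island=0,
            V_resid=0,
        )
        table = bare_table(100_000)
        counts, latent = simulate_trait_counts(table, truth, flat_effects(["F0"]), seed=1)
        assert 4.9 <= counts.mean() <= 5.1
        # dispersion: variance/mean within [0.95, 1.05] for pure Poisson
        assert 0.95 <= counts.var(ddof=0) / counts.mean() <= 1.05

    def test_poisson_lognormal_moments(self):
        truth = TrueParams(
            beta0=0.0, beta_mean_age=0, beta_delta_age=0, beta_age_interaction=0,
            beta_year=0, beta_colony_density=0, beta_island_density=0,
            V_A=0, V_PE=0, V_year=0, V_island=0, V_resid=0.5,
        )
        counts, _ = simulate_trait_counts(
            bare_table(100_000), truth, flat_effects(["F0"]), seed=2
        )
        m = np.exp(0.25)
        v = m + m * m * (np.exp(0.5) - 1.0)
        assert counts.mean() == pytest.approx(m, rel=0.03)
        assert counts.var(ddof=0) == pytest.approx(v, rel=0.03)

    def test_same_seed_identical(self):
        truth = recovery_truth(5)
        ds = simulate_dataset(truth, n_founders=20, n_generations=2, n_years=5,
                              start_year=2000, unknown_age_frac=0.0, seed=5)
        eff = ds.effects
        c1, _ = simulate_trait_counts(ds.nests, truth, eff, seed=9)
        c2, _ = simulate_trait_counts(ds.nests, truth, eff, seed=9)
        assert c1.tolist() == c2.tolist()

    def test_missing_covariate_named(self):
        truth = TrueParams(
            beta_mean_age=0, beta_delta_age=0, beta_age_interaction=0,
            beta_year=0, beta_colony_density=0,
        )  # beta_island_density still != 0 by default
        with pytest.raises(SchemaError, match="island_density_std"):
            simulate_trait_counts(bare_table(10), truth, flat_effects(["F0"]), seed=1)

    def test_missing_breeding_values_reported(self):
        truth = TrueParams(
            beta_mean_age=0, beta_delta_age=0, beta_age_interaction=0,
            beta_year=0, beta_colony_density=0, beta_island_density=0,
        )
        with pytest.raises(SchemaError, match="breeding values"):
            simulate_trait_counts(
                bare_table(10), truth, flat_effects(["OTHER"]), seed=1
            )


@pytest.fixture(scope="module")
def dataset():
    return simulate_dataset(
        recovery_truth(8), n_founders=40, n_generations=3, n_years=10,
        start_year=2005, unknown_age_frac=0.05, seed=8,
    )


class TestSimulateDataset:

    def test_phenotyped_females_in_pedigree(self, dataset):
        assert all(f in dataset.pedigree for f in dataset.phenotyped_females)

    def test_counts_are_non_negative_integers(self, dataset):
        counts = dataset.nests["count"]
        assert (counts >= 0).all()
        assert (counts == counts.astype(int)).all()

    def test_latent_round_trip_exact(self, dataset):
        latent = dataset.latent_values
        parts = latent.drop(columns="eta").sum(axis=1)
        assert np.allclose(parts, latent.eta, atol=1e-12)

    def test_one_record_per_female_year(self, dataset):
        assert not dataset.nests.duplicated(["female_id", "year"]).any()

    def test_unknown_age_fraction_applied(self, dataset):
        frac = dataset.nests.groupby("female_id").age.apply(
            lambda s: s.isna().any()
        ).mean()
        assert 0.0 < frac <= 0.12

    def test_byte_identical_under_fixed_seed(self, tmp_path):
        t = recovery_truth(12)
        d1 = simulate_dataset(t, n_founders=20, n_generations=2, n_years=6,
                              start_year=2000, seed=12)
        d2 = simulate_dataset(t, n_founders=20, n_generations=2, n_years=6,
                              start_year=2000, seed=12)
        d1.write(tmp_path / "a")
        d2.write(tmp_path / "b")
        for name in ("nests.csv", "pedigree.csv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_study_conditions_emulated(self):
        ds = simulate_dataset(
            default_study_params(3), n_founders=80, n_generations=3,
            n_years=29, unknown_age_frac=0.0, seed=3,
        )
        tab = ds.nests
        assert tab.age.between(2, 27).all()
        assert 5.5 <= tab.age.mean() <= 9.5  # study: 7.67
        assert tab.year.nunique() == 29
        assert tab.island.between(1, 6).all()
        # colony grows over the study period
        first = tab[tab.year <= tab.year.min() + 5].groupby("year").size().mean()
        last = tab[tab.year >= tab.year.max() - 5].groupby("year").size().mean()
        assert last > first
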