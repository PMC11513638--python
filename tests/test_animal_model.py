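"""The MCMC animal-model engine: validation, oracles, invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from colonyqg import (
    MCMCConfig,
    ModelSpec,
    ess_and_autocorr,
    fit_glmm_animal,
    fit_random_regression,
    hpd_interval,
)
from colonyqg.errors import ConfigError, InvalidArgumentError, SchemaError
from colonyqg.pedigree import Pedigree
from colonyqg.summaries import ReactionNormEstimates

from conftest import quick_cfg, recovery_dataset, recovery_truth


def sib_design(n_families=25, n_offspring=2, repeats=2, seed=7):
    """Phenotyped parents + full-sib offspring: identifies V_A vs V_PE well."""
    rng = np.random.default_rng(seed)
    ids, sires, dams, phen = [], [], [], []
    for k in range(n_families):
        s, d = f"S{k}", f"D{k}"
        ids += [s, d]
        sires += ["", ""]
        dams += ["", ""]
        phen += [s, d]
        for j in range(n_offspring):
            i = f"O{k}_{j}"
            ids.append(i)
            sires.append(s)
            dams.append(d)
            phen.append(i)
    ped = Pedigree(ids, sires, dams)
    A = ped.a_matrix()
    sub = A.indices_of(phen)
    Af = A.values[np.ix_(sub, sub)]
    V_A, V_PE, V_e = 0.4, 0.25, 0.2
    a = (
        np.linalg.cholesky(Af + 1e-10 * np.eye(len(phen)))
        @ rng.standard_normal(len(phen))
        * np.sqrt(V_A)
    )
    pe = rng.normal(0, np.sqrt(V_PE), len(phen))
    rows = [(f, a[k] + pe[k]) for k, f in enumerate(phen) for _ in range(repeats)]
    df = pd.DataFrame(rows, columns=["female_id", "base"])
    df["y"] = 2.0 + df.base + rng.normal(0, np.sqrt(V_e), len(df))
    return ped, df.drop(columns="base")


def reml_oracle(ped, df):
    """Direct restricted-likelihood optimizer over (V_A, V_PE, V_e)."""
    A = ped.a_matrix()
    fem_codes, fem_levels = pd.factorize(df.female_id)
    sub = A.indices_of(list(fem_levels))
    Ax = A.values[np.ix_(sub, sub)]
    n = len(df)
    Z = np.zeros((n, len(fem_levels)))
    Z[np.arange(n), fem_codes] = 1.0
    X = np.ones((n, 1))
    y = df.y.to_numpy()

    def neg_reml(logv):
        va, vp, ve = np.exp(logv)
        V = va * (Z @ Ax @ Z.T) + vp * (Z @ Z.T) + ve * np.eye(n)
        _, logdet = np.linalg.slogdet(V)
        Vi = np.linalg.inv(V)
        XVX = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
        return 0.5 * (logdet + np.log(np.linalg.det(XVX)) + y @ P @ y)

    res = optimize.minimize(
        neg_reml, np.log([0.3, 0.3, 0.3]), method="Nelder-Mead",
        options=dict(xatol=1e-6, fatol=1e-9, maxiter=3000),
    )
    return np.exp(res.x)


class TestValidation:
    def table(self):
        return pd.DataFrame(
            {
                "count": [1, 2], "female_id": ["a", "b"],
                "year": [1, 1], "island": [1, 2],
                "age_std": [-1.0, 1.0], "age_class": [1, 2],
            }
        )

    def test_missing_column_named(self):
        spec = ModelSpec(fixed=("nope",), random=("year",))
        with pytest.raises(SchemaError, match="nope"):
            spec.validate(self.table(), None)

    def test_genetic_requires_relationship_matrix(self):
        spec = ModelSpec(fixed=(), random=("genetic",))
        with pytest.raises(ConfigError, match="relationship"):
            spec.validate(self.table(), None)

    def test_slopes_require_gradient(self):
        spec = ModelSpec(fixed=(), random=("individual_slopes",))
        with pytest.raises(ConfigError, match="gradient"):
            spec.validate(self.table(), None)

    def test_individual_and_genetic_slopes_exclusive(self):
        spec = ModelSpec(
            fixed=(), random=("individual_slopes", "genetic_slopes"),
            gradient="age_std",
        )
        with pytest.raises(ConfigError, match="individual_slopes"):
            spec.validate(self.table(), None)

    def test_intercepts_subsumed_by_slopes(self):
        spec = ModelSpec(
            fixed=(), random=("permanent_env", "pe_slopes"), gradient="age_std"
        )
        with pytest.raises(ConfigError, match="pe_slopes"):
            spec.validate(self.table(), None)

    def test_chain_config_contracts(self):
        with pytest.raises(ConfigError):
            MCMCConfig(n_iter=100, burn_in=100)
        with pytest.raises(ConfigError):
            MCMCConfig(n_iter=100, burn_in=99, thin=50)

    def test_poisson_requires_counts(self):
        df = self.table().assign(count=[0.5, 1.2])
        with pytest.raises(InvalidArgumentError, match="non-negative integers"):
            fit_glmm_animal(
                df, None, ModelSpec(fixed=(), random=("year",)), quick_cfg()
            )

    def test_uncentred_gradient_rejected(self):
        df = self.table().assign(count=[1, 2], age_std=[1.0, 2.0])
        with pytest.raises(InvalidArgumentError, match="mean-centred"):
            fit_glmm_animal(
                df, None,
                ModelSpec(fixed=(), random=("individual_slopes",),
                          residual="by_age_class", gradient="age_std"),
                quick_cfg(),
            )


class TestGaussianREMLOracle:
    def test_variances_match_restricted_likelihood_optimum(self):
        ped, df = sib_design()
        assert len(df) == 200
        reml = reml_oracle(ped, df)
        spec = ModelSpec(
            response="y", fixed=(), random=("genetic", "permanent_env"),
            family="gaussian",
        )
        chains = fit_glmm_animal(
            df, ped.a_matrix(), spec,
            MCMCConfig(n_iter=3000, burn_in=800, thin=2, seed=3,
                       variance_substeps=1),
        )
        post = np.array(
            [float(np.median(chains[k])) for k in ("V_A", "V_PE", "V_resid")]
        )
        assert np.all(np.abs(post - reml) / reml < 0.15)


class TestChainContracts:
    def test_determinism_under_fixed_seed(self):
        ped, df = sib_design(n_families=10, repeats=2)
        spec = ModelSpec(response="y", fixed=(),
                         random=("genetic", "permanent_env"), family="gaussian")
        cfg = MCMCConfig(n_iter=600, burn_in=200, thin=2, seed=5)
        c1 = fit_glmm_animal(df, ped.a_matrix(), spec, cfg)
        c2 = fit_glmm_animal(df, ped.a_matrix(), spec, cfg)
        for key in c1.keys():
            assert np.array_equal(c1[key], c2[key])

    def test_posterior_predictive_conserves_mean_count(self, small_poisson_fit):
        ds, A, chains = small_poisson_fit
        rng = np.random.default_rng(1)
        simulated = rng.poisson(np.exp(chains.meta["eta_mean"]))
        observed = ds.nests["count"].mean()
        assert simulated.mean() == pytest.approx(observed, rel=0.10)

    def test_label_invariance_of_posterior_summaries(self, small_poisson_fit):
        ds, A, chains = small_poisson_fit
        permuted = ds.nests.sample(frac=1.0, random_state=99).reset_index(drop=True)
        chains_p = fit_glmm_animal(permuted, A, ModelSpec(), quick_cfg(seed=1))
        for key in ("V_A", "V_PE", "V_year", "V_island", "V_resid"):
            lo, hi = hpd_interval(chains[key])
            width = max(hi - lo, 1e-3)
            d = abs(float(np.median(chains[key])) - float(np.median(chains_p[key])))
            assert d < 0.5 * width, key

    def test_prior_scale_insensitivity(self):
        truth = recovery_truth(31)
        ds, A = recovery_dataset(truth, n_founders=48)
        meds = {}
        for scale in (10.0, 20.0):
            chains = fit_glmm_animal(
                ds.nests, A, ModelSpec(),
                quick_cfg(seed=2, n_iter=2600, burn_in=800, prior_sd_scale=scale),
            )
            meds[scale] = {
                k: float(np.median(chains[k]))
                for k in ("V_A", "V_PE", "V_resid")
            }
        for k in meds[10.0]:
            base = meds[10.0][k]
            assert abs(meds[20.0][k] - base) / max(base, 0.05) < 0.20, k


class TestReactionNormChains:
    def test_individual_level_fit_contract(self):
        truth = recovery_truth(
            37, G2=[[0.2, 0.06], [0.06, 0.05]], P2=[[0.05, 0.0], [0.0, 0.0]]
        )
        ds, A = recovery_dataset(truth, n_founders=48)
        chains = fit_random_regression(
            ds.nests, A, "individual", cfg=quick_cfg(seed=3, n_iter=1600,
                                                     burn_in=600)
        )
        rn = ReactionNormEstimates.from_chains(chains, "I")
        # per-sample invariants of the reported reaction-norm posteriors
        assert np.all(np.abs(rn.corr) <= 1.0)
        assert np.array_equal(rn.variance_at(0.0), rn.v_int)
        assert np.all(rn.v_int > 0) and np.all(rn.v_slope > 0)
        g = ds.nests["age_std"]
        for q in (g.min(), g.max()):
            assert np.all(rn.variance_at(float(q)) >= 0.0)
        # five heterogeneous residual variances were fitted
        assert sum(k.startswith("V_resid_") for k in chains.keys()) == 5


class TestConvergenceYardstick:
    def test_default_config_reaches_target_ess(self):
        """Variance chains reach ESS >= 1000 with |lag-1 acf| < 0.1."""
        truth = recovery_truth(42)
        ds, A = recovery_dataset(truth, n_founders=36)
        chains = fit_glmm_animal(ds.nests, A, ModelSpec(), MCMCConfig(seed=4))
        for key in ("V_A", "V_PE", "V_year", "V_island", "V_resid"):
            d = ess_and_autocorr(chains[key])
            assert d["ess"] >= 1000, (key, d)
            assert abs(d["lag1_autocorr"]) < 0.1, (key, d)
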