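"""Shared fixtures and helpers for the colonyqg test suite.

All fixtures are generated programmatically; MCMC helpers use short chains
(the chain settings here are test-speed choices, not the library defaults).
"""

from __future__ import annotations

import numpy as np
import pytest

from colonyqg import MCMCConfig, ModelSpec, TrueParams, fit_glmm_animal
from colonyqg.pedigree import Pedigree
from colonyqg.simulate import simulate_dataset


def quick_cfg(**kwargs) -> MCMCConfig:
    """Short-chain MCMC settings for tests."""
    defaults = dict(n_iter=1800, burn_in=600, thin=2, seed=0, variance_substeps=1)
    defaults.update(kwargs)
    return MCMCConfig(**defaults)


def recovery_truth(seed: int, **overrides) -> TrueParams:
    """Ground truth with all fixed-effect slopes zero (pure variance recovery)."""
    base = dict(
        beta_mean_age=0.0,
        beta_delta_age=0.0,
        beta_age_interaction=0.0,
        beta_year=0.0,
        beta_colony_density=0.0,
        beta_island_density=0.0,
        seed=seed,
    )
    base.update(overrides)
    return TrueParams(**base)


def recovery_dataset(truth: TrueParams, n_founders: int = 60, n_years: int = 29,
                     seed: int | None = None):
    """Desk-scale synthetic study: ~120 females, ~600 observations."""
    ds = simulate_dataset(
        truth,
        n_founders=n_founders,
        n_generations=3,
        offspring_per_pair=2,
        n_years=n_years,
        start_year=1993,
        unknown_age_frac=0.0,
        seed=truth.seed if seed is None else seed,
    )
    A = ds.pedigree.prune(ds.nests["female_id"].unique()).a_matrix()
    return ds, A


def random_pedigree(rng: np.random.Generator, n: int, p_parent: float = 0.7):
    """Random acyclic pedigree: parents drawn among earlier individuals."""
    ids, sires, dams = [], [], []
    for i in range(n):
        ids.append(f"I{i}")
        if i >= 2 and rng.random() < p_parent:
            s, d = rng.choice(i, size=2, replace=False)
            sires.append(f"I{s}")
            dams.append(f"I{d}")
        else:
            sires.append("")
            dams.append("")
    return Pedigree(ids, sires, dams)


@pytest.fixture(scope="session")
def small_poisson_fit():
    """One shared intercept-model fit on synthetic ground truth."""
    truth = recovery_truth(42)
    ds, A = recovery_dataset(truth, n_founders=48)
    chains = fit_glmm_animal(ds.nests, A, ModelSpec(), quick_cfg(seed=1))
    return ds, A, chains
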