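"""Synthetic pedigreed breeding colonies with known ground truth.

The generator emulates a long-term colony study: six rectangular islands of
10.7 m x 4.6 m, a multi-decade run of breeding seasons with colony size
ramping over years, females breeding from age 2 up to age 27 under a
geometric-like annual survival of 0.87, laying dates that advance with age
(producing a negative correlation between annual mean age and annual mean
laying date), and a latent-scale Poisson-lognormal trait model with additive
genetic, permanent-environment, year, island and overdispersion components,
plus optional genetic and permanent-environment reaction-norm slopes over
standardized age (G x Age and PE x Age).

Every simulated dataset stores its generative parameters and the exact
latent decomposition of each observation, so parameter-recovery tests can
compare posteriors against truth and white-box tests can verify the
generator arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, SchemaError
from .pedigree import Pedigree
from .prep import prepare_model_table
from .traits import ISLAND_LENGTH_M, ISLAND_WIDTH_M, N_ISLANDS, build_trait_table

#: reference adult age used to anchor the phenology model (years)
AGE_REFERENCE = 7.67


def _psd_factor(M: np.ndarray) -> np.ndarray:
    """Factor F with F @ F.T = M for a symmetric PSD matrix (rank-deficient ok)."""
    M = np.asarray(M, dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T):
        raise InvalidArgumentError("covariance matrix must be square symmetric")
    w, V = np.linalg.eigh(M)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise InvalidArgumentError("covariance matrix is not positive semidefinite")
    return V * np.sqrt(np.clip(w, 0.0, None))


@dataclass
class TrueParams:
    """Generative parameters of the synthetic colony, all on the latent scale.

    Fixed-effect slopes are per standardized unit of their covariate, except
    the age components, which are per raw year (matching how the partitioned
    animal model fits them).  ``G2``/``P2`` are 2x2 intercept/slope
    covariance matrices over the standardized-age gradient; when ``None``
    they default to pure-intercept matrices built from ``V_A``/``V_PE``.
    """

    beta0: float = 1.6
    beta_mean_age: float = -0.024
    beta_delta_age: float = -0.059
    beta_age_interaction: float = 0.003
    beta_year: float = 0.015
    beta_colony_density: float = 0.037
    beta_island_density: float = 0.67
    beta_laying_date: float = 0.0
    beta_wall: float = 0.0
    V_A: float = 0.20
    V_PE: float = 0.10
    V_year: float = 0.05
    V_island: float = 0.02
    V_resid: float = 0.30
    G2: np.ndarray | None = None
    P2: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("V_A", "V_PE", "V_year", "V_island", "V_resid"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if self.G2 is None:
            self.G2 = np.array([[self.V_A, 0.0], [0.0, 0.0]])
        else:
            self.G2 = np.asarray(self.G2, dtype=float)
            self.V_A = float(self.G2[0, 0])
        if self.P2 is None:
            self.P2 = np.array([[self.V_PE, 0.0], [0.0, 0.0]])
        else:
            self.P2 = np.asarray(self.P2, dtype=float)
            self.V_PE = float(self.P2[0, 0])
        _psd_factor(self.G2)  # raises unless symmetric PSD
        _psd_factor(self.P2)

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items()}
        d["G2"] = self.G2.tolist()
        d["P2"] = self.P2.tolist()
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TrueParams":
        d = json.loads(text)
        d["G2"] = np.array(d["G2"])
        d["P2"] = np.array(d["P2"])
        return cls(**d)


def default_study_params(seed: int = 0) -> TrueParams:
    """Study-condition parameter set: heritable intercepts *and* ageing slopes.

    Latent variance magnitudes are chosen so that the variance proportions
    match the published decomposition (h2 36.5%, PE 28.4%, year 9.2%,
    island 0.8%, residual the rest) at an evolvability of about 2.5% and a
    trait mean near 6.65 — i.e. a total latent random variance of about
    0.076.  The genetic intercept/slope covariance implies a correlation of
    about +0.6 (fanning-out), the permanent-environment slopes are nearly
    flat, and laying date and wall distance carry real effects.
    """
    return TrueParams(
        beta0=1.795,
        beta_laying_date=0.19,
        beta_wall=0.084,
        V_year=0.0070,
        V_island=0.0006,
        V_resid=0.0190,
        G2=np.array([[0.0276, 0.0100], [0.0100, 0.0100]]),
        P2=np.array([[0.0215, 0.0], [0.0, 0.0010]]),
        seed=seed,
    )


@dataclass
class PhenologyParams:
    """Laying-date model: start + slope_age * (age - 7.67) + year shift + noise."""

    season_start: float = 128.0  # day-of-year around which first clutches centre
    slope_age: float = -2.0  # days per year of age (older birds lay earlier)
    sd_days: float = 8.0  # within-year individual scatter
    year_sd_days: float = 4.0  # among-year phenology shifts (weather)


def sample_ages(
    rng: np.random.Generator,
    size: int,
    survival: float = 0.87,
    min_age: int = 2,
    max_age: int = 27,
) -> np.ndarray:
    """Ages from a truncated geometric survival model (stationary age mix)."""
    if not 0 < survival < 1:
        raise InvalidArgumentError("survival must lie in (0, 1)")
    ages = np.arange(min_age, max_age + 1)
    p = survival ** (ages - min_age)
    return rng.choice(ages, size=size, p=p / p.sum())


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    offspring_per_pair: int = 2,
    seed: int = 0,
) -> Pedigree:
    """Discrete-generation pedigree with monogamous random pairing.

    Founders (generation 0) have unknown parents; each later generation is
    produced by randomly pairing the males and females of the previous one,
    every pair contributing ``offspring_per_pair`` offspring with balanced
    sexes.  Individual ids encode generation and index (``G2_013``).
    """
    if n_founders < 2 or n_founders % 2:
        raise InvalidArgumentError("n_founders must be an even integer >= 2")
    if n_generations < 1:
        raise InvalidArgumentError("n_generations must be >= 1")
    if offspring_per_pair < 1:
        raise InvalidArgumentError("offspring_per_pair must be >= 1")
    rng = np.random.default_rng([seed, 101])
    ids, sires, dams = [], [], []
    sex = {}
    current = []
    for k in range(n_founders):
        i = f"G0_{k:04d}"
        ids.append(i)
        sires.append("")
        dams.append("")
        sex[i] = "F" if k % 2 else "M"
        current.append(i)
    for gen in range(1, n_generations + 1):
        males = [i for i in current if sex[i] == "M"]
        females = [i for i in current if sex[i] == "F"]
        rng.shuffle(males)
        rng.shuffle(females)
        nxt = []
        k = 0
        for sire, dam in zip(males, females):
            for _ in range(offspring_per_pair):
                child = f"G{gen}_{k:04d}"
                ids.append(child)
                sires.append(sire)
                dams.append(dam)
                sex[child] = "F" if k % 2 else "M"
                nxt.append(child)
                k += 1
        current = nxt
        if len(current) < 2:
            break
    return Pedigree(ids, sires, dams, sex=sex)


def simulate_breeding_values(
    pedigree: Pedigree,
    G2: np.ndarray,
    seed: int = 0,
    method: str = "mendelian",
    size: int | None = None,
):
    """Breeding values (intercept, slope) with covariance A (x) G2.

    ``mendelian`` (default, linear time): founders are drawn iid from
    N(0, G2); a non-founder is the mean of its known parents' values plus a
    Mendelian deviation with covariance v_i * G2, where v_i is 1/2 minus a
    quarter of each known parent's inbreeding coefficient (3/4 with one
    unknown parent, 1 with both unknown).  ``cholesky`` draws the whole
    vector from the exact joint distribution via factorizations of A and G2;
    it is quadratic in pedigree size and serves as the small-pedigree oracle.

    With ``size`` given, ``size`` independent replicate draws are returned
    as an array of shape (size, n, d) — the form used by Monte-Carlo checks.
    """
    G2 = np.atleast_2d(np.asarray(G2, dtype=float))
    d = G2.shape[0]
    FG = _psd_factor(G2)
    rng = np.random.default_rng([seed, 211])
    n = len(pedigree)
    reps = 1 if size is None else int(size)
    A = pedigree.a_matrix()
    if method == "cholesky":
        FA = _psd_factor(A.values)
        z = rng.standard_normal((reps, n, d))
        values = np.einsum("ij,rjk,lk->ril", FA, z, FG)
    elif method == "mendelian":
        F = A.inbreeding
        s, dm = pedigree.sire_index, pedigree.dam_index
        values = np.zeros((reps, n, d))
        z = rng.standard_normal((reps, n, d)) @ FG.T
        for i in range(n):
            si, di = s[i], dm[i]
            mean = np.zeros((reps, d))
            v = 1.0
            for p in (si, di):
                if p >= 0:
                    mean += 0.5 * values[:, p]
                    v -= 0.25 * (1.0 + F[p])
            values[:, i] = mean + np.sqrt(v) * z[:, i]
    else:
        raise InvalidArgumentError(f"unknown method: {method!r}")
    if size is not None:
        return values
    cols = ["a_int", "a_slope"][:d] if d <= 2 else [f"a_{k}" for k in range(d)]
    return pd.DataFrame(values[0], index=list(pedigree.ids), columns=cols)


# ---------------------------------------------------------------------------
# nest map simulation
# ---------------------------------------------------------------------------

def simulate_colony_season(
    year: int,
    pairs: int,
    age_distribution=None,
    phenology: PhenologyParams | None = None,
    seed: int = 0,
    island_length: float = ISLAND_LENGTH_M,
    island_width: float = ISLAND_WIDTH_M,
    n_islands: int = N_ISLANDS,
    cluster_sd: float | None = None,
) -> pd.DataFrame:
    """One season of nest records placed on the islands.

    ``age_distribution`` is a callable ``(rng, size) -> ages``; the default
    is the truncated geometric survival mix of :func:`sample_ages`.
    Placement is uniform within each island; with ``cluster_sd`` set, nests
    scatter (truncated) around a few random cluster centres per island
    instead, emulating social nest aggregation.
    """
    if pairs < 0:
        raise InvalidArgumentError("pairs must be >= 0")
    if island_length <= 0 or island_width <= 0:
        raise InvalidArgumentError("island dimensions must be positive")
    phenology = phenology or PhenologyParams()
    rng = np.random.default_rng([seed, 307, int(year)])
    if age_distribution is None:
        age_distribution = sample_ages
    ages = np.asarray(age_distribution(rng, pairs), dtype=float)
    laying = (
        phenology.season_start
        + phenology.slope_age * (ages - AGE_REFERENCE)
        + rng.normal(0.0, phenology.sd_days, size=pairs)
    )
    islands = rng.integers(1, n_islands + 1, size=pairs)
    if cluster_sd is None:
        x = rng.uniform(0.0, island_length, size=pairs)
        y = rng.uniform(0.0, island_width, size=pairs)
    else:
        if cluster_sd <= 0:
            raise InvalidArgumentError("cluster_sd must be positive")
        centres = {
            isl: (
                rng.uniform(0.0, island_length, size=3),
                rng.uniform(0.0, island_width, size=3),
            )
            for isl in range(1, n_islands + 1)
        }
        x = np.empty(pairs)
        y = np.empty(pairs)
        for k, isl in enumerate(islands):
            cx, cy = centres[int(isl)]
            c = int(rng.integers(0, len(cx)))
            x[k] = np.clip(rng.normal(cx[c], cluster_sd), 0.0, island_length)
            y[k] = np.clip(rng.normal(cy[c], cluster_sd), 0.0, island_width)
    return pd.DataFrame(
        {
            "female_id": [f"Y{year}_F{k:04d}" for k in range(pairs)],
            "year": int(year),
            "island": islands,
            "x": x,
            "y": y,
            "laying_date": np.clip(np.rint(laying), 1, 366).astype(int),
            "age": ages,
        }
    )


# ---------------------------------------------------------------------------
# trait-count simulation (generative inverse of the fitted animal model)
# ---------------------------------------------------------------------------

@dataclass
class SimulatedEffects:
    """Realized random effects: per-individual, per-year and per-island draws."""

    breeding_values: pd.DataFrame  # columns a_int, a_slope; index individual id
    pe_values: pd.DataFrame  # columns pe_int, pe_slope; index female id
    year_effects: dict  # year -> latent deviation
    island_effects: dict  # island -> latent deviation


#: fixed-effect slope -> covariate column it multiplies
_BETA_COLUMNS = {
    "beta_mean_age": "mean_age",
    "beta_delta_age": "delta_age",
    "beta_age_interaction": "age_interaction",  # mean_age * delta_age, built here
    "beta_year": "year_std",
    "beta_colony_density": "colony_density_std",
    "beta_island_density": "island_density_std",
    "beta_laying_date": "laying_date_std",
    "beta_wall": "wall_distance_std",
}


def simulate_effects(
    pedigree: Pedigree,
    females,
    years,
    islands,
    truth: TrueParams,
    seed: int | None = None,
) -> SimulatedEffects:
    """Draw every random effect the trait model needs, from one seed."""
    seed = truth.seed if seed is None else seed
    bv = simulate_breeding_values(pedigree, truth.G2, seed=seed)
    if bv.shape[1] == 1:
        bv["a_slope"] = 0.0
    rng = np.random.default_rng([seed, 401])
    FP = _psd_factor(truth.P2)
    pe = pd.DataFrame(
        rng.standard_normal((len(females), 2)) @ FP.T,
        index=list(females),
        columns=["pe_int", "pe_slope"],
    )
    year_effects = {
        int(y): e
        for y, e in zip(sorted(set(int(y) for y in years)),
                        rng.normal(0.0, np.sqrt(truth.V_year),
                                   size=len(set(int(y) for y in years))))
    }
    island_effects = {
        int(i): e
        for i, e in zip(sorted(set(int(i) for i in islands)),
                        rng.normal(0.0, np.sqrt(truth.V_island),
                                   size=len(set(int(i) for i in islands))))
    }
    return SimulatedEffects(bv, pe, year_effects, island_effects)


def simulate_trait_counts(
    table: pd.DataFrame,
    truth: TrueParams,
    effects: SimulatedEffects,
    seed: int | None = None,
):
    """Counts from the Poisson-lognormal latent model; returns (counts, latent).

    The linear predictor is
    ``eta = beta0 + sum_k beta_k x_k + a_int + age_std * a_slope
    + pe_int + age_std * pe_slope + year + island + e`` with
    ``e ~ N(0, V_resid)`` (the overdispersion term) and
    ``count ~ Poisson(exp(eta))``.  Covariate columns are only required when
    their slope is non-zero; a missing required column raises a
    :class:`~colonyqg.errors.SchemaError` naming it.  ``latent`` holds every
    additive piece of eta per record, so stored values reconstruct eta
    exactly.
    """
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng([seed, 503])
    n = len(table)
    work = table.copy()
    latent = pd.DataFrame(index=table.index)
    eta = np.full(n, truth.beta0, dtype=float)
    latent["fixed_beta0"] = truth.beta0

    if truth.beta_age_interaction != 0.0:
        for col in ("mean_age", "delta_age"):
            if col not in work.columns:
                raise SchemaError(f"missing required column(s): ['{col}']")
        work["age_interaction"] = work["mean_age"] * work["delta_age"]
    for beta_name, col in _BETA_COLUMNS.items():
        beta = getattr(truth, beta_name)
        if beta == 0.0:
            continue
        if col not in work.columns:
            raise SchemaError(f"missing required column(s): ['{col}']")
        piece = beta * work[col].to_numpy(dtype=float)
        eta += piece
        latent["fixed_" + col] = piece

    slopes_active = truth.G2[1, 1] > 0 or truth.P2[1, 1] > 0
    g = None
    if slopes_active:
        if "age_std" not in work.columns:
            raise SchemaError("missing required column(s): ['age_std']")
        g = work["age_std"].to_numpy(dtype=float)

    fem = work["female_id"].astype(str)
    missing = set(fem) - set(effects.breeding_values.index)
    if missing:
        raise SchemaError(
            f"breeding values missing for {len(missing)} female(s), "
            f"e.g. {sorted(missing)[:5]}"
        )
    a_int = effects.breeding_values["a_int"].reindex(fem).to_numpy()
    pe_int = effects.pe_values["pe_int"].reindex(fem).to_numpy()
    latent["a_int"] = a_int
    latent["pe_int"] = pe_int
    eta += a_int + pe_int
    if slopes_active:
        a_sl = effects.breeding_values["a_slope"].reindex(fem).to_numpy() * g
        pe_sl = effects.pe_values["pe_slope"].reindex(fem).to_numpy() * g
        latent["a_slope_term"] = a_sl
        latent["pe_slope_term"] = pe_sl
        eta += a_sl + pe_sl

    yr = work["year"].astype(int).map(effects.year_effects).to_numpy(dtype=float)
    isl = work["island"].astype(int).map(effects.island_effects).to_numpy(dtype=float)
    latent["year_effect"] = yr
    latent["island_effect"] = isl
    eta += yr + isl

    e = rng.normal(0.0, np.sqrt(truth.V_resid), size=n)
    latent["e"] = e
    eta += e
    latent["eta"] = eta
    counts = rng.poisson(np.exp(np.clip(eta, None, 30.0)))
    return pd.Series(counts, index=table.index, name="count"), latent


# ---------------------------------------------------------------------------
# end-to-end dataset simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """A complete synthetic study: pedigree, nest table, truth and latents."""

    pedigree: Pedigree
    nests: pd.DataFrame  # incl. trait covariates and simulated 'count'
    truth: TrueParams
    effects: SimulatedEffects
    latent_values: pd.DataFrame
    scalers: dict = field(default_factory=dict)

    @property
    def phenotyped_females(self) -> list:
        return sorted(self.nests["female_id"].astype(str).unique())

    def write(self, directory) -> None:
        """CSV/JSON export: nests.csv, pedigree.csv, truth.json."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cols = [
            "female_id", "year", "island", "x", "y", "laying_date", "age", "count",
        ]
        self.nests[cols].to_csv(directory / "nests.csv", index=False)
        self.pedigree.write_csv(directory / "pedigree.csv")
        (directory / "truth.json").write_text(self.truth.to_json())


def simulate_dataset(
    truth: TrueParams | None = None,
    n_founders: int = 440,
    n_generations: int = 3,
    offspring_per_pair: int = 2,
    n_years: int = 29,
    start_year: int = 1993,
    survival: float = 0.87,
    max_age: int = 27,
    entry_ramp: float = 3.0,
    island_switch_prob: float = 0.1,
    unknown_age_frac: float = 0.025,
    phenology: PhenologyParams | None = None,
    radius_m: float = 2.0,
    window_days: int = 28,
    seed: int | None = None,
) -> SimulatedDataset:
    """Simulate a full longitudinal colony study with known truth.

    Every female in the pedigree breeds annually from her entry year until
    death (annual survival ``survival``, age capped at ``max_age``) on a
    sticky home island, nests placed uniformly.  Entry years are weighted by
    a linear ramp (colony growth); first-season entrants receive stationary
    ages, later entrants recruit at age 2.  Covariates are assembled with
    :func:`colonyqg.traits.build_trait_table` and
    :func:`colonyqg.prep.prepare_model_table`, and counts are generated by
    :func:`simulate_trait_counts` — so fitting the matching animal model to
    the ``count`` column is a well-posed recovery problem.
    """
    truth = truth if truth is not None else TrueParams()
    seed = truth.seed if seed is None else seed
    phenology = phenology or PhenologyParams()
    ped = simulate_pedigree(n_founders, n_generations, offspring_per_pair, seed=seed)
    females = [i for i in ped.ids if ped.sex.get(i) == "F"]
    rng = np.random.default_rng([seed, 601])

    years = np.arange(start_year, start_year + n_years)
    weights = np.linspace(1.0, max(entry_ramp, 1e-9), n_years)
    weights /= weights.sum()
    rows = []
    recruit_ages, recruit_p = (2, 3, 4), (0.35, 0.45, 0.2)
    for f in females:
        entry = int(rng.choice(years, p=weights))
        age = (
            int(sample_ages(rng, 1, survival=survival, max_age=max_age)[0])
            if entry == start_year
            else int(rng.choice(recruit_ages, p=recruit_p))
        )
        island = int(rng.integers(1, N_ISLANDS + 1))
        year = entry
        while year <= years[-1] and age <= max_age:
            rows.append((f, year, island, age))
            if rng.random() >= survival:
                break
            if rng.random() < island_switch_prob:
                island = int(rng.integers(1, N_ISLANDS + 1))
            year += 1
            age += 1
    base = pd.DataFrame(rows, columns=["female_id", "year", "island", "age"])

    n = len(base)
    base["x"] = rng.uniform(0.0, ISLAND_LENGTH_M, size=n)
    base["y"] = rng.uniform(0.0, ISLAND_WIDTH_M, size=n)
    year_shift = {
        int(y): s
        for y, s in zip(years, rng.normal(0.0, phenology.year_sd_days, n_years))
    }
    laying = (
        phenology.season_start
        + phenology.slope_age * (base["age"].to_numpy(dtype=float) - AGE_REFERENCE)
        + base["year"].map(year_shift).to_numpy()
        + rng.normal(0.0, phenology.sd_days, size=n)
    )
    base["laying_date"] = np.clip(np.rint(laying), 1, 366).astype(int)

    table = build_trait_table(base, radius_m=radius_m, window_days=window_days)
    table, scalers = prepare_model_table(table)

    effects = simulate_effects(
        ped, sorted(set(base["female_id"])), years, range(1, N_ISLANDS + 1),
        truth, seed=seed,
    )
    counts, latent = simulate_trait_counts(table, truth, effects, seed=seed)
    table["count"] = counts.to_numpy()

    if unknown_age_frac > 0:
        fem_ids = np.array(sorted(set(base["female_id"])))
        n_unknown = int(round(unknown_age_frac * len(fem_ids)))
        if n_unknown:
            unknown = rng.choice(fem_ids, size=n_unknown, replace=False)
            table.loc[table["female_id"].isin(unknown), "age"] = np.nan

    return SimulatedDataset(
        pedigree=ped,
        nests=table,
        truth=truth,
        effects=effects,
        latent_values=latent,
        scalers=scalers,
    )
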