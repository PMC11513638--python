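"""Bayesian Poisson-lognormal animal models by MCMC, written from scratch.

Model
-----
Counts are overdispersed Poisson on a log link:

    y_i ~ Poisson(exp(eta_i)),   eta_i = x_i' beta + sum_r z_i' u_r + e_i,

with ``e_i ~ N(0, V_resid)`` the observation-level overdispersion term
(optionally heterogeneous over age classes).  Random terms cover the
animal-model intercepts — additive genetic ``a ~ N(0, V_A * A)`` with **A**
the pedigree relationship matrix, permanent environment, year and island —
and random-regression (intercept, slope) pairs over a standardized age
gradient at the individual, genetic (``A (x) G2``) and permanent-environment
levels.

Sampler
-------
Metropolis-within-Gibbs with a partially collapsed variance update:

1. The latent ``eta_i`` are conditionally independent given the linear
   predictor, and each conditional (Poisson log-likelihood plus Gaussian
   prior) is log-concave; all n sites are therefore updated at once by a
   vectorized Metropolis-Hastings step with Gaussian independence proposals
   centred at the conditional mode (found by a few Newton iterations) with
   the conditional curvature as precision.  Acceptance is near one and eta
   decorrelates in about one sweep.
2. Variance components (and the 2x2 reaction-norm covariance matrices,
   parameterized as log-variances and atanh correlations) are updated on
   their *marginal* posterior given eta, with every fixed and random effect
   integrated out analytically: first exact univariate slice sampling
   coordinate by coordinate (robust for the heavy-tailed posteriors of
   few-level components such as island and year), then adaptive joint
   random-walk Metropolis moves for correlated directions (proposal
   covariance adapted during burn-in, then frozen).  The marginal
   likelihood falls out of the same joint precision matrix used for the
   effect draw (matrix inversion lemma), so each collapsed evaluation costs
   one Cholesky factorization, and the collapsed update removes the
   funnel-shaped coupling between effects and their variances that cripples
   uncollapsed Gibbs samplers for confounded components (genetic vs
   permanent environment).
3. All fixed effects and every random-effect level are then redrawn in one
   exact joint Gaussian block given the accepted variances; genetic terms
   are whitened through a Cholesky factor of A, so their prior precision is
   diagonal and no A-inverse is ever formed.  The overdispersion variances
   get conjugate inverse-gamma updates.

Priors: diffuse Gaussian on fixed effects; half-Cauchy on every random sd
(half-t, the marginal family that parameter-expanded variance priors
induce) with uniform priors on reaction-norm correlations; weakly
informative inverse-gamma on the residual variances.

The deviance trace, the posterior mean of the latent predictor (for the
conditional-deviance DIC) and all monitored parameters are stored thinned.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
import scipy.linalg as sla
from scipy.special import gammaln

from .errors import (
    ConfigError,
    InvalidArgumentError,
    SamplerError,
    SchemaError,
)
from .pedigree import RelatednessMatrix

INTERCEPT_RANDOM_TERMS = ("genetic", "permanent_env", "year", "island")
SLOPE_RANDOM_TERMS = ("genetic_slopes", "pe_slopes", "individual_slopes")

#: chain keys of the variance components of the partitioned intercept model
INTERCEPT_VARIANCE_KEYS = ("V_A", "V_PE", "V_year", "V_island", "V_resid")

_LOGV_MIN, _LOGV_MAX = -20.0, 10.0
_ATANH_MAX = 8.0


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one animal model."""

    response: str = "count"
    fixed: tuple = (
        "mean_age",
        "delta_age",
        "mean_age:delta_age",
        "year_std",
        "colony_density_std",
        "island_density_std",
    )
    random: tuple = INTERCEPT_RANDOM_TERMS
    residual: str = "homogeneous"  # or "by_age_class"
    gradient: str | None = None  # standardized-age column for slope terms
    family: str = "poisson"  # or "gaussian" (identity link, eta observed)

    def __post_init__(self):
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "random", tuple(self.random))

    @property
    def has_slopes(self) -> bool:
        return any(t in SLOPE_RANDOM_TERMS for t in self.random)

    def validate(self, table: pd.DataFrame, A: RelatednessMatrix | None) -> None:
        needed = [self.response]
        for term in self.fixed:
            needed.extend(term.split(":"))
        if self.gradient:
            needed.append(self.gradient)
        if self.residual == "by_age_class":
            needed.append("age_class")
        elif self.residual != "homogeneous":
            raise ConfigError(f"unknown residual structure: {self.residual!r}")
        missing = sorted(set(c for c in needed if c not in table.columns))
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        unknown = [
            t
            for t in self.random
            if t not in INTERCEPT_RANDOM_TERMS + SLOPE_RANDOM_TERMS
        ]
        if unknown:
            raise ConfigError(f"unknown random term(s): {unknown}")
        if len(set(self.random)) != len(self.random):
            raise ConfigError("duplicate random terms")
        slope_terms = [t for t in self.random if t in SLOPE_RANDOM_TERMS]
        if slope_terms and not self.gradient:
            raise ConfigError("slope terms require a gradient column")
        if "individual_slopes" in self.random and (
            "genetic_slopes" in self.random or "pe_slopes" in self.random
        ):
            raise ConfigError(
                "individual_slopes may not be combined with genetic_slopes/pe_slopes"
            )
        if "genetic" in self.random and "genetic_slopes" in self.random:
            raise ConfigError("genetic_slopes already includes genetic intercepts")
        if "permanent_env" in self.random and "pe_slopes" in self.random:
            raise ConfigError("pe_slopes already includes permanent_env intercepts")
        if ("genetic" in self.random or "genetic_slopes" in self.random) and A is None:
            raise ConfigError("genetic terms require a relationship matrix")
        if self.family not in ("poisson", "gaussian"):
            raise ConfigError(f"unknown family: {self.family!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MCMCConfig:
    """Chain lengths, seed and prior hyperparameters.

    ``prior_sd_scale`` is the half-Cauchy scale on every random-effect
    standard deviation (latent log scale); fixed effects are
    Normal(0, ``prior_beta_var``); the overdispersion variances get an
    inverse-gamma(``prior_resid_shape``, ``prior_resid_rate``) prior.
    """

    n_iter: int = 17000
    burn_in: int = 2600
    thin: int = 12
    seed: int = 0
    prior_beta_var: float = 1e8
    prior_sd_scale: float = 10.0
    prior_resid_shape: float = 0.5
    prior_resid_rate: float = 0.05
    adapt_interval: int = 250  # refresh cadence of the variance-proposal covariance
    variance_substeps: int = 2  # collapsed joint Metropolis substeps per sweep
    slice_interval: int = 1  # run the coordinate slice pass every k-th sweep

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ConfigError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")
        if (self.n_iter - self.burn_in) // self.thin < 2:
            raise ConfigError("fewer than 2 samples would be stored")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PosteriorChains:
    """Thinned MCMC output: one array per monitored parameter, plus metadata."""

    samples: dict
    meta: dict

    def __getitem__(self, key: str) -> np.ndarray:
        return self.samples[key]

    def __contains__(self, key: str) -> bool:
        return key in self.samples

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.samples.values())))

    def keys(self):
        return self.samples.keys()

    def summary(self) -> pd.DataFrame:
        """Posterior mode, median, 95% HPD, ESS and lag-1 autocorrelation."""
        from .summaries import ess_and_autocorr, hpd_interval, posterior_mode

        rows = []
        for key, x in self.samples.items():
            lo, hi = hpd_interval(x, 0.95)
            try:
                diag = ess_and_autocorr(x)
            except Exception:
                diag = {"ess": np.nan, "lag1_autocorr": np.nan}
            rows.append(
                {
                    "parameter": key,
                    "mode": posterior_mode(x),
                    "median": float(np.median(x)),
                    "hpd_lo": lo,
                    "hpd_hi": hi,
                    "ess": diag["ess"],
                    "lag1_autocorr": diag["lag1_autocorr"],
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def save(self, directory) -> None:
        """Chains as CSV (one column per parameter) plus JSON metadata."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.samples).to_csv(directory / "chains.csv", index=False)
        meta = {
            k: v for k, v in self.meta.items() if not isinstance(v, np.ndarray)
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2, default=str))

    @staticmethod
    def load(directory) -> "PosteriorChains":
        directory = Path(directory)
        df = pd.read_csv(directory / "chains.csv")
        meta = json.loads((directory / "meta.json").read_text())
        return PosteriorChains(
            samples={c: df[c].to_numpy() for c in df.columns}, meta=meta
        )


# ---------------------------------------------------------------------------
# internal machinery
# ---------------------------------------------------------------------------

def _chol(P: np.ndarray) -> np.ndarray:
    try:
        return sla.cholesky(P, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * float(np.mean(np.diag(P)))
        try:
            return np.linalg.cholesky(P + jitter * np.eye(P.shape[0]))
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise SamplerError(f"precision matrix not positive definite: {exc}")


def _log_half_cauchy_sd_of_logv(x: float, scale: float) -> float:
    """Log prior density of log-variance x when sd = exp(x/2) is half-Cauchy."""
    sd = np.exp(0.5 * x)
    # p(x) = p(sd) * dsd/dx,  dsd/dx = sd / 2
    return float(-np.log1p((sd / scale) ** 2) + np.log(sd / 2.0))


class _Group:
    """One column group of the joint Gaussian system.

    A group is an indicator design over ``nlev`` levels (record -> level via
    ``idx``), optionally multiplied record-wise by a gradient ``mult``, and
    optionally mixed through the pedigree Cholesky factor ``L`` (genetic
    groups, whitened coordinates).  ``multkey`` is 0 for intercept columns
    and 1 for slope columns, used to look up precomputed Gram matrices.
    """

    __slots__ = ("idx", "mult", "nlev", "L", "multkey", "offset", "term", "comp")

    def __init__(self, idx, mult, nlev, L, multkey, term, comp):
        self.idx, self.mult, self.nlev, self.L = idx, mult, nlev, L
        self.multkey, self.term, self.comp = multkey, term, comp
        self.offset = 0

    def weights(self, base: np.ndarray) -> np.ndarray:
        return base if self.mult is None else base * self.mult

    def project(self, vec: np.ndarray) -> np.ndarray:
        """base' vec: accumulate a record vector to levels (and whiten)."""
        t = np.bincount(self.idx, weights=self.weights(vec), minlength=self.nlev)
        return self.L.T @ t if self.L is not None else t


class _ScalarTerm:
    """One iid or pedigree-structured random-intercept component.

    Unconstrained variance parameter: log V.  The whitened level effects
    ``u`` have prior N(0, V I).
    """

    n_params = 1

    def __init__(self, name, key, idx, nlev, L):
        self.name, self.key = name, key
        self.nlev, self.L = nlev, L
        self.u = np.zeros(nlev)
        self.groups = [_Group(idx, None, nlev, L, 0, self, 0)]
        self.contrib = np.zeros(len(idx))

    def init_params(self) -> list:
        return [np.log(0.1)]

    def variance(self, params) -> float:
        return float(np.exp(params[0]))

    def log_prior(self, params, cfg) -> float:
        x = params[0]
        if not _LOGV_MIN < x < _LOGV_MAX:
            return -np.inf
        return _log_half_cauchy_sd_of_logv(x, cfg.prior_sd_scale)

    def prior_blocks(self, params):
        yield 0, 0, 1.0 / self.variance(params)

    def logdet_prior(self, params) -> float:
        return self.nlev * float(params[0])

    def set_state(self, parts) -> None:
        self.u = parts[0]

    def refresh(self) -> np.ndarray:
        lev = self.L @ self.u if self.L is not None else self.u
        self.contrib = lev[self.groups[0].idx]
        return self.contrib

    def record(self, out, s, params):
        out[self.key][s] = self.variance(params)


class _SlopeTerm:
    """A 2x2 (intercept, slope) random-regression component.

    Unconstrained parameters: (log V_int, log V_slope, atanh r).  Whitened
    level pairs have prior N(0, I (x) G2) with G2 rebuilt from the
    parameters, so positive-definiteness holds by construction.
    """

    n_params = 3

    def __init__(self, name, prefix, idx, g, nlev, L):
        self.name, self.prefix = name, prefix
        self.nlev, self.L, self.g = nlev, L, g
        self.gamma = np.zeros((nlev, 2))
        self.groups = [
            _Group(idx, None, nlev, L, 0, self, 0),
            _Group(idx, g, nlev, L, 1, self, 1),
        ]
        self.contrib = np.zeros(len(idx))

    def init_params(self) -> list:
        return [np.log(0.1), np.log(0.05), 0.0]

    def covariance(self, params) -> np.ndarray:
        v1, v2 = np.exp(params[0]), np.exp(params[1])
        r = np.tanh(params[2])
        c = r * np.sqrt(v1 * v2)
        return np.array([[v1, c], [c, v2]])

    def log_prior(self, params, cfg) -> float:
        x1, x2, z = params
        if not (_LOGV_MIN < x1 < _LOGV_MAX and _LOGV_MIN < x2 < _LOGV_MAX):
            return -np.inf
        if abs(z) > _ATANH_MAX:
            return -np.inf
        r = np.tanh(z)
        # uniform prior on the correlation; Jacobian dr/dz = 1 - r^2
        return (
            _log_half_cauchy_sd_of_logv(x1, cfg.prior_sd_scale)
            + _log_half_cauchy_sd_of_logv(x2, cfg.prior_sd_scale)
            + float(np.log1p(-r * r))
        )

    def prior_blocks(self, params):
        G2 = self.covariance(params)
        det = G2[0, 0] * G2[1, 1] - G2[0, 1] ** 2
        yield 0, 0, G2[1, 1] / det
        yield 1, 1, G2[0, 0] / det
        yield 0, 1, -G2[0, 1] / det

    def logdet_prior(self, params) -> float:
        r = np.tanh(params[2])
        logdet_g2 = float(params[0] + params[1] + np.log1p(-r * r))
        return self.nlev * logdet_g2

    def set_state(self, parts) -> None:
        self.gamma = np.column_stack(parts)

    def refresh(self) -> np.ndarray:
        lev = self.L @ self.gamma if self.L is not None else self.gamma
        idx = self.groups[0].idx
        self.contrib = lev[idx, 0] + lev[idx, 1] * self.g
        return self.contrib

    def record(self, out, s, params):
        V = self.covariance(params)
        p = self.prefix
        out[f"V_{p}_int"][s] = V[0, 0]
        out[f"V_{p}_slope"][s] = V[1, 1]
        out[f"COV_{p}_int_slope"][s] = V[0, 1]
        out[f"r_{p}_int_slope"][s] = float(np.tanh(params[2]))


class _JointSystem:
    """Data-side Gram matrix of the joint Gaussian system, assembled per sweep.

    Structure exploited per cross-product block:

    - genetic x genetic: precomputed pedigree Gram matrices
      ``K_c = L' diag(m_c) L`` per residual class and gradient power;
    - genetic x female-keyed group: each female maps to one pedigree row, so
      the block is a scaled gather of columns of L';
    - genetic x small group (year, island, X): O(n) accumulation into an
      (n_ped x nlev) table, then one thin matrix product with L';
    - everything else: O(n) scatter-adds into small dense blocks.
    """

    def __init__(self, X, terms, class_idx, n_classes):
        self.X = X
        self.n, self.p = X.shape
        self.terms = terms
        self.class_idx = class_idx
        self.n_classes = n_classes
        self.groups = [g for t in terms for g in t.groups]
        off = self.p
        self.term_params_slices = []
        for g in self.groups:
            g.offset = off
            off += g.nlev
        self.q = off
        self.K = {}
        self.jmap = {}
        gen_groups = [g for g in self.groups if g.L is not None]
        if gen_groups:
            L = gen_groups[0].L
            idx = gen_groups[0].idx
            N = gen_groups[0].nlev
            powers = sorted(
                {ga.multkey + gb.multkey for ga in gen_groups for gb in gen_groups}
            )
            g_mult = next((g.mult for g in gen_groups if g.mult is not None), None)
            for power in powers:
                w = np.ones(self.n) if not power else g_mult ** power
                stacks = []
                for c in range(n_classes):
                    m = np.bincount(idx, weights=w * (class_idx == c), minlength=N)
                    stacks.append(L.T @ (m[:, None] * L))
                self.K[power] = np.stack(stacks)
            for g in self.groups:
                if g.L is None and self._is_female_keyed(g, idx):
                    jm = np.zeros(g.nlev, dtype=np.intp)
                    jm[g.idx] = idx
                    self.jmap[id(g)] = jm

    @staticmethod
    def _is_female_keyed(group, gen_idx) -> bool:
        """True when every level of ``group`` maps to a single pedigree row."""
        first = np.full(group.nlev, -1, dtype=np.intp)
        first[group.idx[::-1]] = gen_idx[::-1]
        return bool(np.all(first[group.idx] == gen_idx))

    def _cross(self, ga: _Group, gb: _Group, rinv, w_class) -> np.ndarray:
        if ga.L is not None and gb.L is not None:
            power = ga.multkey + gb.multkey
            return np.tensordot(w_class, self.K[power], axes=1)
        if ga.L is None and gb.L is not None:
            return self._cross(gb, ga, rinv, w_class).T
        w = gb.weights(ga.weights(rinv))
        if ga.L is not None:  # gb has no L
            jm = self.jmap.get(id(gb))
            if jm is not None:
                col_w = np.bincount(gb.idx, weights=w, minlength=gb.nlev)
                return ga.L.T[:, jm] * col_w
            T = np.zeros((ga.nlev, gb.nlev))
            np.add.at(T, (ga.idx, gb.idx), w)
            return ga.L.T @ T
        out = np.zeros((ga.nlev, gb.nlev))
        np.add.at(out, (ga.idx, gb.idx), w)
        return out

    def assemble(self, eta, rinv, w_class, prior_beta_var):
        """Data Gram matrix (incl. the fixed-effect prior) and rhs b."""
        q = self.q
        M0 = np.zeros((q, q))
        b = np.empty(q)
        X, p = self.X, self.p
        Xw = X * rinv[:, None]
        M0[:p, :p] = Xw.T @ X
        M0[np.diag_indices(p)] += 1.0 / prior_beta_var
        b[:p] = X.T @ (rinv * eta)
        for g in self.groups:
            sl = slice(g.offset, g.offset + g.nlev)
            blk = np.empty((p, g.nlev))
            for k in range(p):
                blk[k] = g.project(Xw[:, k])
            M0[:p, sl] = blk
            M0[sl, :p] = blk.T
            b[sl] = g.project(rinv * eta)
        for i, ga in enumerate(self.groups):
            sa = slice(ga.offset, ga.offset + ga.nlev)
            for gb in self.groups[i:]:
                sb = slice(gb.offset, gb.offset + gb.nlev)
                blk = self._cross(ga, gb, rinv, w_class)
                M0[sa, sb] += blk
                if gb is not ga:
                    M0[sb, sa] += blk.T
        return M0, b

    def with_priors(self, M0: np.ndarray, params_by_term) -> np.ndarray:
        M = M0.copy()
        for t, params in zip(self.terms, params_by_term):
            for ca, cb, val in t.prior_blocks(params):
                ga, gb = t.groups[ca], t.groups[cb]
                ia = np.arange(ga.offset, ga.offset + ga.nlev)
                ib = np.arange(gb.offset, gb.offset + gb.nlev)
                M[ia, ib] += val
                if ca != cb:
                    M[ib, ia] += val
        return M

    def collapsed_loglik(self, M: np.ndarray, b: np.ndarray, params_by_term):
        """log p(eta | variances) up to terms constant within one sweep.

        Uses log|Sigma| = log|R| + log|D| + log|M| and
        eta' Sigma^-1 eta = eta' R^-1 eta - b' M^-1 b; the R-only pieces are
        constant during the variance update and omitted.
        """
        Lc = _chol(M)
        logdet_m = 2.0 * float(np.sum(np.log(np.diag(Lc))))
        half = solve_triangular(Lc, b, lower=True)
        quad = float(half @ half)
        logdet_d = sum(
            t.logdet_prior(params) for t, params in zip(self.terms, params_by_term)
        )
        return -0.5 * (logdet_d + logdet_m) + 0.5 * quad, Lc, half

    def draw_effects(self, Lc, half, rng):
        """theta | variances, eta from the cached factorization."""
        mean = solve_triangular(Lc, half, lower=True, trans="T")
        z = rng.standard_normal(self.q)
        theta = mean + solve_triangular(Lc, z, lower=True, trans="T")
        beta = theta[: self.p]
        for t in self.terms:
            parts = [theta[g.offset : g.offset + g.nlev] for g in t.groups]
            t.set_state(parts)
        return beta


def _with_coord(vec: np.ndarray, j: int, value: float) -> np.ndarray:
    out = vec.copy()
    out[j] = value
    return out


def _poisson_deviance(y, eta, log_fact):
    mu = np.exp(np.minimum(eta, 30.0))
    return -2.0 * float(y @ eta - mu.sum() - log_fact)


def _sample_eta_poisson(eta, y, mu_lin, rinv, rng):
    """Vectorized MH update of all latent log-rates at once.

    The conditional target for site i is
    ``y eta - exp(eta) - rinv (eta - mu)^2 / 2`` (log-concave).  A Gaussian
    independence proposal is built at its mode (Newton, damped steps) with
    the local curvature as precision; the proposal does not depend on the
    current state, so the MH ratio uses only target and proposal densities.
    """
    m = np.log(y + 0.5)
    for _ in range(12):
        grad = y - np.exp(np.minimum(m, 30.0)) - rinv * (m - mu_lin)
        curv = np.exp(np.minimum(m, 30.0)) + rinv
        m += np.clip(grad / curv, -5.0, 5.0)
    curv = np.exp(np.minimum(m, 30.0)) + rinv
    sd = 1.0 / np.sqrt(curv)
    prop = m + sd * rng.standard_normal(len(eta))

    def log_target(x):
        return y * x - np.exp(np.minimum(x, 30.0)) - 0.5 * rinv * (x - mu_lin) ** 2

    logr = (
        log_target(prop)
        - log_target(eta)
        + 0.5 * curv * ((prop - m) ** 2 - (eta - m) ** 2)
    )
    accepted = np.log(rng.random(len(eta))) < logr
    return np.where(accepted, prop, eta), accepted


def _build_design(table: pd.DataFrame, fixed) -> tuple:
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for term in fixed:
        parts = term.split(":")
        col = np.ones(len(table))
        for p in parts:
            col = col * table[p].to_numpy(dtype=float)
        cols.append(col)
        names.append(term)
    return np.column_stack(cols), names


def fit_glmm_animal(
    table: pd.DataFrame,
    A: RelatednessMatrix | None,
    spec: ModelSpec,
    cfg: MCMCConfig | None = None,
) -> PosteriorChains:
    """Fit one animal model by MCMC and return thinned posterior chains.

    ``table`` must contain the response, every fixed-effect column, a
    ``female_id`` column for individual-level terms, and ``year``/``island``
    columns for those intercepts.  ``A`` must cover every phenotyped female
    (it may contain additional ancestors).
    """
    cfg = cfg or MCMCConfig()
    spec.validate(table, A)
    rng = np.random.default_rng([cfg.seed, 701])
    n = len(table)
    y = table[spec.response].to_numpy(dtype=float)
    if spec.family == "poisson" and (np.any(y < 0) or np.any(y != np.rint(y))):
        raise InvalidArgumentError("poisson response must be non-negative integers")

    X, fixed_names = _build_design(table, spec.fixed)

    if spec.residual == "by_age_class":
        labels = table["age_class"].to_numpy(dtype=int)
        classes = np.unique(labels)
        class_idx = np.searchsorted(classes, labels)
        n_classes = len(classes)
    else:
        class_idx = np.zeros(n, dtype=int)
        n_classes = 1

    if spec.has_slopes:
        g = table[spec.gradient].to_numpy(dtype=float)
        if abs(float(np.mean(g))) > 1e-6:
            raise InvalidArgumentError(
                f"gradient column {spec.gradient!r} must be mean-centred"
            )

    L_A = None
    if "genetic" in spec.random or "genetic_slopes" in spec.random:
        fem = table["female_id"].astype(str)
        phen = fem.unique()
        # breeding values of unphenotyped ancestors carry no data: the
        # marginal prior of the phenotyped females' values is simply the
        # corresponding submatrix of A, so only those levels are sampled
        sub = A.indices_of(phen)
        A_phen = A.values[np.ix_(sub, sub)] + 1e-8 * np.eye(len(sub))
        phen_pos = {f: k for k, f in enumerate(phen)}
        a_idx = np.array([phen_pos[f] for f in fem], dtype=np.intp)
        n_gen = len(phen)
        try:
            L_A = np.linalg.cholesky(A_phen)
        except np.linalg.LinAlgError as exc:
            raise SamplerError(f"relationship matrix is not positive definite: {exc}")
    if {"permanent_env", "individual_slopes", "pe_slopes"} & set(spec.random):
        fem_codes, fem_levels = pd.factorize(table["female_id"].astype(str))

    terms = []
    for name in spec.random:
        if name == "genetic":
            terms.append(_ScalarTerm(name, "V_A", a_idx, n_gen, L_A))
        elif name == "permanent_env":
            terms.append(_ScalarTerm(name, "V_PE", fem_codes, len(fem_levels), None))
        elif name == "year":
            codes, levels = pd.factorize(table["year"])
            terms.append(_ScalarTerm(name, "V_year", codes, len(levels), None))
        elif name == "island":
            codes, levels = pd.factorize(table["island"])
            terms.append(_ScalarTerm(name, "V_island", codes, len(levels), None))
        elif name == "genetic_slopes":
            terms.append(_SlopeTerm(name, "A", a_idx, g, n_gen, L_A))
        elif name == "pe_slopes":
            terms.append(_SlopeTerm(name, "PE", fem_codes, g, len(fem_levels), None))
        elif name == "individual_slopes":
            terms.append(_SlopeTerm(name, "I", fem_codes, g, len(fem_levels), None))

    system = _JointSystem(X, terms, class_idx, n_classes)

    # unconstrained variance-parameter vector and its adaptive RW proposal
    v_params = []
    slices = []
    pos = 0
    for t in terms:
        init = t.init_params()
        slices.append(slice(pos, pos + len(init)))
        v_params.extend(init)
        pos += len(init)
    v_params = np.array(v_params)
    d_v = len(v_params)
    prop_chol = 0.3 * np.eye(d_v) if d_v else None
    v_hist = []

    def split_params(vec):
        return [vec[sl] for sl in slices]

    def log_prior(vec) -> float:
        return sum(
            t.log_prior(p, cfg) for t, p in zip(terms, split_params(vec))
        )

    poisson = spec.family == "poisson"
    eta = np.log(y + 0.5) if poisson else y.astype(float).copy()
    beta = np.zeros(X.shape[1])
    beta[0] = float(np.mean(eta))
    Xb = X @ beta
    V_resid = np.full(n_classes, 0.3)
    n_per_class = np.bincount(class_idx, minlength=n_classes)
    total_random = np.zeros(n)
    log_fact = float(gammaln(y + 1.0).sum()) if poisson else 0.0
    eta_acc = 0.0
    v_acc = 0

    n_stored = cfg.n_stored
    out = {f"beta:{nm}": np.empty(n_stored) for nm in fixed_names}
    for t in terms:
        if isinstance(t, _ScalarTerm):
            out[t.key] = np.empty(n_stored)
        else:
            for k in (
                f"V_{t.prefix}_int",
                f"V_{t.prefix}_slope",
                f"COV_{t.prefix}_int_slope",
                f"r_{t.prefix}_int_slope",
            ):
                out[k] = np.empty(n_stored)
    if n_classes == 1:
        out["V_resid"] = np.empty(n_stored)
    else:
        for c in range(n_classes):
            out[f"V_resid_{c + 1}"] = np.empty(n_stored)
    out["deviance"] = np.empty(n_stored)
    fit_mean = np.zeros(n)
    vres_mean = np.zeros(n_classes)

    s = 0
    for it in range(cfg.n_iter):
        rinv_class = 1.0 / V_resid
        rinv = rinv_class[class_idx]
        if poisson:
            mu_lin = Xb + total_random
            eta, accepted = _sample_eta_poisson(eta, y, mu_lin, rinv, rng)
            eta_acc += float(accepted.mean())

        # collapsed variance update: slice sampling per coordinate plus a
        # joint Metropolis move, both on the marginal of eta
        M0, b = system.assemble(eta, rinv, rinv_class, cfg.prior_beta_var)

        def eval_lp(vec):
            parts = split_params(vec)
            prior = log_prior(vec)
            if not np.isfinite(prior):
                return -np.inf, None, None
            Mv = system.with_priors(M0, parts)
            ll, Lv, half_v = system.collapsed_loglik(Mv, b, parts)
            return ll + prior, Lv, half_v

        cur_lp, Lc, half = eval_lp(v_params)
        if d_v and it % cfg.slice_interval == 0:
            # exact univariate slice sampling, coordinate by coordinate:
            # robust for the heavy-tailed few-level components (island, year)
            widths = np.sqrt(np.diag(prop_chol @ prop_chol.T))
            for j in range(d_v):
                logu = cur_lp + np.log(rng.random())
                w = max(2.5 * widths[j], 0.2)
                x0 = v_params[j]
                lo = x0 - w * rng.random()
                hi = lo + w
                # bounded stepping-out with randomized budget split (Neal 2003)
                j_steps = int(rng.integers(0, 5))
                k_steps = 4 - j_steps
                for _ in range(j_steps):
                    lp_lo, _, _ = eval_lp(_with_coord(v_params, j, lo))
                    if lp_lo <= logu:
                        break
                    lo -= w
                for _ in range(k_steps):
                    lp_hi, _, _ = eval_lp(_with_coord(v_params, j, hi))
                    if lp_hi <= logu:
                        break
                    hi += w
                while True:  # shrinkage
                    x1 = lo + (hi - lo) * rng.random()
                    cand = _with_coord(v_params, j, x1)
                    lp1, L1, h1 = eval_lp(cand)
                    if lp1 > logu:
                        v_params = cand
                        cur_lp, Lc, half = lp1, L1, h1
                        break
                    if x1 < x0:
                        lo = x1
                    else:
                        hi = x1
                    if hi - lo < 1e-12:
                        break
        if d_v:
            # joint Metropolis moves catch correlated directions
            for _ in range(cfg.variance_substeps):
                prop_v = v_params + prop_chol @ rng.standard_normal(d_v)
                prop_lp, Lp, half_p = eval_lp(prop_v)
                if np.log(rng.random()) < prop_lp - cur_lp:
                    v_params = prop_v
                    Lc, half = Lp, half_p
                    cur_lp = prop_lp
                    v_acc += 1
            if it < cfg.burn_in:
                v_hist.append(v_params.copy())
                if (it + 1) % cfg.adapt_interval == 0 and len(v_hist) > 4 * d_v:
                    emp = np.cov(np.array(v_hist[len(v_hist) // 2 :]).T)
                    emp = np.atleast_2d(emp) + 1e-6 * np.eye(d_v)
                    prop_chol = np.linalg.cholesky((2.38 ** 2 / d_v) * emp)

        # exact joint draw of all fixed and random effects
        beta = system.draw_effects(Lc, half, rng)
        Xb = X @ beta
        total_random = np.zeros(n)
        for t in terms:
            total_random += t.refresh()

        # conjugate overdispersion / residual variances
        e = eta - Xb - total_random
        sse = np.bincount(class_idx, weights=e * e, minlength=n_classes)
        V_resid = (cfg.prior_resid_rate + 0.5 * sse) / rng.gamma(
            cfg.prior_resid_shape + 0.5 * n_per_class
        )

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            for k, nm in enumerate(fixed_names):
                out[f"beta:{nm}"][s] = beta[k]
            for t, params in zip(terms, split_params(v_params)):
                t.record(out, s, params)
            if n_classes == 1:
                out["V_resid"][s] = V_resid[0]
            else:
                for c in range(n_classes):
                    out[f"V_resid_{c + 1}"][s] = V_resid[c]
            if poisson:
                out["deviance"][s] = _poisson_deviance(y, eta, log_fact)
                fit_mean += eta
            else:
                mu_fit = Xb + total_random
                ve = V_resid[class_idx]
                out["deviance"][s] = float(
                    np.sum(np.log(2.0 * np.pi * ve) + (y - mu_fit) ** 2 / ve)
                )
                fit_mean += mu_fit
            vres_mean += V_resid
            s += 1

    fit_mean /= s
    vres_mean /= s
    if not np.isfinite(out["deviance"]).all():
        raise SamplerError("divergent chain: non-finite deviance encountered")
    if poisson:
        d_at_mean = _poisson_deviance(y, fit_mean, log_fact)
    else:
        ve = vres_mean[class_idx]
        d_at_mean = float(np.sum(np.log(2.0 * np.pi * ve) + (y - fit_mean) ** 2 / ve))

    meta = {
        "spec": spec.to_dict(),
        "config": asdict(cfg),
        "n_obs": n,
        "n_females": int(table["female_id"].nunique()),
        "trait_mean": float(np.mean(y)),
        "d_at_mean": d_at_mean,
        "model_kind": "random_regression" if spec.has_slopes else "intercept",
        "fixed_names": fixed_names,
        "eta_accept_rate": eta_acc / cfg.n_iter if poisson else None,
        "variance_accept_rate": (
            v_acc / (cfg.n_iter * cfg.variance_substeps) if d_v else None
        ),
        "eta_mean": fit_mean,
    }
    return PosteriorChains(samples=out, meta=meta)


def fit_random_regression(
    table: pd.DataFrame,
    A: RelatednessMatrix | None,
    level: str = "individual",
    gradient: str = "age_std",
    cfg: MCMCConfig | None = None,
    fixed: tuple | None = None,
    response: str = "count",
) -> PosteriorChains:
    """Random-regression reaction-norm model over a standardized age gradient.

    ``level='individual'`` fits one unstructured 2x2 (intercept, slope)
    covariance per female (I x Age); ``level='genetic+pe'`` splits it into an
    additive genetic block with covariance ``A (x) G2`` and an independent
    permanent-environment block (G x Age + PE x Age).  Five heterogeneous
    residual variances over age classes are always used, following the
    convention that residual heterogeneity must be modelled before slope
    variance is interpreted.
    """
    if level == "individual":
        random = ("individual_slopes", "year", "island")
    elif level == "genetic+pe":
        random = ("genetic_slopes", "pe_slopes", "year", "island")
    else:
        raise InvalidArgumentError(f"unknown level: {level!r}")
    if fixed is None:
        fixed = (gradient, "year_std", "colony_density_std", "island_density_std")
    spec = ModelSpec(
        response=response,
        fixed=tuple(fixed),
        random=random,
        residual="by_age_class",
        gradient=gradient,
    )
    return fit_glmm_animal(table, A, spec, cfg)
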