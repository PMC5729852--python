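"""Bayesian estimation of the joint IRT + moderated-ACE twin model.

The estimator couples the biometric variance-moderation model with a
Rasch/OPLM measurement model and samples the joint posterior of the eight
structural parameters (mu, beta1m and the six log-variance coefficients),
the latent traits, any missing family moderators (treated as latent
Bernoulli variables with zygosity-specific Beta-distributed probabilities),
by Markov chain Monte Carlo.  Item difficulties and discriminations are
fixed known constants, which anchors the latent scale.

The class follows scikit-learn estimator conventions: hyperparameters in
``__init__``, data in ``fit``, fitted results in trailing-underscore
attributes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._kernel import AceKernel, KernelPriors
from .evaluate import hpd_interval
from .model import AceMParams, DZ_GENETIC_CORRELATION, ItemBank
from .simulate import TwinData

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "PosteriorSamples",
    "LatentState",
    "IrtAceModel",
    "fit_irt_ace",
    "log_likelihood",
    "apply_moderator_policy",
]

_PARAM_NAMES = list(AceMParams.names()) + ["pi_mz", "pi_dz"]


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors for the structural parameters.

    Normal(loc, scale^2) on the mean parameters mu and beta1m; a common
    Normal(loc, scale^2) on each of the six log-variance coefficients (wide
    on the log scale, preventing numerical overflow of the exponential);
    Beta(a, b) hyperpriors on the zygosity-specific moderator probabilities.
    """

    mu_loc: float = 0.0
    mu_scale: float = 10.0
    beta1m_loc: float = 0.0
    beta1m_scale: float = 10.0
    logvar_loc: float = 0.0
    logvar_scale: float = 2.0
    pi_mz_a: float = 1.0
    pi_mz_b: float = 1.0
    pi_dz_a: float = 1.0
    pi_dz_b: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mu_scale", "beta1m_scale", "logvar_scale",
                     "pi_mz_a", "pi_mz_b", "pi_dz_a", "pi_dz_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PriorSpec.{name} must be strictly positive")

    def to_kernel(self) -> KernelPriors:
        return KernelPriors(**{f.name: getattr(self, f.name) for f in self.__dataclass_fields__.values()})

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class McmcConfig:
    """Chain-length configuration.

    ``paper_scale`` reproduces the published protocol (5,000 adaptation,
    50,000 burn-in, 25,000 retained draws from one chain); the default is a
    short preset suitable for simulation sweeps, where convergence is
    checked by diagnostics rather than iteration count.
    """

    n_adapt: int = 1000
    n_burnin: int = 1000
    n_keep: int = 3000
    n_chains: int = 1
    thin: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_adapt < 0 or self.n_burnin < 0:
            raise ValueError("n_adapt and n_burnin must be >= 0")
        if self.n_keep < 1 or self.n_chains < 1 or self.thin < 1:
            raise ValueError("n_keep, n_chains and thin must be >= 1")

    @classmethod
    def paper_scale(cls, **kw) -> "McmcConfig":
        return cls(n_adapt=5000, n_burnin=50_000, n_keep=25_000, n_chains=1, **kw)

    @classmethod
    def quick(cls, **kw) -> "McmcConfig":
        """Miniature preset for smoke tests and CLI examples."""
        return cls(n_adapt=200, n_burnin=200, n_keep=400, **kw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class PosteriorSamples:
    """Labeled MCMC draws with chain structure.

    ``draws`` maps parameter name to an (n_chains, n_draws) array.  Latent
    traits are stored (thinned) only on request; they are large and rarely
    needed downstream.
    """

    draws: dict
    theta: Optional[np.ndarray] = None  # (n_chains, n_theta_draws, n, 2)

    @property
    def names(self) -> list:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        return np.asarray(self.draws[name]).ravel()

    def mean(self, name: str) -> float:
        return float(self.pooled(name).mean())

    def sd(self, name: str) -> float:
        return float(self.pooled(name).std(ddof=1))

    def hpd(self, name: str, prob: float = 0.95):
        return hpd_interval(self.pooled(name), prob)

    def derived(self) -> dict:
        """Variance-scale transforms of the draws (plus heritability)."""
        out = {}
        if not {"beta0a", "beta0c", "beta0e"} <= set(self.draws):
            return out
        for x in ("a", "c", "e"):
            out[f"exp_beta0{x}"] = np.exp(np.asarray(self.draws[f"beta0{x}"]))
        total = sum(out[f"exp_beta0{x}"] for x in ("a", "c", "e"))
        out["h2"] = out["exp_beta0a"] / total
        return out

    def summary(self, prob: float = 0.95, derived: bool = True) -> pd.DataFrame:
        rows = []
        items = {k: np.asarray(v) for k, v in self.draws.items()}
        if derived:
            items.update(self.derived())
        for name, arr in items.items():
            pooled = arr.ravel()
            lo, hi = hpd_interval(pooled, prob)
            rows.append(
                {
                    "parameter": name,
                    "mean": pooled.mean(),
                    "sd": pooled.std(ddof=1),
                    "hpd_lower": lo,
                    "hpd_upper": hi,
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def to_frame(self) -> pd.DataFrame:
        """Long table (chain, iteration, parameter, value)."""
        frames = []
        for name, arr in self.draws.items():
            arr = np.asarray(arr)
            n_chains, n_draws = arr.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(n_chains), n_draws),
                        "iteration": np.tile(np.arange(n_draws), n_chains),
                        "parameter": name,
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PosteriorSamples":
        draws = {}
        for name, g in df.groupby("parameter", sort=False):
            n_chains = g["chain"].nunique()
            draws[name] = (
                g.sort_values(["chain", "iteration"])["value"].to_numpy().reshape(n_chains, -1)
            )
        return cls(draws=draws)


# ---------------------------------------------------------------------------
# data validation and policies
# ---------------------------------------------------------------------------

def apply_moderator_policy(obs: pd.DataFrame, policy: str) -> pd.DataFrame:
    """Missing-moderator handling: ``impute`` keeps all families (the
    moderator is then sampled as a latent Bernoulli variable inside the
    fit); ``complete-cases`` drops families whose moderator is missing."""
    if policy == "impute":
        return obs
    if policy == "complete-cases":
        keep = obs.groupby("family_id")["moderator"].transform(lambda s: s.notna().all())
        return obs[keep].reset_index(drop=True)
    raise ValueError(f"unknown missing-moderator policy {policy!r}")


def _validate_obs(obs: pd.DataFrame, item_columns=None):
    """Check the wide per-twin table and return per-family arrays."""
    required = {"family_id", "twin", "zygosity", "moderator"}
    missing_cols = required - set(obs.columns)
    if missing_cols:
        raise ValueError(f"dataset is missing required columns: {sorted(missing_cols)}")
    obs = obs.sort_values(["family_id", "twin"], kind="stable")
    counts = obs.groupby("family_id").size()
    if not (counts == 2).all():
        bad = counts[counts != 2].index.tolist()[:5]
        raise ValueError(f"every family must contribute exactly two twins; offending families: {bad}")
    zyg = obs["zygosity"].astype(str).str.upper()
    if not zyg.isin(["MZ", "DZ"]).all():
        raise ValueError("zygosity must be 'MZ' or 'DZ'")
    fam = obs.groupby("family_id", sort=True)
    if (fam["zygosity"].nunique() != 1).any():
        raise ValueError("zygosity must be constant within a family")
    mod_n = fam["moderator"].nunique(dropna=False)
    if (mod_n != 1).any():
        raise ValueError(
            "the moderator is family-level and must be identical for both twins; "
            "individual-level moderators are not supported"
        )
    mz = (fam["zygosity"].first().str.upper() == "MZ").to_numpy()
    if mz.all() or (~mz).all():
        raise ValueError("both MZ and DZ families are required to identify the model")
    moderator = fam["moderator"].first().to_numpy(dtype=float)
    family_ids = fam.size().index.to_numpy()

    responses = None
    if item_columns:
        resp = obs[item_columns].to_numpy(dtype=float)
        all_missing = np.all(~np.isfinite(resp), axis=0)
        if all_missing.any():
            bad = [item_columns[k] for k in np.flatnonzero(all_missing)]
            raise ValueError(f"item column(s) with no observed responses: {bad}")
        valid = np.isfinite(resp)
        if not np.isin(resp[valid], (0.0, 1.0)).all():
            raise ValueError("item responses must be 0, 1 or missing")
        responses = resp.reshape(mz.size, 2, len(item_columns))
    return family_ids, mz, moderator, responses


def _resolve_data(X, item_bank):
    if isinstance(X, TwinData):
        if item_bank is None:
            item_bank = X.bank
        X = X.obs
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a TwinData or a per-twin DataFrame")
    return X, item_bank


# ---------------------------------------------------------------------------
# augmented-form joint density (oracle form of the likelihood)
# ---------------------------------------------------------------------------

@dataclass
class LatentState:
    """Explicit latent-variable state of the augmented hierarchy.

    ``family_effect`` is the familial effect F_i for MZ families and the
    common-environmental effect C_i for DZ families; ``a1``/``a2`` are the
    DZ family-level genetic value and per-twin Mendelian sampling terms
    (ignored for MZ families).
    """

    theta: np.ndarray  # (n, 2)
    family_effect: np.ndarray  # (n,)
    a1: Optional[np.ndarray] = None  # (n,)
    a2: Optional[np.ndarray] = None  # (n, 2)


def _norm_logpdf(x, mean, var):
    return -0.5 * (math.log(2 * math.pi) + np.log(var) + (x - mean) ** 2 / var)


def log_likelihood(
    mz,
    moderator,
    state: LatentState,
    params: AceMParams,
    responses=None,
    bank: Optional[ItemBank] = None,
) -> float:
    """Joint log density of the latent hierarchy and the observed responses.

    This is the fully augmented form: MZ families contribute
    Normal(F_i; mu+beta1m*M, s2A+s2C) and Normal(theta_ij; F_i, s2E); DZ
    families contribute Normal(C_i; mu+beta1m*M, s2C), standard-normal
    densities for the genetic value A1_i and Mendelian terms A2_ij, and
    Normal(theta_ij; C_i + sigma_A*(sqrt(.5)A1_i + sqrt(.5)A2_ij), s2E).
    Observed item responses add Bernoulli-logistic terms; missing responses
    are skipped.  The collapsed kernel integrates the family-level terms out
    analytically; the two forms are checked against each other in the tests.
    """
    mz = np.asarray(mz, dtype=bool)
    M = np.asarray(moderator, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("log_likelihood requires fully observed moderators")
    theta = np.asarray(state.theta, dtype=float)
    if theta.shape != (mz.size, 2):
        raise ValueError("state.theta must have shape (n_families, 2)")
    s2a, s2c, s2e = params.variances(M)
    s2a, s2c, s2e = (np.broadcast_to(s, M.shape) for s in (s2a, s2c, s2e))
    mean = params.mu + params.beta1m * M
    fe = np.asarray(state.family_effect, dtype=float)

    total = 0.0
    if mz.any():
        i = mz
        total += _norm_logpdf(fe[i], mean[i], (s2a + s2c)[i]).sum()
        total += _norm_logpdf(theta[i], fe[i, None], s2e[i, None]).sum()
    if (~mz).any():
        i = ~mz
        if state.a1 is None or state.a2 is None:
            raise ValueError("DZ families require a1 and a2 in the latent state")
        a1 = np.asarray(state.a1, dtype=float)
        a2 = np.asarray(state.a2, dtype=float)
        w = math.sqrt(DZ_GENETIC_CORRELATION)
        total += _norm_logpdf(fe[i], mean[i], s2c[i]).sum()
        total += _norm_logpdf(a1[i], 0.0, 1.0).sum()
        total += _norm_logpdf(a2[i], 0.0, 1.0).sum()
        a3 = np.sqrt(s2a[i])[:, None] * (w * a1[i][:, None] + w * a2[i])
        total += _norm_logpdf(theta[i], fe[i][:, None] + a3, s2e[i][:, None]).sum()

    if responses is not None:
        if bank is None:
            raise ValueError("an item bank is required when responses are given")
        resp = np.asarray(responses, dtype=float)  # (n, 2, K)
        z = bank.discrimination * (theta[..., None] - bank.difficulty)
        ll = np.where(np.isfinite(resp), resp * z - np.logaddexp(0.0, z), 0.0)
        total += float(ll.sum())
    return float(total)


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class IrtAceModel(BaseEstimator):
    """Joint Rasch-IRT + moderated-ACE estimator for twin item data.

    Parameters
    ----------
    priors : PriorSpec, optional
    mcmc : McmcConfig, optional
    missing_moderator : {'impute', 'complete-cases'}
        Latent-Bernoulli imputation of missing family moderators (default)
        or listwise deletion of those families.
    store_theta : bool
        Keep thinned draws of the latent traits in the posterior object.
    theta_thin : int
        Additional thinning applied to stored latent-trait draws.
    random_state : int, optional
        Seed used when the McmcConfig carries none.

    Attributes
    ----------
    posterior_ : PosteriorSamples
    summary_ : pandas.DataFrame
        Posterior mean, SD and 95% HPD per parameter (including the
        variance-scale transforms exp(beta0x) and heritability).
    n_pairs_, n_mz_, n_dz_ : int
    item_columns_ : list of str
    bank_ : ItemBank
    """

    _has_item_layer = True

    def __init__(
        self,
        priors: Optional[PriorSpec] = None,
        mcmc: Optional[McmcConfig] = None,
        missing_moderator: str = "impute",
        store_theta: bool = False,
        theta_thin: int = 50,
        random_state: Optional[int] = None,
    ):
        self.priors = priors
        self.mcmc = mcmc
        self.missing_moderator = missing_moderator
        self.store_theta = store_theta
        self.theta_thin = theta_thin
        self.random_state = random_state

    # -- hooks specialized by the sum-score subclass -------------------
    def _prepare(self, X, item_bank):
        X, item_bank = _resolve_data(X, item_bank)
        if item_bank is None:
            raise ValueError("an item bank (fixed difficulties) is required for the IRT model")
        item_columns = [c for c in X.columns if c.startswith("item_")]
        if len(item_columns) != len(item_bank):
            raise ValueError(
                f"item bank has {len(item_bank)} items but the dataset has "
                f"{len(item_columns)} item columns"
            )
        obs = apply_moderator_policy(X, self.missing_moderator)
        family_ids, mz, moderator, responses = _validate_obs(obs, item_columns)
        self.item_columns_ = item_columns
        self.bank_ = item_bank
        return family_ids, mz, moderator, responses

    def _init_theta(self, responses):
        """Starting traits from logit-transformed proportion correct."""
        bank = self.bank_
        obs_mask = np.isfinite(responses)
        k = obs_mask.sum(axis=2)
        s = np.where(obs_mask, responses, 0.0).sum(axis=2)
        p = (s + 0.5) / (k + 1.0)
        return float(bank.difficulty.mean()) + np.log(p / (1 - p)) / float(
            bank.discrimination.mean()
        )

    def _make_kernel(self, mz, moderator, responses, priors, rng):
        theta0 = self._init_theta(responses)
        return AceKernel(
            theta=theta0,
            mz=mz,
            moderator=moderator,
            priors=priors.to_kernel(),
            rng=rng,
            responses=responses,
            difficulty=self.bank_.difficulty,
            discrimination=self.bank_.discrimination,
        )

    # ------------------------------------------------------------------
    def fit(self, X, y=None, *, item_bank=None):
        """Sample the joint posterior for one dataset.

        ``X`` is a :class:`~twinirt.simulate.TwinData` or the per-twin wide
        DataFrame (family_id, twin, zygosity, moderator, item_*).  ``y`` is
        ignored (present for scikit-learn API compatibility).
        """
        priors = self.priors if self.priors is not None else PriorSpec()
        mcmc = self.mcmc if self.mcmc is not None else McmcConfig()
        family_ids, mz, moderator, payload = self._prepare(X, item_bank)

        seed = mcmc.seed if mcmc.seed is not None else self.random_state
        root = np.random.SeedSequence(seed)
        chain_seeds = root.spawn(mcmc.n_chains)

        draws = {name: np.empty((mcmc.n_chains, mcmc.n_keep // mcmc.thin)) for name in _PARAM_NAMES}
        theta_draws = [] if self.store_theta else None
        for chain in range(mcmc.n_chains):
            rng = np.random.default_rng(chain_seeds[chain])
            kern = self._make_kernel(mz, moderator, payload, priors, rng)
            for _ in range(mcmc.n_adapt + mcmc.n_burnin):
                kern.step(adapt=True)
            kern.finalize_adaptation()
            chain_theta = []
            kept = 0
            for it in range(mcmc.n_keep):
                kern.step(adapt=False)
                if (it + 1) % mcmc.thin == 0:
                    state = kern.state_vector()
                    for j, name in enumerate(_PARAM_NAMES):
                        draws[name][chain, kept] = state[j]
                    if theta_draws is not None and kept % self.theta_thin == 0:
                        chain_theta.append(kern.theta.copy())
                    kept += 1
            if theta_draws is not None:
                theta_draws.append(np.asarray(chain_theta))

        self.family_ids_ = family_ids
        self.n_pairs_ = int(mz.size)
        self.n_mz_ = int(mz.sum())
        self.n_dz_ = int((~mz).sum())
        self.priors_ = priors
        self.mcmc_ = mcmc
        self.posterior_ = PosteriorSamples(
            draws=draws,
            theta=np.asarray(theta_draws) if theta_draws else None,
        )
        self.summary_ = self.posterior_.summary()
        return self

    # ------------------------------------------------------------------
    def params_posterior_mean(self) -> AceMParams:
        """Posterior-mean structural parameters as an AceMParams."""
        self._check_fitted()
        return AceMParams(**{n: self.posterior_.mean(n) for n in AceMParams.names()})

    def heritability_posterior_mean(self) -> float:
        self._check_fitted()
        return float(self.posterior_.derived()["h2"].mean())

    def _check_fitted(self) -> None:
        if not hasattr(self, "posterior_"):
            raise RuntimeError("this estimator has not been fitted yet")


def fit_irt_ace(data, item_bank=None, priors=None, mcmc=None, **kwargs) -> IrtAceModel:
    """Functional wrapper over :class:`IrtAceModel`."""
    return IrtAceModel(priors=priors, mcmc=mcmc, **kwargs).fit(data, item_bank=item_bank)
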