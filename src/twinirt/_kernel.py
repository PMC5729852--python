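"""Collapsed MCMC kernel for the moderated ACE twin model.

The generative hierarchy (family effect, DZ Mendelian-sampling terms, unique
noise) is jointly normal given the structural parameters, so the family-level
latents are integrated out analytically: a twin pair's latent traits follow a
bivariate normal with common mean ``mu + beta1m*M_i``, common variance
``sigma2_A + sigma2_C + sigma2_E`` and cross-covariance ``sigma2_A + sigma2_C``
(MZ) or ``0.5*sigma2_A + sigma2_C`` (DZ), each component log-linear in the
moderator.  The chain state is therefore only

* the eight structural parameters,
* the latent traits ``theta`` (when an item-response layer is attached;
  for a directly observed phenotype they are data),
* imputed moderators for families where M is missing, and
* the zygosity-specific moderator probabilities ``pi_mz``/``pi_dz``.

Updates: exact Gibbs for ``(mu, beta1m)`` (conjugate given the pair
covariances) and for the moderator probabilities (Beta); adaptive single-site
random-walk Metropolis plus one joint adaptive-covariance Metropolis step for
the six log-variance coefficients; vectorized random-walk Metropolis for the
latent traits against their co-twin-conditional normal prior and Bernoulli
item likelihood; exact Bernoulli draws for missing moderators.  This kernel
targets the same posterior as the fully augmented sampler (the augmented joint
density is available in :mod:`twinirt.fit` and checked against this marginal
in the test suite) but mixes far better at short chain lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_LOG2PI = math.log(2.0 * math.pi)

#: Index of the six log-variance coefficients inside the parameter vector
#: (mu, beta1m, beta0a, beta1a, beta0c, beta1c, beta0e, beta1e).
_VAR_SLICE = slice(2, 8)


@dataclass
class KernelPriors:
    """Gaussian/Beta prior hyperparameters consumed by the kernel."""

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


class AceKernel:
    """One-dataset sampler state and transition kernel.

    Parameters
    ----------
    theta : (n, 2) ndarray
        Initial latent traits (IRT path) or the observed phenotypes
        (direct-phenotype path); NaN entries mark missing phenotypes and are
        treated as latent.
    mz : (n,) bool ndarray
        True for MZ families.
    moderator : (n,) ndarray
        Family moderator values, NaN where missing.
    priors : KernelPriors
    rng : numpy Generator
    responses : (n, 2, K) ndarray or None
        Binary item responses with NaN for missing; None for the
        direct-phenotype model (no item layer — theta is then data except
        where NaN).
    difficulty, discrimination : (K,) ndarrays
        Item parameters (required iff ``responses`` is given).
    """

    def __init__(
        self,
        theta,
        mz,
        moderator,
        priors: KernelPriors,
        rng: np.random.Generator,
        responses=None,
        difficulty=None,
        discrimination=None,
        sample_varcoefs: bool = True,
    ):
        #: when False the six log-variance coefficients stay at their current
        #: values (used for conditional-slice checks against quadrature)
        self.sample_varcoefs = sample_varcoefs
        self.mz = np.asarray(mz, dtype=bool)
        self.n = self.mz.size
        moderator = np.asarray(moderator, dtype=float)
        self.m_missing = ~np.isfinite(moderator)
        self.priors = priors
        self.rng = rng

        self.responses = None
        if responses is not None:
            self.responses = np.asarray(responses, dtype=float)
            self.resp_missing = ~np.isfinite(self.responses)
            self.difficulty = np.asarray(difficulty, dtype=float)
            self.discrimination = np.asarray(discrimination, dtype=float)
            self.theta_latent = np.ones((self.n, 2), dtype=bool)
        else:
            self.theta_latent = ~np.isfinite(np.asarray(theta, dtype=float))

        self.theta = np.array(theta, dtype=float)
        self.theta[~np.isfinite(self.theta)] = 0.0

        # imputed moderator state: start missing entries at the observed rate
        self.M = moderator.copy()
        if self.m_missing.any():
            p0 = np.nanmean(moderator) if np.isfinite(moderator).any() else 0.5
            self.M[self.m_missing] = (rng.random(self.m_missing.sum()) < p0).astype(float)

        self.pi = {"mz": 0.5, "dz": 0.5}
        self.params = np.zeros(8)
        self._init_structural()

        # adaptation state
        self.scales = np.full(6, 0.1)
        self.theta_scale = 0.5
        self._adapt_count = 0
        self._joint_chol = None
        self._joint_scale = 2.38 / math.sqrt(6.0)
        self._history: list[np.ndarray] = []

    # ------------------------------------------------------------------
    # likelihood pieces
    # ------------------------------------------------------------------
    def pair_loglik(self, p, M=None, theta=None, idx=None):
        """Per-family bivariate-normal log-likelihood of the trait pair."""
        if M is None:
            M = self.M
        if theta is None:
            theta = self.theta
        mz = self.mz
        if idx is not None:
            M, theta, mz = M[idx], theta[idx], mz[idx]
        mu, b1m, b0a, b1a, b0c, b1c, b0e, b1e = p
        s2a = np.exp(b0a + b1a * M)
        s2c = np.exp(b0c + b1c * M)
        s2e = np.exp(b0e + b1e * M)
        v = s2a + s2c + s2e
        c = np.where(mz, s2a + s2c, 0.5 * s2a + s2c)
        mean = mu + b1m * M
        d1 = theta[:, 0] - mean
        d2 = theta[:, 1] - mean
        det = v * v - c * c
        return -_LOG2PI - 0.5 * np.log(det) - 0.5 * (v * (d1 * d1 + d2 * d2) - 2.0 * c * d1 * d2) / det

    def _logprior_varcoef(self, p):
        pr = self.priors
        z = (p[_VAR_SLICE] - pr.logvar_loc) / pr.logvar_scale
        return -0.5 * float(z @ z)

    def _item_loglik(self, theta_col, j):
        """Summed Bernoulli item log-likelihood for twin column ``j``."""
        if self.responses is None:
            return 0.0
        z = self.discrimination * (theta_col[:, None] - self.difficulty)
        y = self.responses[:, j, :]
        ll = np.where(self.resp_missing[:, j, :], 0.0, y * z - np.logaddexp(0.0, z))
        return ll.sum(axis=1)

    # ------------------------------------------------------------------
    # initialization
    # ------------------------------------------------------------------
    def _init_structural(self) -> None:
        """Method-of-moments starting values from the current theta/M state."""
        theta, M, mz = self.theta, self.M, self.mz
        pooled_var = max(float(theta.var()), 1e-4)

        # mean model: least squares of theta on (1, M)
        y = theta.ravel()
        x = np.repeat(M, 2)
        X = np.column_stack([np.ones_like(x), x])
        try:
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            mu0, b1m0 = float(coef[0]), float(coef[1])
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate design
            mu0, b1m0 = float(y.mean()), 0.0
        if not np.isfinite(b1m0):
            b1m0 = 0.0

        levels = np.unique(np.round(M, 9))
        use_levels = levels if levels.size == 2 else np.array([np.nan])

        def _acevars(sel):
            """Falconer-style component estimates on a family subset."""
            res = y - X @ [mu0, b1m0]
            res = res.reshape(-1, 2)
            sub_mz = sel & mz
            sub_dz = sel & ~mz
            if sub_mz.sum() < 10 or sub_dz.sum() < 10:
                return None
            cmz = float(np.cov(res[sub_mz].T)[0, 1])
            cdz = float(np.cov(res[sub_dz].T)[0, 1])
            var = float(res[sel].var())
            sa = 2.0 * (cmz - cdz)
            sc = 2.0 * cdz - cmz
            se = var - cmz
            floor = 0.05 * max(var, 1e-4)
            return tuple(max(s, floor) for s in (sa, sc, se))

        base = _acevars(np.ones(self.n, dtype=bool))
        if base is None:
            base = (pooled_var / 4, pooled_var / 4, pooled_var / 2)
        b0 = np.log(base)
        slopes = np.zeros(3)
        if use_levels.size == 2:
            lo = _acevars(np.isclose(M, use_levels[0]))
            hi = _acevars(np.isclose(M, use_levels[1]))
            if lo is not None and hi is not None:
                span = use_levels[1] - use_levels[0]
                b0 = np.log(lo)
                slopes = np.clip((np.log(hi) - np.log(lo)) / span, -3.0, 3.0)
                b0 = b0 - slopes * use_levels[0]

        self.params[:] = [mu0, b1m0, b0[0], slopes[0], b0[1], slopes[1], b0[2], slopes[2]]

    # ------------------------------------------------------------------
    # updates
    # ------------------------------------------------------------------
    def _update_mean(self) -> None:
        """Exact Gibbs draw of (mu, beta1m) from its conditional normal."""
        p = self.params
        _, v, c = self._pair_vc(p)
        w = 2.0 * (v + c)  # variance of the pair sum
        s = self.theta.sum(axis=1)
        x0 = 2.0 / w
        x1 = 2.0 * self.M / w
        pr = self.priors
        prec = np.array(
            [
                [np.sum(2.0 * x0) + 1.0 / pr.mu_scale**2, np.sum(2.0 * x1)],
                [np.sum(2.0 * x1), np.sum(2.0 * self.M * x1) + 1.0 / pr.beta1m_scale**2],
            ]
        )
        rhs = np.array(
            [
                np.sum(x0 * s) + pr.mu_loc / pr.mu_scale**2,
                np.sum(x1 * s) + pr.beta1m_loc / pr.beta1m_scale**2,
            ]
        )
        cov = np.linalg.inv(prec)
        mean = cov @ rhs
        L = np.linalg.cholesky(cov)
        draw = mean + L @ self.rng.standard_normal(2)
        self.params[0], self.params[1] = draw

    def _pair_vc(self, p):
        mu, b1m, b0a, b1a, b0c, b1c, b0e, b1e = p
        s2a = np.exp(b0a + b1a * self.M)
        s2c = np.exp(b0c + b1c * self.M)
        s2e = np.exp(b0e + b1e * self.M)
        v = s2a + s2c + s2e
        c = np.where(self.mz, s2a + s2c, 0.5 * s2a + s2c)
        return mu + b1m * self.M, v, c

    def _update_varcoefs(self, adapt: bool) -> None:
        cur_ll = float(self.pair_loglik(self.params).sum()) + self._logprior_varcoef(self.params)
        for k in range(6):
            j = 2 + k
            prop = self.params.copy()
            prop[j] += self.scales[k] * self.rng.standard_normal()
            prop_ll = float(self.pair_loglik(prop).sum()) + self._logprior_varcoef(prop)
            logr = prop_ll - cur_ll
            acc = math.exp(min(0.0, logr))
            if math.log(self.rng.random()) < logr:
                self.params = prop
                cur_ll = prop_ll
            if adapt:
                gamma = min(0.25, (self._adapt_count + 10) ** -0.6)
                self.scales[k] *= math.exp(gamma * (acc - 0.44))
        if self._joint_chol is not None:
            prop = self.params.copy()
            prop[_VAR_SLICE] += self._joint_scale * (
                self._joint_chol @ self.rng.standard_normal(6)
            )
            prop_ll = float(self.pair_loglik(prop).sum()) + self._logprior_varcoef(prop)
            if math.log(self.rng.random()) < prop_ll - cur_ll:
                self.params = prop
        if adapt:
            self._history.append(self.params[_VAR_SLICE].copy())
            self._adapt_count += 1

    def finalize_adaptation(self) -> None:
        """Freeze step sizes; build the joint proposal from burn-in history."""
        if len(self._history) >= 200:
            hist = np.asarray(self._history[len(self._history) // 2:])
            cov = np.cov(hist.T) + 1e-8 * np.eye(6)
            try:
                self._joint_chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:  # pragma: no cover
                self._joint_chol = None
        self._history = []

    def _update_theta(self, adapt: bool) -> None:
        if self.responses is None and not self.theta_latent.any():
            return
        mean, v, c = self._pair_vc(self.params)
        rho_num = c / v
        cond_sd = np.sqrt(v - c * c / v)
        acc_sum, acc_n = 0.0, 0
        for j in (0, 1):
            other = self.theta[:, 1 - j]
            cmean = mean + rho_num * (other - mean)
            if self.responses is None:
                free = self.theta_latent[:, j]
                if free.any():
                    self.theta[free, j] = self.rng.normal(cmean[free], cond_sd[free])
                continue
            cur = self.theta[:, j]
            prop = cur + self.theta_scale * self.rng.standard_normal(self.n)
            ll_cur = self._item_loglik(cur, j)
            ll_prop = self._item_loglik(prop, j)
            logr = (
                ll_prop
                - ll_cur
                - 0.5 * ((prop - cmean) ** 2 - (cur - cmean) ** 2) / (cond_sd**2)
            )
            accept = np.log(self.rng.random(self.n)) < logr
            self.theta[accept, j] = prop[accept]
            acc_sum += float(np.exp(np.minimum(0.0, logr)).sum())
            acc_n += self.n
        if adapt and acc_n:
            gamma = min(0.25, (self._adapt_count + 10) ** -0.6)
            self.theta_scale *= math.exp(gamma * (acc_sum / acc_n - 0.44))

    def _update_missing_moderator(self) -> None:
        if not self.m_missing.any():
            return
        idx = np.flatnonzero(self.m_missing)
        ll0 = self.pair_loglik(self.params, M=np.zeros(self.n), idx=idx)
        ll1 = self.pair_loglik(self.params, M=np.ones(self.n), idx=idx)
        pi_fam = np.where(self.mz[idx], self.pi["mz"], self.pi["dz"])
        logit = np.log(pi_fam) - np.log1p(-pi_fam) + ll1 - ll0
        p1 = 1.0 / (1.0 + np.exp(-logit))
        self.M[idx] = (self.rng.random(idx.size) < p1).astype(float)

    def _update_pi(self) -> None:
        pr = self.priors
        for label, sel, a, b in (
            ("mz", self.mz, pr.pi_mz_a, pr.pi_mz_b),
            ("dz", ~self.mz, pr.pi_dz_a, pr.pi_dz_b),
        ):
            n1 = float(self.M[sel].sum())
            n0 = float(sel.sum()) - n1
            self.pi[label] = float(self.rng.beta(a + n1, b + n0))

    # ------------------------------------------------------------------
    def step(self, adapt: bool = False) -> None:
        """One full sweep over all blocks."""
        self._update_mean()
        if self.sample_varcoefs:
            self._update_varcoefs(adapt)
        self._update_theta(adapt)
        self._update_missing_moderator()
        self._update_pi()

    def state_vector(self) -> np.ndarray:
        return np.concatenate([self.params, [self.pi["mz"], self.pi["dz"]]])
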