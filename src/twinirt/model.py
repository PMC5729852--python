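"""Core mathematical definitions for the ACE x M twin model with an IRT phenotype.

The phenotypic variance of a trait in twin pairs is decomposed into additive
genetic (A), common-environmental (C) and unique-environmental (E) components.
A measured family-level moderator M (e.g. a binary socio-economic-status
indicator) is allowed to moderate each component on the log-variance scale,

    sigma2_X(M) = exp(beta0_X + beta1_X * M),    X in {A, C, E},

which keeps every variance positive for any real coefficients and — unlike
the classical path-moderation parametrization, in which variances are squared
regression paths — is uniquely identified.  The latent trait itself is linked
to binary item responses through a Rasch/OPLM item response model.

Everything in this module is a pure function of parameters; the simulator and
the MCMC fitters build on these definitions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = [
    "AceMParams",
    "ItemBank",
    "PurcellParams",
    "log_linear_variance",
    "irt_probability",
    "twin_trait_covariance",
    "heritability",
    "moderator_variance_explained",
    "purcell_variance",
    "purcell_equivalent_solutions",
]

#: Additive-genetic correlation between dizygotic co-twins.
DZ_GENETIC_CORRELATION = 0.5

_STRUCTURAL_NAMES = (
    "mu",
    "beta1m",
    "beta0a",
    "beta1a",
    "beta0c",
    "beta1c",
    "beta0e",
    "beta1e",
)


def _require_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class AceMParams:
    """Structural parameters of the moderated ACE model.

    Parameters
    ----------
    mu : float
        Phenotypic population mean on the latent-trait scale.
    beta1m : float
        Main effect of the moderator on the phenotypic mean.
    beta0a, beta1a : float
        Intercept and moderation slope of the log additive-genetic variance.
    beta0c, beta1c : float
        Intercept and moderation slope of the log common-environmental variance.
    beta0e, beta1e : float
        Intercept and moderation slope of the log unique-environmental variance.
    """

    mu: float = 0.0
    beta1m: float = 0.0
    beta0a: float = 0.0
    beta1a: float = 0.0
    beta0c: float = 0.0
    beta1c: float = 0.0
    beta0e: float = 0.0
    beta1e: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValueError(f"AceMParams.{f.name} must be a finite real, got {v!r}")

    # -- convenience -------------------------------------------------------
    def variances(self, m):
        """sigma2_A(m), sigma2_C(m), sigma2_E(m) at moderator value(s) ``m``."""
        return (
            log_linear_variance(self.beta0a, self.beta1a, m),
            log_linear_variance(self.beta0c, self.beta1c, m),
            log_linear_variance(self.beta0e, self.beta1e, m),
        )

    def total_variance(self, m):
        """Phenotypic variance sigma2_P(m) = sum of the three components."""
        s2a, s2c, s2e = self.variances(m)
        return s2a + s2c + s2e

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _STRUCTURAL_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "AceMParams":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (8,):
            raise ValueError(f"expected 8 structural parameters, got shape {arr.shape}")
        return cls(**dict(zip(_STRUCTURAL_NAMES, arr.tolist())))

    @classmethod
    def names(cls) -> tuple:
        return _STRUCTURAL_NAMES


@dataclass(frozen=True)
class ItemBank:
    """A fixed bank of dichotomous items with known parameters.

    Difficulties ``b_k`` live on the latent-trait scale; discriminations
    ``a_k`` are fixed known constants (all 1 for a pure Rasch model, free
    positive constants for the OPLM variant).
    """

    difficulty: np.ndarray
    discrimination: np.ndarray = None  # type: ignore[assignment]
    item_id: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        difficulty = np.atleast_1d(np.asarray(self.difficulty, dtype=float))
        if self.discrimination is None:
            discrimination = np.ones_like(difficulty)
        else:
            discrimination = np.atleast_1d(np.asarray(self.discrimination, dtype=float))
        if self.item_id is None:
            item_id = np.array([f"item_{k + 1}" for k in range(difficulty.size)])
        else:
            item_id = np.atleast_1d(np.asarray(self.item_id))
        if difficulty.shape != discrimination.shape or difficulty.shape != item_id.shape:
            raise ValueError("item_id, difficulty and discrimination must have equal length")
        if not np.all(np.isfinite(difficulty)):
            raise ValueError("item difficulties must be finite")
        if not (np.all(np.isfinite(discrimination)) and np.all(discrimination > 0)):
            raise ValueError("item discriminations must be finite and strictly positive")
        if len(set(item_id.tolist())) != item_id.size:
            raise ValueError("item ids must be unique")
        object.__setattr__(self, "difficulty", difficulty)
        object.__setattr__(self, "discrimination", discrimination)
        object.__setattr__(self, "item_id", item_id)

    def __len__(self) -> int:
        return self.difficulty.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": self.item_id,
                "difficulty": self.difficulty,
                "discrimination": self.discrimination,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ItemBank":
        disc = df["discrimination"].to_numpy(float) if "discrimination" in df else None
        return cls(
            difficulty=df["difficulty"].to_numpy(float),
            discrimination=disc,
            item_id=df["item_id"].to_numpy(),
        )


@dataclass(frozen=True)
class PurcellParams:
    """Path-moderation coefficients for one variance component.

    In the classical moderation parametrization the variance is a squared
    moderated path, sigma2 = (b0 + b1*M)^2.  Deliberately no sign constraint:
    the resulting sign indeterminacy is the identification defect this type
    exists to exhibit.
    """

    b0: float
    b1: float

    def __post_init__(self) -> None:
        _require_finite(b0=self.b0, b1=self.b1)


# ---------------------------------------------------------------------------
# variance functions
# ---------------------------------------------------------------------------

def log_linear_variance(beta0, beta1, m):
    """Moderated variance ``exp(beta0 + beta1 * m)``.

    Log-linear in the moderator, hence strictly positive for all finite
    coefficients.  Accepts scalars or arrays for ``m``.
    """
    beta0 = np.asarray(beta0, dtype=float)
    beta1 = np.asarray(beta1, dtype=float)
    m = np.asarray(m, dtype=float)
    if not (np.all(np.isfinite(beta0)) and np.all(np.isfinite(beta1)) and np.all(np.isfinite(m))):
        raise ValueError("log_linear_variance requires finite inputs")
    out = np.exp(beta0 + beta1 * m)
    if out.ndim == 0:
        return float(out)
    return out


def irt_probability(theta, difficulty, discrimination=1.0):
    """Rasch/OPLM probability of a correct response.

    ``P(Y=1 | theta) = logistic(a * (theta - b))`` — at ``theta == b`` the
    endorsement probability is exactly one half; the curve is monotone
    increasing in ``theta``.  Broadcasts over items and persons.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    b = np.asarray(difficulty, dtype=float)
    a = np.asarray(discrimination, dtype=float)
    if np.any(a <= 0):
        raise ValueError("discrimination must be strictly positive")
    from scipy.special import expit

    out = expit(a * (theta - b))
    if out.ndim == 0:
        return float(out)
    return out


def twin_trait_covariance(params: AceMParams, m: float, zygosity: str):
    """Mean vector and 2x2 covariance matrix of a twin pair's latent traits.

    Both twins share mean ``mu + beta1m*m`` and variance
    ``sigma2_A(m)+sigma2_C(m)+sigma2_E(m)``.  The cross-covariance is
    ``sigma2_A+sigma2_C`` for MZ pairs and ``0.5*sigma2_A+sigma2_C`` for DZ
    pairs, reflecting the halved additive-genetic sharing of dizygotic twins.
    """
    _require_finite(m=m)
    z = str(zygosity).upper()
    if z not in ("MZ", "DZ"):
        raise ValueError(f"zygosity must be 'MZ' or 'DZ', got {zygosity!r}")
    s2a, s2c, s2e = params.variances(m)
    mean = params.mu + params.beta1m * m
    var = s2a + s2c + s2e
    rg = 1.0 if z == "MZ" else DZ_GENETIC_CORRELATION
    cov = rg * s2a + s2c
    return np.array([mean, mean]), np.array([[var, cov], [cov, var]])


def heritability(params: AceMParams) -> float:
    """Narrow-sense heritability at the moderator reference level.

    h2 = exp(beta0a) / (exp(beta0a) + exp(beta0c) + exp(beta0e)).
    """
    s2a, s2c, s2e = params.variances(0.0)
    return float(s2a / (s2a + s2c + s2e))


def moderator_variance_explained(params: AceMParams, p: float) -> float:
    """Share of total phenotypic variance due to a Bernoulli(p) moderator.

    With a binary moderator the main effect contributes variance
    ``beta1m^2 * p * (1-p)`` on top of the ACE variance evaluated at the
    reference level with zero moderation slopes.  Used to verify scenario
    calibration (e.g. beta1m=0.7, p=0.5, sigma2_P=1 gives about 11%).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"moderator probability must lie in (0, 1), got {p}")
    base = AceMParams(
        mu=params.mu,
        beta1m=params.beta1m,
        beta0a=params.beta0a,
        beta0c=params.beta0c,
        beta0e=params.beta0e,
    )
    s2p = base.total_variance(0.0)
    vm = params.beta1m**2 * p * (1.0 - p)
    return float(vm / (vm + s2p))


# ---------------------------------------------------------------------------
# the classical (path-moderation) parametrization and its non-identification
# ---------------------------------------------------------------------------

def purcell_variance(p: PurcellParams, m) -> float:
    """Variance implied by a moderated path: ``(b0 + b1*m)^2``."""
    m = np.asarray(m, dtype=float)
    _require_finite(m=m)
    out = (p.b0 + p.b1 * m) ** 2
    if out.ndim == 0:
        return float(out)
    return out


def purcell_equivalent_solutions(p: PurcellParams, moderator_levels) -> list:
    """All path-coefficient pairs reproducing the same variance function.

    Because only the square ``(b0+b1*m)^2`` enters the likelihood, the path
    can change sign independently at each observed moderator level as long as
    the implied values stay linear in ``m``.  For a binary moderator this
    yields up to four observationally equivalent pairs, so likelihood-based
    estimates of the path coefficients (and in particular the sign of the
    moderation effect) are not unique.  The log-variance parametrization has
    no such orbit.

    Parameters
    ----------
    p : PurcellParams
        Reference solution.
    moderator_levels : iterable of float
        The distinct moderator values realized in the data.

    Returns
    -------
    list of PurcellParams
        The full equivalence class on those levels (including ``p`` itself),
        deduplicated.  For more than two distinct levels only the global sign
        flip survives.
    """
    levels = sorted({float(m) for m in np.atleast_1d(np.asarray(moderator_levels, float))})
    if len(levels) == 0:
        raise ValueError("at least one moderator level is required")

    candidates: list[tuple[float, float]] = []
    if len(levels) == 1:
        # A single level constrains only |b0 + b1*m|; within the linear family
        # anchored at the reference slope this leaves the global sign flip.
        candidates = [(p.b0, p.b1), (-p.b0, -p.b1)]
    elif len(levels) == 2:
        m1, m2 = levels
        r1 = p.b0 + p.b1 * m1
        r2 = p.b0 + p.b1 * m2
        for s1, s2 in itertools.product((1.0, -1.0), repeat=2):
            # solve b0 + b1*m_i = s_i * r_i
            b1 = (s2 * r2 - s1 * r1) / (m2 - m1)
            b0 = s1 * r1 - b1 * m1
            candidates.append((b0, b1))
    else:
        candidates = [(p.b0, p.b1), (-p.b0, -p.b1)]

    seen: dict[tuple, PurcellParams] = {}
    for b0, b1 in candidates:
        key = (round(b0, 12), round(b1, 12))
        if key not in seen:
            sol = PurcellParams(b0=b0, b1=b1)
            expected = purcell_variance(p, np.asarray(levels))
            got = purcell_variance(sol, np.asarray(levels))
            assert np.allclose(expected, got), "equivalence-class construction failed"
            seen[key] = sol
    return list(seen.values())
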