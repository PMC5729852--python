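"""Sum-score comparison analysis.

The comparator treats the (scaled) number-correct score as the directly
observed phenotype and fits the same moderated-ACE biometric hierarchy as
the IRT model, with no measurement layer.  Because the sum score compresses
the trait near the floor or ceiling of the scale, its measurement error is
heterogeneous across the trait continuum, and variance-moderation estimates
based on it pick up spurious interaction effects; the contrast with the IRT
fit on identical data is the point of this module.

Scaling rule: all scores are divided by the standard deviation of the sum
scores of the twins (MZ and DZ pooled, both pair members) whose moderator
equals 1, which puts the sum-score and IRT analyses on a comparable scale.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .fit import IrtAceModel, McmcConfig, PriorSpec, _resolve_data, _validate_obs
from ._kernel import AceKernel

__all__ = [
    "compute_sum_scores",
    "scale_sum_scores",
    "make_sumscore_dataset",
    "SumScoreAceModel",
    "fit_sumscore_ace",
]


def compute_sum_scores(obs: pd.DataFrame) -> pd.Series:
    """Raw number-correct score per twin.

    Twins with any missing item response get a missing score: a partial sum
    has a different meaning than a complete one, so such twins enter the
    biometric fit with a missing phenotype instead.
    """
    item_columns = [c for c in obs.columns if c.startswith("item_")]
    if not item_columns:
        raise ValueError("dataset has no item_* columns to sum")
    items = obs[item_columns].to_numpy(dtype=float)
    raw = items.sum(axis=1)
    raw[np.any(~np.isfinite(items), axis=1)] = np.nan
    return pd.Series(raw, index=obs.index, name="raw_sum")


def scale_sum_scores(raw: pd.Series, moderator: pd.Series):
    """Divide all scores by the SD of scores in the moderator-1 group.

    Returns the scaled scores and the divisor.  After scaling, the
    moderator-1 group has unit standard deviation by construction.
    """
    raw = pd.Series(raw).astype(float)
    mod = pd.Series(moderator).astype(float)
    group = raw[(mod == 1.0) & raw.notna()]
    if group.size < 2:
        raise ValueError("scaling requires at least two scored twins with moderator == 1")
    divisor = float(group.std(ddof=1))
    if divisor == 0.0:
        raise ValueError("moderator-1 sum scores are constant; cannot scale")
    return raw / divisor, divisor


def make_sumscore_dataset(obs: pd.DataFrame):
    """Build the per-twin sum-score table (family_id, twin, zygosity,
    moderator, phenotype) from item-level data, applying the scaling rule.

    Returns the table and the scaling divisor.
    """
    raw = compute_sum_scores(obs)
    scaled, divisor = scale_sum_scores(raw, obs["moderator"])
    out = obs[["family_id", "twin", "zygosity", "moderator"]].copy()
    out["phenotype"] = scaled
    return out, divisor


class SumScoreAceModel(IrtAceModel):
    """Moderated-ACE estimator with the scaled sum score as the phenotype.

    Accepts either item-level data (the sum score is computed and scaled
    internally) or a table that already carries a ``phenotype`` column, in
    which case it is used as-is — the latter path doubles as a sanity oracle:
    feeding the true latent trait recovers the generating parameters, so any
    bias seen with sum scores comes from the score transform, not the fitter.

    Shares the biometric MCMC kernel with :class:`~twinirt.fit.IrtAceModel`
    code-for-code; only the measurement layer differs.
    """

    _has_item_layer = False

    def __init__(
        self,
        priors: Optional[PriorSpec] = None,
        mcmc: Optional[McmcConfig] = None,
        missing_moderator: str = "impute",
        store_theta: bool = False,
        theta_thin: int = 50,
        random_state: Optional[int] = None,
    ):
        super().__init__(
            priors=priors,
            mcmc=mcmc,
            missing_moderator=missing_moderator,
            store_theta=store_theta,
            theta_thin=theta_thin,
            random_state=random_state,
        )

    def _prepare(self, X, item_bank):
        X, _ = _resolve_data(X, item_bank)
        from .fit import apply_moderator_policy

        obs = apply_moderator_policy(X, self.missing_moderator)
        if "phenotype" in obs.columns:
            table = obs
            self.scaling_divisor_ = None
        else:
            table, divisor = make_sumscore_dataset(obs)
            self.scaling_divisor_ = divisor
        family_ids, mz, moderator, _ = _validate_obs(table)
        phen = (
            table.sort_values(["family_id", "twin"], kind="stable")["phenotype"]
            .to_numpy(dtype=float)
            .reshape(mz.size, 2)
        )
        self.item_columns_ = []
        self.bank_ = None
        return family_ids, mz, moderator, phen

    def _make_kernel(self, mz, moderator, phenotype, priors, rng):
        return AceKernel(
            theta=phenotype,
            mz=mz,
            moderator=moderator,
            priors=priors.to_kernel(),
            rng=rng,
            responses=None,
        )


def fit_sumscore_ace(data, priors=None, mcmc=None, **kwargs) -> SumScoreAceModel:
    """Functional wrapper over :class:`SumScoreAceModel`."""
    return SumScoreAceModel(priors=priors, mcmc=mcmc, **kwargs).fit(data)
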