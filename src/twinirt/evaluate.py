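"""Posterior and replication-level summaries.

Highest-posterior-density intervals, HPD-based power / false-positive rates
across simulation replications, the three Joanes–Gill sample skewness
estimators, replication summary tables (averaged posterior means and SDs,
HPD-exclusion rates against the generating truth), and MCMC convergence
diagnostics (split-R-hat and effective sample size via ArviZ).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "hpd_interval",
    "power_from_replications",
    "skewness_joanes_gill",
    "SkewnessEstimates",
    "summarize_replications",
    "ReplicationSummary",
    "convergence_report",
]

#: Parameters whose HPD interval is a meaningful zero test.  Variance
#: components are bounded below by zero, so their intervals are reported
#: but annotated as non-tests.
INTERACTION_PARAMS = ("beta1a", "beta1c", "beta1e")


def hpd_interval(draws, prob: float = 0.95):
    """Shortest interval containing ``prob`` of the empirical distribution.

    Computed by the shortest-window scan over the sorted (pooled) draws.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("at least two draws are required for an HPD interval")
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must lie strictly between 0 and 1")
    if x[0] == x[-1]:
        warnings.warn("all draws identical; HPD interval has zero width")
        return float(x[0]), float(x[0])
    k = max(1, int(np.ceil(prob * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])


def power_from_replications(intervals: Iterable) -> float:
    """Fraction of intervals that exclude zero (lower > 0 or upper < 0).

    Under a zero-truth parameter this is the false-positive rate; under a
    non-zero truth it is the power.  Invariant to the order of intervals.
    """
    intervals = list(intervals)
    if not intervals:
        raise ValueError("at least one interval is required")
    hits = sum(1 for lo, hi in intervals if lo > 0.0 or hi < 0.0)
    return hits / len(intervals)


@dataclass(frozen=True)
class SkewnessEstimates:
    """The three sample skewness estimators of Joanes & Gill."""

    b1: float  # g1 * ((n-1)/n)^{3/2}
    g1: float  # m3 / m2^{3/2}
    G1: float  # g1 * sqrt(n(n-1)) / (n-2)

    def as_tuple(self):
        return (self.b1, self.g1, self.G1)


def skewness_joanes_gill(x) -> SkewnessEstimates:
    """Compute g1 (moment estimator) and its two finite-sample adjustments.

    g1 = m3 / m2^(3/2) with m_r the r-th central sample moment (1/n
    normalization); G1 = g1 * sqrt(n(n-1)) / (n-2); b1 = g1 * ((n-1)/n)^(3/2).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise ValueError("skewness requires at least three observations")
    d = x - x.mean()
    m2 = float(np.mean(d**2))
    if m2 == 0.0:
        raise ValueError("skewness is undefined for a constant sample")
    m3 = float(np.mean(d**3))
    g1 = m3 / m2**1.5
    G1 = g1 * np.sqrt(n * (n - 1.0)) / (n - 2.0)
    b1 = g1 * ((n - 1.0) / n) ** 1.5
    return SkewnessEstimates(b1=float(b1), g1=float(g1), G1=float(G1))


@dataclass
class ReplicationSummary:
    """Across-replication summary for one model on one scenario.

    ``table`` has one row per parameter: the generating truth, the mean of
    posterior means, the mean of posterior SDs, and the proportion of
    replications whose HPD interval excluded zero.
    """

    table: pd.DataFrame
    model_label: str
    n_replications: int

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["model"] = self.model_label
        out["n_replications"] = self.n_replications
        return out

    def report(self) -> str:
        lines = [
            f"model: {self.model_label}   replications: {self.n_replications}",
            f"{'parameter':<12}{'truth':>10}{'mean':>10}{'sd_mean':>10}{'hpd_excl':>10}  note",
        ]
        for name, row in self.table.iterrows():
            truth = "" if pd.isna(row["truth"]) else f"{row['truth']:.3f}"
            note = "" if row["zero_test"] else "(bounded; not a zero test)"
            lines.append(
                f"{name:<12}{truth:>10}{row['mean_of_means']:>10.3f}"
                f"{row['mean_of_sds']:>10.3f}{row['hpd_exclusion']:>10.3f}  {note}"
            )
        return "\n".join(lines)


def summarize_replications(
    fits: Sequence,
    truth=None,
    model_label: str = "irt",
    prob: float = 0.95,
    parameters: Optional[Sequence[str]] = None,
) -> ReplicationSummary:
    """Aggregate a list of posterior sample objects across replications.

    Parameters may include the variance-scale transforms ``exp_beta0a`` etc.;
    the truth (an :class:`~twinirt.model.AceMParams` or a name->value dict)
    is matched by name where available.
    """
    if len(fits) == 0:
        raise ValueError("at least one fitted replication is required")
    posteriors = [f.posterior_ if hasattr(f, "posterior_") else f for f in fits]
    names = list(parameters) if parameters is not None else None
    if names is None:
        names = list(posteriors[0].draws) + list(posteriors[0].derived())
    for ps in posteriors:
        have = set(ps.draws) | set(ps.derived())
        if not set(names) <= have:
            raise ValueError("replications carry mismatched parameter sets")

    truth_map: dict = {}
    if truth is not None:
        if hasattr(truth, "to_array"):
            truth_map = dict(zip(truth.names(), truth.to_array()))
            for x in ("a", "c", "e"):
                truth_map[f"exp_beta0{x}"] = float(np.exp(truth_map[f"beta0{x}"]))
            total = sum(truth_map[f"exp_beta0{x}"] for x in ("a", "c", "e"))
            truth_map["h2"] = truth_map["exp_beta0a"] / total
        else:
            truth_map = dict(truth)

    rows = {}
    for name in names:
        means, sds, intervals = [], [], []
        for ps in posteriors:
            arr = ps.draws[name] if name in ps.draws else ps.derived()[name]
            pooled = np.asarray(arr).ravel()
            means.append(pooled.mean())
            sds.append(pooled.std(ddof=1))
            intervals.append(hpd_interval(pooled, prob))
        rows[name] = {
            "truth": truth_map.get(name, np.nan),
            "mean_of_means": float(np.mean(means)),
            "mean_of_sds": float(np.mean(sds)),
            "hpd_exclusion": power_from_replications(intervals),
            "zero_test": name in INTERACTION_PARAMS or name in ("mu", "beta1m"),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "parameter"
    return ReplicationSummary(table=table, model_label=model_label, n_replications=len(posteriors))


def convergence_report(posterior, rhat_threshold: float = 1.05, ess_threshold: float = 100.0) -> pd.DataFrame:
    """Split-R-hat and effective sample size per parameter (via ArviZ).

    Parameters whose split-chain scale reduction exceeds ``rhat_threshold``
    or whose ESS falls below ``ess_threshold`` are flagged.
    """
    import arviz as az

    rows = []
    for name, arr in posterior.draws.items():
        arr = np.asarray(arr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = float(az.rhat(arr))
            ess = float(az.ess(arr))
        rows.append(
            {
                "parameter": name,
                "rhat": rhat,
                "ess": ess,
                "flagged": bool(rhat > rhat_threshold or ess < ess_threshold),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
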