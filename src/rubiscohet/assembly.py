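"""Stoichiometry models for two-species small-subunit (SSu) incorporation.

Form I Rubisco is an L8S8 hexadecamer with eight SSu binding sites. When two
distinguishable SSu species (here "His-tagged" and "Strep-tagged") compete for
those sites, the number of His-tagged copies per holoenzyme, ``k``, follows

* a Binomial(8, p) distribution if every site is filled independently with
  His-skew ``p`` (the fraction of the incorporated SSu pool that is
  His-tagged), or
* a one-parameter sequential-preference chain if consecutive incorporation
  events are not independent: sites are filled in order, and the odds of
  repeating the species that filled the previous site are multiplied by
  ``alpha`` (``alpha = 1`` recovers the binomial; ``alpha > 1`` favours
  homogeneous runs).

Throughout the package ``k`` counts copies of the His-tagged species; the
Strep-tagged count is ``8 - k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy.optimize import brentq

N_SITES = 8

__all__ = [
    "N_SITES",
    "SkewEstimate",
    "StoichiometryDistribution",
    "stoichiometry_pmf",
    "predicted_heterogeneity",
    "homogeneous_fraction",
    "fit_preference_alpha",
    "NoSolutionError",
]


def _check_p(p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"skew p must lie in [0, 1], got {p}")


def _check_alpha(alpha: float) -> None:
    if not alpha > 0:
        raise ValueError(f"preference alpha must be positive, got {alpha}")


@dataclass(frozen=True)
class SkewEstimate:
    """His-skew estimate: mean of per-replicate skews.

    The His-skew is the fraction of initial holoenzyme-incorporated SSu
    signal attributable to the His-tagged species; it is the ``p`` of the
    binomial assembly model.
    """

    p_hat: float
    per_replicate: tuple[float, ...]
    n_replicates: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "n_replicates", len(self.per_replicate))
        if not (0.0 <= self.p_hat <= 1.0):
            raise ValueError(f"p_hat must lie in [0, 1], got {self.p_hat}")


@dataclass(frozen=True)
class StoichiometryDistribution:
    """Probability mass over k = 0..8 His-tagged copies per holoenzyme."""

    pmf: np.ndarray
    model: str  # "binomial" | "preference"

    def __post_init__(self):
        pmf = np.asarray(self.pmf, dtype=float)
        if pmf.shape != (N_SITES + 1,):
            raise ValueError(f"pmf must have {N_SITES + 1} entries")
        if np.any(pmf < -1e-15) or abs(pmf.sum() - 1.0) > 1e-12:
            raise ValueError("pmf entries must be nonnegative and sum to 1")
        object.__setattr__(self, "pmf", pmf)

    def heterogeneous_fraction(self) -> float:
        """P(1 <= k <= 7): both species present on one holoenzyme."""
        return float(1.0 - self.pmf[0] - self.pmf[N_SITES])


def _preference_step_probs(p: float, alpha: float) -> tuple[float, float]:
    """P(next = His | prev = His) and P(next = His | prev = Strep).

    Repeating the previous species has its odds multiplied by alpha:
    prev His  -> odds His:Strep = alpha*p : (1-p)
    prev Strep-> odds Strep:His = alpha*(1-p) : p
    """
    p_hh = alpha * p / (alpha * p + (1.0 - p)) if p > 0 else 0.0
    p_sh = p / (p + alpha * (1.0 - p)) if p < 1 else 1.0
    return p_hh, p_sh


def _preference_pmf(p: float, alpha: float, n_sites: int = N_SITES) -> np.ndarray:
    """Exact pmf of the sequential-preference chain via dynamic programming.

    State: (previous species, count of His so far). Equivalent to summing the
    chain probability over all 2^n ordered fill sequences, but O(n^2).
    """
    if p == 0.0:
        out = np.zeros(n_sites + 1)
        out[0] = 1.0
        return out
    if p == 1.0:
        out = np.zeros(n_sites + 1)
        out[n_sites] = 1.0
        return out
    p_hh, p_sh = _preference_step_probs(p, alpha)
    # prob[prev][k]: prev = 0 (Strep), 1 (His)
    prob = np.zeros((2, n_sites + 1))
    prob[1, 1] = p          # first site His
    prob[0, 0] = 1.0 - p    # first site Strep
    for _ in range(n_sites - 1):
        nxt = np.zeros_like(prob)
        # previous His
        nxt[1, 1:] += prob[1, :-1] * p_hh
        nxt[0, :] += prob[1, :] * (1.0 - p_hh)
        # previous Strep
        nxt[1, 1:] += prob[0, :-1] * p_sh
        nxt[0, :] += prob[0, :] * (1.0 - p_sh)
        prob = nxt
    return prob.sum(axis=0)


def stoichiometry_pmf(p: float, alpha: float = 1.0) -> StoichiometryDistribution:
    """Distribution of His-tagged copy number k per L8S8 holoenzyme.

    Parameters
    ----------
    p : float
        His-skew, probability a site is filled by the His-tagged species.
    alpha : float
        Preference multiplier on the odds of repeating the previous species;
        1 gives independent sites (binomial model).
    """
    _check_p(p)
    _check_alpha(alpha)
    if alpha == 1.0:
        k = np.arange(N_SITES + 1)
        coeff = np.array([comb(N_SITES, int(i)) for i in k], dtype=float)
        pmf = coeff * p**k * (1.0 - p) ** (N_SITES - k)
        return StoichiometryDistribution(pmf=pmf, model="binomial")
    return StoichiometryDistribution(pmf=_preference_pmf(p, alpha), model="preference")


def predicted_heterogeneity(p: float, alpha: float = 1.0) -> float:
    """Predicted fraction of SSu-heterogeneous holoenzymes, 1 - P(k=0) - P(k=8).

    For alpha = 1 this is the closed form 1 - p**8 - (1-p)**8.
    """
    _check_p(p)
    _check_alpha(alpha)
    if alpha == 1.0:
        return float(1.0 - p**N_SITES - (1.0 - p) ** N_SITES)
    return stoichiometry_pmf(p, alpha).heterogeneous_fraction()


def homogeneous_fraction(p: float, alpha: float = 1.0) -> float:
    """Fraction of fully homogeneous holoenzymes, P(k=0) + P(k=8)."""
    return 1.0 - predicted_heterogeneity(p, alpha)


class NoSolutionError(ValueError):
    """Requested heterogeneity is outside the range attainable by alpha."""


def fit_preference_alpha(
    measured_het: float,
    p: float,
    *,
    alpha_bounds: tuple[float, float] = (1e-3, 1e3),
    tol: float = 1e-8,
) -> float:
    """Invert the preference model: find alpha with predicted het = measured.

    predicted_heterogeneity(p, alpha) is monotone decreasing in alpha (larger
    alpha favours homogeneous runs), so a bracketed root on log(alpha) is
    well posed. Raises :class:`NoSolutionError` if the target lies outside
    the range attainable over ``alpha_bounds`` — it is never silently clamped.
    """
    if not (0.0 < measured_het < 1.0):
        raise ValueError("measured_het must lie strictly in (0, 1)")
    _check_p(p)
    lo, hi = alpha_bounds
    f = lambda log_a: predicted_heterogeneity(p, float(np.exp(log_a))) - measured_het
    f_lo, f_hi = f(np.log(lo)), f(np.log(hi))
    if f_lo * f_hi > 0:
        raise NoSolutionError(
            f"heterogeneity {measured_het} unattainable for p={p} with alpha in "
            f"[{lo}, {hi}] (attainable range "
            f"[{min(f_lo, f_hi) + measured_het:.6g}, {max(f_lo, f_hi) + measured_het:.6g}])"
        )
    log_alpha = brentq(f, np.log(lo), np.log(hi), xtol=tol)
    return float(np.exp(log_alpha))
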