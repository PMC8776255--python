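"""Transmission fidelity, efficacy, and the optimal readily-releasable pool.

A postsynaptic response (spike, or current beyond noise) is generated only
when the number of vesicles released during an action potential of duration
T exceeds a threshold M.  Release from an RRP of ``ntot1`` vesicles is
binomial with per-vesicle fusion probability ``F1(T) = (1 - e^{-k1 T})^N``,
so the failure probability is a binomial lower tail; a Chernoff bound makes
the exponential dependence on RRP size explicit.  Balancing failures
(missing a presynaptic spike, fired with probability q) against error reads
(responding to resting-calcium release with no spike) yields the total
error probability, the closed-form optimal RRP size, and the broad plateau
of near-optimal sizes that spares large synapses any fine tuning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .snare import SNAREEnergetics, snare_rate

__all__ = [
    "TransmissionSetting",
    "psc_peak",
    "fusion_probability",
    "p_fail",
    "chernoff_fail_bound",
    "p_error",
    "optimal_rrp",
    "error_bound",
]


@dataclass(frozen=True)
class TransmissionSetting:
    """Single-synapse communication context.

    M : postsynaptic response threshold (vesicles); response requires
        strictly more than M released (failure sums m = 0..M inclusive).
    q : probability that the presynaptic neuron fires an action potential.
    ca_rest, ca_AP : calcium concentration at rest / during the action
        potential, uM.
    T : action-potential duration, ms (f = 1/T is the maximum transmission
        rate).
    gamma : peak postsynaptic current per released vesicle.
    """

    M: int
    q: float
    ca_rest: float
    ca_AP: float
    T: float
    gamma: float = 1.0

    def __post_init__(self):
        if not (isinstance(self.M, (int, np.integer)) and self.M >= 0):
            raise ValueError("M must be a non-negative integer")
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must lie strictly in (0, 1)")
        if not 0.0 < self.ca_rest < self.ca_AP:
            raise ValueError("need 0 < ca_rest < ca_AP")
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def psc_peak(n_released: float, gamma: float):
    """Peak postsynaptic current, linear in the released count: gamma * n."""
    n_released = np.asarray(n_released, dtype=float)
    if np.any(n_released < 0):
        raise ValueError("released count must be non-negative")
    out = gamma * n_released
    return out if out.ndim else float(out)


def fusion_probability(ca: float, T: float, N: int, e: SNAREEnergetics) -> float:
    """Per-vesicle RRP fusion probability (1 - exp(-k1(ca) T))**N."""
    return float(-np.expm1(-snare_rate(ca, e) * T)) ** N


def p_fail(
    setting: TransmissionSetting, ntot1: int, N: int, e: SNAREEnergetics, ca: float | None = None
) -> float:
    """Exact probability that at most M of ntot1 vesicles fuse during T.

    Binomial lower tail evaluated through the regularized incomplete beta
    function (scipy's binom.cdf), stable up to RRP sizes of thousands.
    ``ca`` defaults to the action-potential concentration.
    """
    if not (isinstance(ntot1, (int, np.integer)) and ntot1 >= 1):
        raise ValueError("exact p_fail requires a positive integer ntot1")
    F1 = fusion_probability(setting.ca_AP if ca is None else ca, setting.T, N, e)
    if setting.M >= ntot1:
        return 1.0
    return float(binom.cdf(setting.M, ntot1, F1))


def _chernoff_lower_tail(alpha: float, F: float, n: float) -> float:
    """exp(-alpha n (F/alpha + ln(alpha/F) - 1)): Poisson-dominated bound on
    P{Binomial(n, F) <= alpha n} for alpha < F."""
    return math.exp(-alpha * n * (F / alpha + math.log(alpha / F) - 1.0))


def chernoff_fail_bound(
    setting: TransmissionSetting, ntot1: float, N: int, e: SNAREEnergetics
) -> float:
    """Chernoff bound on the failure probability, valid for alpha = M/ntot1 < F1(T).

    The exponent is linear in ntot1: failure is exponentially suppressed as
    the RRP grows at fixed threshold fraction alpha.
    """
    F1 = fusion_probability(setting.ca_AP, setting.T, N, e)
    alpha = setting.M / ntot1
    if alpha >= F1:
        raise ValueError(
            f"faithful-transmission condition violated: alpha = M/ntot1 = "
            f"{alpha:.4g} must be < F1(T) = {F1:.4g}"
        )
    return _chernoff_lower_tail(alpha, F1, ntot1)


def p_error(
    setting: TransmissionSetting, ntot1: int, N: int, e: SNAREEnergetics
) -> float:
    """Total transmission-error probability.

    q * P{no response | spike} + (1 - q) * P{response | no spike}, with the
    failure probability evaluated at action-potential and resting calcium
    respectively.  The error-read term uses the binomial survival function
    directly (never 1 - cdf, which would cancel catastrophically when the
    resting tail is far below machine precision).
    """
    fail_ap = p_fail(setting, ntot1, N, e, ca=setting.ca_AP)
    Frest = fusion_probability(setting.ca_rest, setting.T, N, e)
    read = float(binom.sf(setting.M, ntot1, Frest)) if setting.M < ntot1 else 0.0
    return setting.q * fail_ap + (1.0 - setting.q) * read


def optimal_rrp(
    setting: TransmissionSetting, N: int, e: SNAREEnergetics, balance: str = "continuous"
) -> int:
    """RRP size minimising the transmission error.

    ``balance="continuous"`` (default) is the closed form

        ceil( M (1 + ln(FAP/Frest) / ln((1-Frest)/(1-FAP)))
              + ln(q/(1-q)) / ln((1-Frest)/(1-FAP)) ),

    obtained by balancing the leading exponentials of the two error terms.
    ``balance="discrete"`` balances the exact one-vesicle increments of the
    two binomial tails (the sign change of p_error(n+1) - p_error(n)),
    which replaces the factor M in the first numerator by M + 1 plus a
    ln(q FAP / ((1-q) Frest)) odds term; the two differ by roughly
    ln(FAP/Frest)/ln((1-Frest)/(1-FAP)) vesicles, negligible for synapses
    with modest dynamic range but several vesicles when FAP/Frest is large
    (see docs/methods.md).  Both results are >= 1 and non-decreasing in q:
    a more active synapse needs a larger RRP (the presynaptic expression of
    long-term potentiation).
    """
    FAP = fusion_probability(setting.ca_AP, setting.T, N, e)
    Frest = fusion_probability(setting.ca_rest, setting.T, N, e)
    if not Frest < FAP:
        raise ValueError("degenerate setting: need Frest < FAP")
    if FAP >= 1.0:
        raise ValueError(
            "release saturates at action-potential calcium (FAP = 1 to machine "
            "precision); the error trade-off is degenerate -- reduce k1*T"
        )
    L = math.log((1.0 - Frest) / (1.0 - FAP))
    K = math.log(FAP / Frest)
    odds = math.log(setting.q / (1.0 - setting.q))
    if balance == "continuous":
        n_star = setting.M * (1.0 + K / L) + odds / L
    elif balance == "discrete":
        n_star = setting.M + ((setting.M + 1) * K + odds) / L
    else:
        raise ValueError("balance must be 'continuous' or 'discrete'")
    return max(1, math.ceil(n_star))


def error_bound(
    setting: TransmissionSetting,
    ntot1: float,
    N: int,
    e: SNAREEnergetics,
    form: str = "printed",
) -> float:
    """Chernoff-type bound on the total error probability, for Frest < alpha < FAP.

    ``form="printed"`` uses the error-read exponent
    ``-(1-alpha) ntot1 ((1-alpha)/Frest + ln(Frest/(1-alpha)) - 1)`` in the
    exact shape the model is usually quoted.  ``form="derived"`` replaces it
    with the bound the standard Chernoff argument yields for the upper tail
    (apply the lower-tail bound to the complement count, Binomial(ntot1,
    1 - Frest) <= (1-alpha) ntot1):
    ``-(1-alpha) ntot1 ((1-Frest)/(1-alpha) + ln((1-alpha)/(1-Frest)) - 1)``.
    Both are exponentially small in the operating regime
    Frest << alpha < FAP, but only the derived form is a guaranteed upper
    bound on the error-read term as alpha approaches Frest (see
    docs/methods.md).
    """
    FAP = fusion_probability(setting.ca_AP, setting.T, N, e)
    Frest = fusion_probability(setting.ca_rest, setting.T, N, e)
    alpha = setting.M / ntot1
    if not Frest < alpha < FAP:
        raise ValueError(
            f"alpha = {alpha:.4g} outside the bound's domain (Frest, FAP) = "
            f"({Frest:.4g}, {FAP:.4g})"
        )
    fail_term = setting.q * _chernoff_lower_tail(alpha, FAP, ntot1)
    if form == "printed":
        x = (1.0 - alpha) / Frest
        read_exp = (1.0 - alpha) * ntot1 * (x - math.log(x) - 1.0)
        read_term = (1.0 - setting.q) * math.exp(-read_exp)
    elif form == "derived":
        beta, G = 1.0 - alpha, 1.0 - Frest
        read_term = (1.0 - setting.q) * _chernoff_lower_tail(beta, G, ntot1)
    else:
        raise ValueError("form must be 'printed' or 'derived'")
    return fail_term + read_term
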