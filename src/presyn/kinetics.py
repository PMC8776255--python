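"""Closed-form release kinetics of the unifying two-pathway fusion scheme.

A docked ("fast pool") vesicle fuses once all of its N independent SNARE
assemblies have undergone the calcium-triggered conformational transition,
each at rate ``k1``.  A "slow pool" vesicle must additionally complete one
slow step at rate ``k2`` (reserve-to-RRP replenishment in vivo, escape from
the hemifusion diaphragm in vitro).  Because every step is exponential and
independent, the scheme with N concurrent steps of rate ``k1`` is equivalent
to a sequential scheme with rates ``N k1, (N-1) k1, ..., k1``.

All times are in ms, rates in 1/ms.  The module provides the exact mean
release rate, mean cumulative release, the per-pathway fusion-time
distributions, the full release-count distribution, and the peak-rate
characteristics (closed-form approximation valid for ``k2 << k1``, and exact
numerical maximisation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import comb
from scipy.stats import binom

__all__ = [
    "FusionKinetics",
    "VesiclePools",
    "ReleaseDistributions",
    "PeakCharacteristics",
    "TimescaleSeparationWarning",
    "release_rate",
    "cumulative_release",
    "fusion_time_distributions",
    "release_count_distribution",
    "release_count_pmf",
    "peak_release",
]

#: Largest supported number of independent SNARE assemblies.  The alternating
#: sums in the exact solutions are evaluated directly in double precision,
#: which is safe well beyond the biological range (N = 1..5) but suffers
#: catastrophic cancellation for large N.
N_MAX = 15

#: Relative half-width (in units of k1) within which a denominator like
#: j*k1 - k2 is treated as a removable singularity and replaced by its
#: analytic limit.
_SINGULAR_TOL = 1e-9


class TimescaleSeparationWarning(UserWarning):
    """Raised when k2/k1 exceeds 0.1 and a k2<<k1 approximation is used."""


def _check_time(t):
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time values must be finite")
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


@dataclass(frozen=True)
class FusionKinetics:
    """Scheme-level rates and stoichiometry of a fusion unit.

    Parameters
    ----------
    N : int
        Number of independent SNARE assemblies that must transition for a
        vesicle to fuse.  Each assembly may be a single SNARE or a
        cooperative super-assembly.
    k1 : float
        Rate of the fast calcium-triggered conformational step (1/ms).
    k2 : float
        Rate of the slow step (1/ms): pool replenishment in vivo, hemifusion
        escape in vitro.
    """

    N: int
    k1: float
    k2: float

    def __post_init__(self):
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 1):
            raise ValueError(f"N must be a positive integer, got {self.N!r}")
        if self.N > N_MAX:
            raise ValueError(
                f"N={self.N} exceeds the supported maximum {N_MAX}; the "
                "alternating-sum solutions are numerically unstable there"
            )
        for name in ("k1", "k2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive finite rate, got {v!r}")

    @property
    def timescale_ratio(self) -> float:
        return self.k2 / self.k1

    def warn_if_overlapping_timescales(self) -> None:
        if self.timescale_ratio > 0.1:
            warnings.warn(
                f"k2/k1 = {self.timescale_ratio:.3g} > 0.1: the closed-form "
                "peak expressions assume separation of timescales (k2 << k1)",
                TimescaleSeparationWarning,
                stacklevel=3,
            )


@dataclass(frozen=True)
class VesiclePools:
    """Sizes of the fast (RRP / point-contact) and slow (reserve /
    extended-contact) vesicle pools.

    Sizes are stored as reals because least-squares fits return non-integer
    pool sizes; count-distribution and simulation operations require integers
    and check explicitly (:meth:`as_integio`).
    """

    ntot1: float
    ntot2: float

    def __post_init__(self):
        for name in ("ntot1", "ntot2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be non-negative and finite, got {v!r}")
        if self.ntot1 + self.ntot2 <= 0:
            raise ValueError("at least one pool must be non-empty")

    @property
    def total(self) -> float:
        return self.ntot1 + self.ntot2

    def as_integers(self) -> tuple[int, int]:
        """Return integer pool sizes, refusing to round silently."""
        out = []
        for name in ("ntot1", "ntot2"):
            v = getattr(self, name)
            if abs(v - round(v)) > 1e-9:
                raise ValueError(
                    f"{name}={v!r} is not integer-valued; count-distribution and "
                    "simulation operations require integer pools"
                )
            out.append(int(round(v)))
        return tuple(out)


@dataclass(frozen=True)
class ReleaseDistributions:
    """Fusion-time densities and cumulatives for the two pathways at times t."""

    t: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    F1: np.ndarray
    F2: np.ndarray


@dataclass(frozen=True)
class PeakCharacteristics:
    """Location and height of the maximum of the mean release rate."""

    tmax: float
    peak_rate: float
    method: str


# ---------------------------------------------------------------------------
# pathway distributions


def _phi(t, a, b, k_scale):
    """(exp(-b t) - exp(-a t)) / (a - b), with the a -> b limit t exp(-b t)."""
    if abs(a - b) < _SINGULAR_TOL * k_scale:
        return t * np.exp(-b * t)
    return (np.exp(-b * t) - np.exp(-a * t)) / (a - b)


def _psi(t, a, b, k_scale):
    """(a exp(-b t) - b exp(-a t)) / (a - b), with limit (1 + b t) exp(-b t)."""
    if abs(a - b) < _SINGULAR_TOL * k_scale:
        return (1.0 + b * t) * np.exp(-b * t)
    return (a * np.exp(-b * t) - b * np.exp(-a * t)) / (a - b)


def _p1(t, kin: FusionKinetics):
    N, k1 = kin.N, kin.k1
    x = -np.expm1(-k1 * t)  # 1 - exp(-k1 t), accurate at small t
    if N == 1:
        base = np.ones_like(x)  # 0^0 = 1 convention
    else:
        base = x ** (N - 1)
    return N * k1 * base * np.exp(-k1 * t)


def _p2(t, kin: FusionKinetics):
    N, k1, k2 = kin.N, kin.k1, kin.k2
    acc = np.zeros_like(t, dtype=float)
    for j in range(N):
        acc += (-1.0) ** j * comb(N - 1, j, exact=True) * _phi(t, (j + 1) * k1, k2, k1)
    return N * k1 * k2 * acc


def _F1(t, kin: FusionKinetics):
    x = -np.expm1(-kin.k1 * t)
    return x**kin.N


def _F2(t, kin: FusionKinetics):
    N, k1, k2 = kin.N, kin.k1, kin.k2
    acc = np.zeros_like(t, dtype=float)
    for j in range(1, N + 1):
        acc += (
            (-1.0) ** (j - 1)
            * comb(N, j, exact=True)
            * (1.0 - _psi(t, j * k1, k2, k1))
        )
    return acc


def fusion_time_distributions(t, kin: FusionKinetics) -> ReleaseDistributions:
    """Per-pathway fusion-time densities p1, p2 and cumulatives F1, F2.

    The fast pathway is the maximum of N exponential(k1) clocks,
    ``F1(t) = (1 - exp(-k1 t))**N``; the slow pathway convolves one extra
    exponential(k2) step.  Removable singularities at ``j k1 = k2`` are
    evaluated by their analytic limits.
    """
    t = _check_time(t)
    p2 = _p2(t, kin)
    F2 = _F2(t, kin)
    # clip tiny negative round-off from the alternating sums
    p2 = np.where((p2 < 0) & (p2 > -1e-12 * kin.k1), 0.0, p2)
    F2 = np.clip(F2, 0.0, 1.0)
    return ReleaseDistributions(t=t, p1=_p1(t, kin), p2=p2, F1=_F1(t, kin), F2=F2)


def release_rate(t, pools: VesiclePools, kin: FusionKinetics):
    """Mean release rate d<n>/dt (vesicles/ms) at time t (ms).

    Exact solution of the two-pathway scheme:
    ``ntot1 * p1(t) + ntot2 * p2(t)``.
    """
    t = _check_time(t)
    out = pools.ntot1 * _p1(t, kin)
    if pools.ntot2 > 0:
        p2 = _p2(t, kin)
        p2 = np.where((p2 < 0) & (p2 > -1e-12 * kin.k1), 0.0, p2)
        out = out + pools.ntot2 * p2
    return out if out.ndim else float(out)


def cumulative_release(t, pools: VesiclePools, kin: FusionKinetics):
    """Mean cumulative release <n(t)> (vesicles): ``ntot1 F1(t) + ntot2 F2(t)``."""
    t = _check_time(t)
    out = pools.ntot1 * _F1(t, kin)
    if pools.ntot2 > 0:
        out = out + pools.ntot2 * np.clip(_F2(t, kin), 0.0, 1.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# count distribution


def release_count_pmf(t: float, pools: VesiclePools, kin: FusionKinetics) -> np.ndarray:
    """Probability mass function of the number of vesicles released by time t.

    Vesicles fuse independently, so the count is the sum of two independent
    binomials, ``Binomial(ntot1, F1(t)) + Binomial(ntot2, F2(t))``; the pmf
    is their convolution, returned for m = 0..ntot1+ntot2.
    """
    n1, n2 = pools.as_integers()
    t = float(t)
    if t < 0:
        raise ValueError("time must be non-negative")
    d = fusion_time_distributions(np.asarray(t), kin)
    pmf1 = binom.pmf(np.arange(n1 + 1), n1, float(d.F1))
    pmf2 = binom.pmf(np.arange(n2 + 1), n2, float(d.F2))
    return np.convolve(pmf1, pmf2)


def release_count_distribution(
    t: float, m: int, pools: VesiclePools, kin: FusionKinetics
) -> float:
    """P{n(t) = m} for integer pools."""
    n1, n2 = pools.as_integers()
    if not (isinstance(m, (int, np.integer)) and 0 <= m <= n1 + n2):
        raise ValueError(f"m must be an integer in [0, {n1 + n2}], got {m!r}")
    return float(release_count_pmf(t, pools, kin)[m])


# ---------------------------------------------------------------------------
# peak characteristics


def _approx_peak(pools: VesiclePools, kin: FusionKinetics) -> PeakCharacteristics:
    N, k1, k2 = kin.N, kin.k1, kin.k2
    if pools.ntot1 <= 0:
        raise ValueError("the closed-form peak expressions require ntot1 > 0")
    ratio = pools.ntot2 / pools.ntot1
    tmax = (math.log(N) + ratio * (N - 1) / N**3 * (k2 / k1)) / k1
    shape = 1.0 if N == 1 else (1.0 - 1.0 / N) ** (N - 1)  # 0^0 = 1 at N=1
    peak = pools.ntot1 * k1 * shape * (1.0 + ratio * (N - 1) / N * (k2 / k1))
    return PeakCharacteristics(tmax=tmax, peak_rate=peak, method="approx")


def _exact_peak(pools: VesiclePools, kin: FusionKinetics) -> PeakCharacteristics:
    k1 = kin.k1
    lo, hi = 1e-6 / k1, 50.0 / k1

    def neg_rate(t):
        return -release_rate(t, pools, kin)

    res = minimize_scalar(
        neg_rate, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10 * (math.log(max(kin.N, 2)) / k1)},
    )
    candidates = [(float(res.x), -float(res.fun))]
    # the rate can be maximal at t = 0 (monotone decay, e.g. N = 1)
    candidates.append((0.0, float(release_rate(0.0, pools, kin))))
    tmax, peak = max(candidates, key=lambda c: c[1])
    return PeakCharacteristics(tmax=tmax, peak_rate=peak, method="exact")


def peak_release(
    pools: VesiclePools, kin: FusionKinetics, method: str = "approx"
) -> PeakCharacteristics:
    """Time and height of the peak mean release rate.

    ``method="approx"`` uses the closed forms valid for ``k2 << k1``
    (warning above k2/k1 = 0.1):

        tmax ~ (1/k1) [ln N + (ntot2/ntot1) ((N-1)/N^3) (k2/k1)]
        peak ~ ntot1 k1 (1 - 1/N)^(N-1) (1 + (ntot2 (N-1))/(ntot1 N) (k2/k1))

    ``method="exact"`` maximises :func:`release_rate` numerically on
    ``[1e-6/k1, 50/k1]`` (checking the t = 0 boundary).
    """
    if method == "approx":
        kin.warn_if_overlapping_timescales()
        return _approx_peak(pools, kin)
    if method == "exact":
        return _exact_peak(pools, kin)
    raise ValueError(f"method must be 'approx' or 'exact', got {method!r}")
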