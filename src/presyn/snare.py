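"""Calcium dependence of the SNARE conformational rate and universal rescaling.

The conformational transition of a SNARE assembly is treated as thermal
escape over a free-energy barrier, with the logarithm of calcium
concentration acting as the external force that tilts the profile (the
force on the molecule comes from the chemical potential, hence the log).
For a cubic barrier profile the Kramers-type rate is

    k1(ca) = k0 (1 - c)^(1/2) exp[ dG (1 - (1 - c)^(3/2)) ],
    c = (2 nCa / (3 dG)) ln(ca / ca0),

where ``dG`` is the activation barrier in kBT, ``nCa`` the number of Ca2+
ions bound at the transition state, ``k0`` the rate at the reference
concentration ``ca0``, and ``c`` the dimensionless concentration.  At c = 1
the barrier vanishes and the description breaks down, so c >= 1 is a domain
error (never clamped: clamping would silently corrupt fits).

Nondimensionalising the peak release rate with

    a = (1 + 1/(N-1))^(N-1) / (ntot1 k0)        (a = 1/(ntot1 k0) at N = 1)
    r = (a (1 - c)^(-1/2) * peak_rate)^(1/dG)

collapses dose-response data from any parameter set onto the single master
curve ``r = exp[1 - (1 - c)^(3/2)]`` (exactly, in the k2/k1 -> 0 limit).
Note the ``(1 - c)^(-1/2)`` factor: dividing out the prefactor of k1 is the
reading under which the collapse is an algebraic identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import FusionKinetics, VesiclePools

__all__ = [
    "SNAREEnergetics",
    "DimensionlessPoint",
    "snare_rate",
    "dimensionless_c",
    "rescale_peak",
    "master_curve",
    "collapse_normalization",
]


@dataclass(frozen=True)
class SNAREEnergetics:
    """Kinetic/energetic identity of a synapse's fusion unit.

    dG : activation barrier at the reference concentration, in kBT.
    nCa : Ca2+ ions bound to the assembly at the transition state (the
        low-concentration power-law exponent); continuous, not constrained
        to integers.
    k0 : rate constant at the reference concentration, 1/ms.
    ca0 : reference calcium concentration, uM.
    """

    dG: float
    nCa: float
    k0: float
    ca0: float

    def __post_init__(self):
        for name in ("dG", "nCa", "k0", "ca0"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")


@dataclass(frozen=True)
class DimensionlessPoint:
    """A rescaled dose-response point (c, r) and its normalisation a."""

    c: float
    r: float
    a: float


def dimensionless_c(ca, e: SNAREEnergetics):
    """Dimensionless calcium concentration c = (2 nCa / (3 dG)) ln(ca/ca0)."""
    ca = np.asarray(ca, dtype=float)
    if np.any(~np.isfinite(ca)) or np.any(ca <= 0):
        raise ValueError("calcium concentration must be positive and finite")
    c = (2.0 * e.nCa / (3.0 * e.dG)) * np.log(ca / e.ca0)
    return c if c.ndim else float(c)


def _check_c(c):
    if np.any(np.asarray(c) >= 1.0):
        raise ValueError(
            "dimensionless concentration c >= 1: the activation barrier "
            "vanishes and the barrier-crossing rate is undefined"
        )


def snare_rate(ca, e: SNAREEnergetics):
    """Rate k1(ca) (1/ms) of the SNARE conformational transition.

    Strictly increasing in ``ca`` on its domain c < 1; near the reference
    concentration it reduces to the power law ``k0 (ca/ca0)**nCa``, and at
    higher concentrations the effective log-log slope falls below nCa (the
    dose-response saturation a fixed power law cannot produce).
    """
    c = dimensionless_c(ca, e)
    _check_c(c)
    omc = 1.0 - np.asarray(c)
    k = e.k0 * np.sqrt(omc) * np.exp(e.dG * (1.0 - omc**1.5))
    return k if k.ndim else float(k)


def log_log_slope(ca, e: SNAREEnergetics, part: str = "full"):
    """Local slope d ln k1 / d ln ca of the dose-response curve.

    ``part="activation"`` takes only the exponential barrier-reduction
    factor, whose slope is ``nCa * sqrt(1 - c)`` -- exactly ``nCa`` at the
    reference concentration; this is the sense in which the rate law reduces
    to the power law ``(ca/ca0)**nCa`` at low concentration.
    ``part="full"`` includes the Kramers prefactor ``(1 - c)^(1/2)``, which
    adds a small correction: at the reference concentration the full slope
    is ``nCa (1 - 1/(3 dG))``.  Either way the slope falls monotonically
    with ``ca`` -- the saturation a fixed power law cannot reproduce.
    """
    c = dimensionless_c(ca, e)
    _check_c(c)
    omc = 1.0 - np.asarray(c)
    slope = e.nCa * np.sqrt(omc)
    if part == "full":
        slope = slope - e.nCa / (3.0 * e.dG * omc)
    elif part != "activation":
        raise ValueError("part must be 'full' or 'activation'")
    return slope if slope.ndim else float(slope)


def master_curve(c):
    """Universal dose-response curve r(c) = exp[1 - (1 - c)^(3/2)]."""
    _check_c(c)
    c = np.asarray(c, dtype=float)
    r = np.exp(1.0 - (1.0 - c) ** 1.5)
    return r if r.ndim else float(r)


def collapse_normalization(kin: FusionKinetics, pools: VesiclePools, e: SNAREEnergetics) -> float:
    """Normalisation a = (1 + 1/(N-1))^(N-1) / (ntot1 k0), a = 1/(ntot1 k0) at N=1."""
    if pools.ntot1 <= 0:
        raise ValueError("rescaling requires ntot1 > 0")
    N = kin.N
    pref = 1.0 if N == 1 else (1.0 + 1.0 / (N - 1)) ** (N - 1)
    return pref / (pools.ntot1 * e.k0)


def rescale_peak(
    peak_rate: float,
    c: float,
    pools: VesiclePools,
    kin: FusionKinetics,
    e: SNAREEnergetics,
) -> DimensionlessPoint:
    """Map a measured (c, peak rate) pair onto the dimensionless plane.

    Returns ``r = (a (1-c)^(-1/2) peak_rate)^(1/dG)``.  When the peak rate
    comes from the closed-form peak expression with k2/k1 -> 0, the point
    (c, r) lies exactly on :func:`master_curve`.
    """
    _check_c(c)
    if not (np.isfinite(peak_rate) and peak_rate > 0):
        raise ValueError(f"peak_rate must be positive, got {peak_rate!r}")
    a = collapse_normalization(kin, pools, e)
    r = (a * peak_rate / np.sqrt(1.0 - c)) ** (1.0 / e.dG)
    return DimensionlessPoint(c=float(c), r=float(r), a=a)
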