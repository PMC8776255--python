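"""Independent reference implementations used only to check the package.

These deliberately avoid the closed forms in presyn: release curves come
from direct numerical integration of the master equations of the reaction
scheme, small coupled systems from explicit state enumeration, and scalar
expressions from sympy arbitrary-precision evaluation.
"""

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp


def ode_release(t_grid, ntot1, ntot2, N, k1, k2, rtol=1e-11, atol=1e-13):
    """Mean rate and cumulative release by integrating the master equations.

    Fast pathway: occupancy s_i of 'i SNARE transitions completed',
    i = 0..N-1, with sequential rates N k1, (N-1) k1, ..., k1 (equivalent to
    N concurrent exponential clocks).  Slow pathway: one extra reservoir
    state drained at k2 ahead of the same cascade.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    # state: [fast s_0..s_{N-1}, slow r, slow s_0..s_{N-1}, cum1, cum2]
    n = 2 * N + 3

    def rhs(_, y):
        dy = np.zeros(n)
        fast = y[:N]
        r = y[N]
        slow = y[N + 1 : N + 1 + N]
        rates = (N - np.arange(N)) * k1  # leaving-stage rates
        # fast cascade
        dy[:N] -= rates * fast
        dy[1:N] += rates[:-1] * fast[:-1]
        dy[-2] = rates[-1] * fast[-1]  # fusion flux, fast pool
        # slow cascade
        dy[N] = -k2 * r
        dy[N + 1 : N + 1 + N] -= rates * slow
        dy[N + 1] += k2 * r
        dy[N + 2 : N + 1 + N] += rates[:-1] * slow[:-1]
        dy[-1] = rates[-1] * slow[-1]
        return dy

    y0 = np.zeros(n)
    y0[0] = 1.0
    y0[N] = 1.0
    sol = solve_ivp(
        rhs, (0.0, float(t_grid[-1])), y0, t_eval=t_grid, rtol=rtol, atol=atol,
        method="LSODA",
    )
    F1 = sol.y[-2]
    F2 = sol.y[-1]
    p1 = (N - (N - 1)) * k1 * sol.y[N - 1]  # k1 * last fast stage
    p2 = k1 * sol.y[2 * N]
    rate = ntot1 * p1 + ntot2 * p2
    cum = ntot1 * F1 + ntot2 * F2
    return rate, cum


def finite_capacity_mean(t_grid, ntot1, ntot2, capacity, k1, k2):
    """Mean cumulative release of the capacity-limited scheme with N = 1.

    Exact master-equation integration over the enumerated state space
    (reserve count, docked count); tractable for a handful of vesicles.
    """
    states = [
        (r, d)
        for r in range(ntot2 + 1)
        for d in range(ntot1 + ntot2 + 1)
        if r + d <= ntot1 + ntot2
    ]
    index = {s: i for i, s in enumerate(states)}
    n = len(states)

    def rhs(_, y):
        dy = np.zeros(n + 1)  # last slot: mean cumulative fused
        for (r, d), i in index.items():
            p = y[i]
            if p == 0.0:
                continue
            if r > 0 and d < capacity:
                rate = k2 * r
                dy[i] -= rate * p
                dy[index[(r - 1, d + 1)]] += rate * p
            if d > 0:
                rate = k1 * d
                dy[i] -= rate * p
                dy[index[(r, d - 1)]] += rate * p
                dy[n] += rate * p
        return dy

    y0 = np.zeros(n + 1)
    y0[index[(ntot2, ntot1)]] = 1.0
    sol = solve_ivp(
        rhs, (0.0, float(t_grid[-1])), y0, t_eval=np.asarray(t_grid, float),
        rtol=1e-10, atol=1e-12, method="LSODA",
    )
    return sol.y[-1]


def snare_rate_highprec(ca, dG, nCa, k0, ca0, dps=50):
    """Arbitrary-precision evaluation of the barrier-crossing rate law."""
    ca_s, dG_s, nCa_s, k0_s, ca0_s = map(sp.Rational, map(str, (ca, dG, nCa, k0, ca0)))
    c = sp.Rational(2, 3) * nCa_s / dG_s * sp.log(ca_s / ca0_s)
    expr = k0_s * sp.sqrt(1 - c) * sp.exp(dG_s * (1 - (1 - c) ** sp.Rational(3, 2)))
    return float(sp.N(expr, dps))


def ppr_syt7_highprec(sigma, tau_res, tau_RRP, k1T, N, tau_int, dps=50):
    """Term-by-term arbitrary-precision evaluation of the syt7 PPR."""
    sg, tr, tR, kT, ti = map(lambda v: sp.Rational(str(v)), (sigma, tau_res, tau_RRP, k1T, tau_int))
    amp = 1 + (sg - 1) * sp.exp(-ti / tr)
    F1 = (1 - sp.exp(-kT)) ** N
    dep = 1 - sp.exp(-ti / tR) * F1
    fac = ((1 - sp.exp(-amp * kT)) / (1 - sp.exp(-kT))) ** N
    return float(sp.N(dep * fac, dps))
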