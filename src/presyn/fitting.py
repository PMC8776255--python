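"""Least-squares parameter extraction from reduced release data.

Estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``/``set_params``, fitted attributes with a trailing
underscore) so they compose with sklearn pipelines and model selection:

- :class:`DoseResponseModel` -- peak release rate vs [Ca2+]; extracts the
  barrier ``dG`` (kBT), transition-state occupancy ``nCa`` and the amplitude
  ``A = ntot1 * k0``.  ``ntot1`` and ``k0`` enter the dose-response curve
  only through their product, so they are deliberately reported as one
  parameter unless one is fixed (the identifiability ridge is never
  silently resolved).
- :class:`K1CurveModel` -- SNARE rate k1 vs [Ca2+]; extracts
  ``{dG, nCa, k0}``.
- :class:`CumulativeTraceModel` -- joint fit of cumulative-release traces
  at several [Ca2+] with shared ``{ntot1, ntot2, k2}`` (and N), one k1 per
  trace; optional model selection over N by smallest residual sum of
  squares.
- :class:`PairedPulseModel` -- (tau_int, PPR) curves under the syt7 or
  buffer-saturation mechanism.

All fits minimise squared residuals of log-transformed observables
(release rates span many orders of magnitude across synapses; a linear
loss would be dominated by the largest points), run from multiple
Latin-hypercube starts inside box bounds, and are deterministic for a
fixed seed.  Approximate confidence half-widths come from the Gauss-Newton
curvature at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin

from .kinetics import FusionKinetics, VesiclePools, cumulative_release
from .snare import SNAREEnergetics, dimensionless_c, master_curve, rescale_peak, snare_rate

__all__ = [
    "FitResult",
    "DoseResponseModel",
    "K1CurveModel",
    "CumulativeTraceModel",
    "PairedPulseModel",
    "fit_dose_response",
    "fit_k1_curve",
    "fit_cumulative_traces",
    "fit_ppr",
    "fit_power_law",
    "collapse_pipeline",
]

_LOG_EPS = 1e-12  # offset added inside log() for zero counts
_TIE_RTOL = 1e-10


@dataclass
class FitResult:
    """Summary of a least-squares fit: estimates, units, and diagnostics."""

    params: dict[str, float]
    units: dict[str, str]
    resid_ss: float
    n_obs: int
    converged: bool
    n_starts: int
    per_param_ci: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "units": self.units,
            "resid_ss": self.resid_ss,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "per_param_ci": self.per_param_ci,
            "warnings": self.warnings,
        }


def _multistart_least_squares(residual, bounds_lo, bounds_hi, center, n_starts, seed):
    """Bounded least squares from LHS starts; best resid_ss wins (tie -> first)."""
    lo = np.asarray(bounds_lo, float)
    hi = np.asarray(bounds_hi, float)
    starts = [np.clip(np.asarray(center, float), lo, hi)]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(lo), seed=seed)
        u = sampler.random(n_starts - 1)
        starts.extend(lo + u * (hi - lo))
    best = None
    for x0 in starts:
        try:
            sol = least_squares(residual, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        ss = 2.0 * sol.cost
        if best is None or ss < best[0] * (1.0 - _TIE_RTOL):
            best = (ss, sol)
    if best is None:
        raise RuntimeError("all optimisation starts failed")
    return best[1]


def _ci_to_natural(value, halfwidth_log):
    """Map a log-coordinate half-width to the natural scale (inf if unbounded)."""
    if not np.isfinite(halfwidth_log) or halfwidth_log > 700.0:
        return float("inf")
    return float(value * np.expm1(halfwidth_log))


def _gauss_newton_ci(sol, n_obs):
    """95% half-widths in the internal coordinates from J^T J at the optimum."""
    J = sol.jac
    dof = max(n_obs - J.shape[1], 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        return 1.96 * np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(J.shape[1], np.nan)


def _as_1d(X):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError(f"expected a single feature column, got shape {X.shape}")
        X = X[:, 0]
    return X


def _rate_model_log(ca, dG, nCa, log_amp, ca0, shape_log):
    """log of amp * shape * (1-c)^(1/2) exp(dG (1-(1-c)^(3/2))), c-clamped.

    Returns (log model, penalty) where penalty counts c >= 1 violations so
    the optimiser is pushed back into the barrier-crossing domain.
    """
    c = (2.0 * nCa / (3.0 * dG)) * np.log(ca / ca0)
    omc = 1.0 - c
    bad = omc <= 1e-12
    omc = np.where(bad, 1e-12, omc)
    logk = 0.5 * np.log(omc) + dG * (1.0 - omc**1.5)
    penalty = 1e3 * bad.astype(float)
    return log_amp + shape_log + logk, penalty


class _BaseRateCurveModel(RegressorMixin, BaseEstimator):
    """Shared machinery for dose-response and k1-vs-calcium fits."""

    _shape_log_attr = 0.0  # overridden: log of the N-dependent peak prefactor
    _amp_name = "A"
    _amp_unit = "vesicles/ms"

    def __init__(self, N=2, ca0=None, n_starts=16, seed=0):
        self.N = N
        self.ca0 = ca0
        self.n_starts = n_starts
        self.seed = seed

    def _shape_log(self) -> float:
        return 0.0

    def fit(self, X, y):
        ca = _as_1d(X)
        y = np.asarray(y, dtype=float)
        if ca.shape != y.shape:
            raise ValueError("X and y must have matching lengths")
        if len(ca) < 4:
            raise ValueError("need at least 4 data points")
        if np.any(ca <= 0) or np.any(y <= 0):
            raise ValueError("concentrations and rates must be positive")
        ca0 = float(np.exp(np.mean(np.log(ca)))) if self.ca0 is None else float(self.ca0)
        shape_log = self._shape_log()
        logy = np.log(y)

        def residual(theta):
            dG, nCa, log_amp = theta
            m, pen = _rate_model_log(ca, dG, nCa, log_amp, ca0, shape_log)
            return (m - logy) + pen

        log_amp_c = float(np.median(logy) - shape_log)
        sol = _multistart_least_squares(
            residual,
            bounds_lo=[1.0, 1e-3, log_amp_c - 30.0],
            bounds_hi=[100.0, 12.0, log_amp_c + 30.0],
            center=[20.0, 4.0, log_amp_c],
            n_starts=self.n_starts,
            seed=self.seed,
        )
        dG, nCa, log_amp = sol.x
        c_opt = (2.0 * nCa / (3.0 * dG)) * np.log(ca / ca0)
        if np.any(c_opt >= 1.0):
            raise ValueError(
                "fit rejected: the optimum implies a vanished barrier (c >= 1) "
                f"at {int(np.sum(c_opt >= 1.0))} data point(s); the "
                "barrier-crossing rate law cannot describe these data"
            )
        ci = _gauss_newton_ci(sol, len(y))
        amp = float(np.exp(log_amp))
        self.ca0_ = ca0
        self.dG_ = float(dG)
        self.nCa_ = float(nCa)
        setattr(self, self._amp_name + "_", amp)
        self.resid_ss_ = float(2.0 * sol.cost)
        self.n_obs_ = len(y)
        self.converged_ = bool(sol.success)
        self.super_assembly_ = bool(nCa > 5.0)
        self.ci_ = {
            "dG": float(ci[0]),
            "nCa": float(ci[1]),
            self._amp_name: _ci_to_natural(amp, ci[2]),
        }
        self.result_ = FitResult(
            params={"dG": self.dG_, "nCa": self.nCa_, self._amp_name: amp, "ca0": ca0},
            units={"dG": "kBT", "nCa": "ions", self._amp_name: self._amp_unit, "ca0": "uM"},
            resid_ss=self.resid_ss_,
            n_obs=self.n_obs_,
            converged=self.converged_,
            n_starts=self.n_starts,
            per_param_ci=self.ci_,
            warnings=(
                ["nCa > 5: SNARE super-assembly (cooperative multi-SNARE unit) indicated"]
                if self.super_assembly_
                else []
            ),
        )
        return self

    def predict(self, X):
        ca = _as_1d(X)
        e = self.energetics_
        amp = getattr(self, self._amp_name + "_")
        k_rel = np.array([snare_rate(c, e) / e.k0 for c in np.atleast_1d(ca)])
        return amp * np.exp(self._shape_log()) * k_rel

    @property
    def energetics_(self) -> SNAREEnergetics:
        """Fitted energetics; for dose-response fits k0 carries the amplitude
        degeneracy (k0 = A corresponds to ntot1 = 1)."""
        return SNAREEnergetics(
            dG=self.dG_, nCa=self.nCa_, k0=getattr(self, self._amp_name + "_"), ca0=self.ca0_
        )


class DoseResponseModel(_BaseRateCurveModel):
    """Fit peak release rate vs [Ca2+].

    Model: ``peak(ca) = A (1 - 1/N)^(N-1) k1(ca)/k0`` with the
    calcium-dependent SNARE rate; free parameters ``{dG, nCa, A}`` where
    ``A = ntot1 * k0``.  The reference concentration defaults to the
    geometric mean of the data, which centres the dimensionless
    concentration near zero.
    """

    _amp_name = "A"
    _amp_unit = "vesicles/ms"

    def _shape_log(self) -> float:
        N = self.N
        return 0.0 if N == 1 else (N - 1) * np.log(1.0 - 1.0 / N)


class K1CurveModel(_BaseRateCurveModel):
    """Fit the SNARE conformational rate k1 vs [Ca2+]; extracts {dG, nCa, k0}."""

    _amp_name = "k0"
    _amp_unit = "1/ms"

    def _shape_log(self) -> float:
        return 0.0


class CumulativeTraceModel(RegressorMixin, BaseEstimator):
    """Joint fit of cumulative-release traces at several calcium levels.

    X has two columns (t_ms, ca_uM); rows with equal ca_uM form one trace.
    Pool sizes ``ntot1, ntot2`` and the replenishment rate ``k2`` are shared
    across traces; each trace gets its own k1.  With ``N="select"`` the fit
    is repeated over ``N_candidates`` and the N with the smallest residual
    sum of squares is kept (ties broken toward smaller N), mirroring how
    SNARE stoichiometry is judged from release kinetics.
    """

    def __init__(
        self,
        N=2,
        N_candidates=(1, 2, 3, 4, 5),
        n_starts=6,
        seed=0,
        k2_prior=0.01,
        fix_k2_if_unconstrained=True,
    ):
        self.N = N
        self.N_candidates = N_candidates
        self.n_starts = n_starts
        self.seed = seed
        self.k2_prior = k2_prior
        self.fix_k2_if_unconstrained = fix_k2_if_unconstrained

    # -- internal -----------------------------------------------------------

    def _split_traces(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: (t_ms, ca_uM)")
        ca_vals = np.unique(X[:, 1])
        groups = [np.flatnonzero(X[:, 1] == ca) for ca in ca_vals]
        for g in groups:
            if len(g) < 8:
                raise ValueError("each trace needs at least 8 points")
        return ca_vals, groups

    def _fit_for_N(self, N, t, y, ca_vals, groups, fixed_k2=None):
        n_traces = len(groups)
        logy = np.log(y + _LOG_EPS)
        free_k2 = fixed_k2 is None

        def unpack(theta):
            ln1, ln2 = theta[0], theta[1]
            if free_k2:
                lk2 = theta[2]
                lk1s = theta[3:]
            else:
                lk2 = np.log(fixed_k2)
                lk1s = theta[2:]
            return np.exp(ln1), np.exp(ln2), np.exp(lk2), np.exp(lk1s)

        def residual(theta):
            ntot1, ntot2, k2, k1s = unpack(theta)
            out = np.empty_like(logy)
            pools = VesiclePools(ntot1=ntot1, ntot2=ntot2)
            for g, k1 in zip(groups, k1s):
                kin = FusionKinetics(N=N, k1=k1, k2=k2)
                out[g] = np.log(cumulative_release(t[g], pools, kin) + _LOG_EPS)
            return out - logy

        # heuristic centre: pool scale from the trace maximum; k1 per trace
        # from the earliest 5%-rise time -- the half-rise time would fall in
        # the slow (replenishment) phase whenever the reserve pool dominates
        y_end = max(np.max(y[g]) for g in groups)
        n1_c = 0.5 * y_end
        k1_c = []
        for g in groups:
            tg, yg = t[g], y[g]
            level = 0.05 * np.max(yg)
            idx = np.argmax(yg >= level)
            k1_c.append(np.log(2.0) * N / max(tg[idx], tg[0]))
        center = [np.log(n1_c), np.log(n1_c)] + ([np.log(self.k2_prior)] if free_k2 else [])
        center += list(np.log(k1_c))
        lo = [np.log(n1_c) - 8, np.log(n1_c) - 8] + ([np.log(self.k2_prior) - 8] if free_k2 else [])
        lo += [np.log(k) - 6 for k in k1_c]
        hi = [np.log(n1_c) + 8, np.log(n1_c) + 8] + ([np.log(self.k2_prior) + 8] if free_k2 else [])
        hi += [np.log(k) + 6 for k in k1_c]
        sol = _multistart_least_squares(
            residual, lo, hi, center, n_starts=self.n_starts, seed=self.seed
        )
        ntot1, ntot2, k2, k1s = unpack(sol.x)
        return sol, dict(ntot1=ntot1, ntot2=ntot2, k2=k2, k1=dict(zip(ca_vals, k1s)))

    # -- sklearn surface ----------------------------------------------------

    def fit(self, X, y):
        ca_vals, groups = self._split_traces(X)
        X = np.asarray(X, dtype=float)
        t = X[:, 0]
        y = np.asarray(y, dtype=float)

        candidates = self.N_candidates if self.N == "select" else (self.N,)
        rows = []
        best = None
        for N in sorted(candidates):
            sol, params = self._fit_for_N(int(N), t, y, ca_vals, groups)
            ss = 2.0 * sol.cost
            rows.append({"N": int(N), "resid_ss": ss})
            if best is None or ss < best[0] * (1.0 - _TIE_RTOL):
                best = (ss, int(N), sol, params)
        ss, N, sol, params = best
        self.selection_table_ = pd.DataFrame(rows)

        msgs = []
        t_max = float(np.max(t))
        if self.fix_k2_if_unconstrained and t_max * params["k2"] < 0.2:
            msgs.append(
                f"traces end at t_max = {t_max:.3g} ms, too short to constrain k2 "
                f"(k2 * t_max < 0.2); k2 fixed to the prior {self.k2_prior} /ms and "
                "ntot2 is identified only through the product k2 * ntot2"
            )
            warnings.warn(msgs[-1], UserWarning, stacklevel=2)
            sol, params = self._fit_for_N(N, t, y, ca_vals, groups, fixed_k2=self.k2_prior)
            ss = 2.0 * sol.cost

        self.N_ = N
        self.ntot1_ = float(params["ntot1"])
        self.ntot2_ = float(params["ntot2"])
        self.k2_ = float(params["k2"])
        self.k1_per_trace_ = {float(k): float(v) for k, v in params["k1"].items()}
        self.resid_ss_ = float(ss)
        self.n_obs_ = len(y)
        self.converged_ = bool(sol.success)
        pnames = ["ntot1", "ntot2", "k2"] + [f"k1@{ca:g}uM" for ca in ca_vals]
        pvals = [self.ntot1_, self.ntot2_, self.k2_] + [
            self.k1_per_trace_[float(ca)] for ca in ca_vals
        ]
        ci = _gauss_newton_ci(sol, len(y))
        ci_nat = {}
        if len(ci) == len(pvals):  # free-k2 fit: log-coordinate half-widths
            ci_nat = {n: _ci_to_natural(v, w) for n, v, w in zip(pnames, pvals, ci)}
        self.result_ = FitResult(
            params={**dict(zip(pnames, pvals)), "N": N},
            units={
                "ntot1": "vesicles",
                "ntot2": "vesicles",
                "k2": "1/ms",
                "N": "",
                **{f"k1@{ca:g}uM": "1/ms" for ca in ca_vals},
            },
            resid_ss=self.resid_ss_,
            n_obs=self.n_obs_,
            converged=self.converged_,
            n_starts=self.n_starts,
            per_param_ci=ci_nat,
            warnings=msgs,
        )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        pools = VesiclePools(ntot1=self.ntot1_, ntot2=self.ntot2_)
        out = np.empty(len(X))
        for i, (t, ca) in enumerate(X):
            k1 = self.k1_per_trace_.get(float(ca))
            if k1 is None:
                raise ValueError(f"no fitted trace at ca = {ca} uM")
            out[i] = cumulative_release(t, pools, FusionKinetics(N=self.N_, k1=k1, k2=self.k2_))
        return out


class PairedPulseModel(RegressorMixin, BaseEstimator):
    """Fit a (tau_int, PPR) curve with a chosen facilitation mechanism.

    mechanism="syt7" estimates {sigma, tau_res, tau_RRP} with {N, k1, T}
    known; mechanism="buffer" estimates {I_Ca, tau_Ca, tau_RRP} and
    additionally needs the energetics ``e`` and first-pulse calcium ``ca_i``
    to evaluate k1 at the incremented concentration.
    """

    def __init__(self, mechanism="syt7", N=2, k1=None, T=1.0, e=None, ca_i=None,
                 n_starts=16, seed=0):
        self.mechanism = mechanism
        self.N = N
        self.k1 = k1
        self.T = T
        self.e = e
        self.ca_i = ca_i
        self.n_starts = n_starts
        self.seed = seed

    def _ppr_syt7(self, tau, sigma, tau_res, tau_RRP):
        k1T = self.k1 * self.T
        F1 = (-np.expm1(-k1T)) ** self.N
        amp = 1.0 + (sigma - 1.0) * np.exp(-tau / tau_res)
        dep = 1.0 - np.exp(-tau / tau_RRP) * F1
        fac = (-np.expm1(-amp * k1T) / -np.expm1(-k1T)) ** self.N
        return dep * fac

    def _ppr_buffer(self, tau, I_Ca, tau_Ca, tau_RRP):
        ca_f = self.ca_i + I_Ca * np.exp(-tau / tau_Ca)
        k1f = np.array([snare_rate(c, self.e) for c in np.atleast_1d(ca_f)])
        k1i = snare_rate(self.ca_i, self.e)
        F1f = (-np.expm1(-k1f * self.T)) ** self.N
        dep = 1.0 - np.exp(-tau / tau_RRP) * F1f
        fac = (-np.expm1(-k1f * self.T) / -np.expm1(-k1i * self.T)) ** self.N
        return dep * fac

    def fit(self, X, y):
        tau = _as_1d(X)
        y = np.asarray(y, dtype=float)
        if len(tau) < 5:
            raise ValueError("need at least 5 (tau_int, PPR) points")
        if np.ptp(np.log10(tau)) < 1.0:
            raise ValueError("tau_int values must span at least one decade")
        if self.mechanism == "syt7":
            if self.k1 is None:
                raise ValueError("syt7 mechanism requires known k1")
            names, units = ["sigma", "tau_res", "tau_RRP"], ["", "ms", "ms"]

            def model(theta):
                lsig, ltres, ltrrp = theta
                return self._ppr_syt7(tau, 1.0 + np.exp(lsig), np.exp(ltres), np.exp(ltrrp))

            center = [0.0, np.log(np.median(tau)), np.log(np.median(tau))]
            lo = [-10.0, np.log(tau.min()) - 3, np.log(tau.min()) - 3]
            hi = [5.0, np.log(tau.max()) + 3, np.log(tau.max()) + 3]

            def natural(theta):
                return [1.0 + np.exp(theta[0]), np.exp(theta[1]), np.exp(theta[2])]

        elif self.mechanism == "buffer":
            if self.e is None or self.ca_i is None:
                raise ValueError("buffer mechanism requires energetics e and ca_i")
            names, units = ["I_Ca", "tau_Ca", "tau_RRP"], ["uM", "ms", "ms"]

            def model(theta):
                lica, ltca, ltrrp = theta
                return self._ppr_buffer(tau, np.exp(lica), np.exp(ltca), np.exp(ltrrp))

            center = [np.log(0.3 * self.ca_i), np.log(np.median(tau)), np.log(np.median(tau))]
            lo = [np.log(self.ca_i) - 12, np.log(tau.min()) - 3, np.log(tau.min()) - 3]
            hi = [np.log(2.0 * self.ca_i), np.log(tau.max()) + 3, np.log(tau.max()) + 3]

            def natural(theta):
                return [np.exp(theta[0]), np.exp(theta[1]), np.exp(theta[2])]

        else:
            raise ValueError(f"mechanism must be 'syt7' or 'buffer', got {self.mechanism!r}")

        logy = np.log(y + _LOG_EPS)

        def residual(theta):
            return np.log(model(theta) + _LOG_EPS) - logy

        sol = _multistart_least_squares(residual, lo, hi, center, self.n_starts, self.seed)
        vals = natural(sol.x)
        for n, v in zip(names, vals):
            setattr(self, n + "_", float(v))
        self.resid_ss_ = float(2.0 * sol.cost)
        self.n_obs_ = len(y)
        self.converged_ = bool(sol.success)
        ci = _gauss_newton_ci(sol, len(y))
        self.result_ = FitResult(
            params=dict(zip(names, map(float, vals))),
            units=dict(zip(names, units)),
            resid_ss=self.resid_ss_,
            n_obs=self.n_obs_,
            converged=self.converged_,
            n_starts=self.n_starts,
            per_param_ci={
                n: _ci_to_natural(v, w) for n, v, w in zip(names, vals, ci)
            },
        )
        return self

    def predict(self, X):
        tau = _as_1d(X)
        if self.mechanism == "syt7":
            return self._ppr_syt7(tau, self.sigma_, self.tau_res_, self.tau_RRP_)
        return self._ppr_buffer(tau, self.I_Ca_, self.tau_Ca_, self.tau_RRP_)


# ---------------------------------------------------------------------------
# functional wrappers


def fit_dose_response(data: pd.DataFrame, ca0=None, N=2, n_starts=16, seed=0) -> FitResult:
    """Fit a (ca_uM, peak_rate_per_ms) table; see :class:`DoseResponseModel`."""
    m = DoseResponseModel(N=N, ca0=ca0, n_starts=n_starts, seed=seed)
    m.fit(data[["ca_uM"]].values, data["peak_rate_per_ms"].values)
    return m.result_


def fit_k1_curve(data: pd.DataFrame, ca0=None, n_starts=16, seed=0) -> FitResult:
    """Fit a (ca_uM, k1_per_ms) table; see :class:`K1CurveModel`."""
    m = K1CurveModel(ca0=ca0, n_starts=n_starts, seed=seed)
    m.fit(data[["ca_uM"]].values, data["k1_per_ms"].values)
    return m.result_


def fit_cumulative_traces(
    traces: pd.DataFrame, N=2, n_starts=6, seed=0, **kw
) -> tuple[FitResult, pd.DataFrame]:
    """Fit a (t_ms, n_cum, ca_uM) table; returns (FitResult, selection table)."""
    m = CumulativeTraceModel(N=N, n_starts=n_starts, seed=seed, **kw)
    m.fit(traces[["t_ms", "ca_uM"]].values, traces["n_cum"].values)
    return m.result_, m.selection_table_


def fit_ppr(data: pd.DataFrame, mechanism: str, known: dict, n_starts=16, seed=0) -> FitResult:
    """Fit a (tau_int_ms, ppr) table with the syt7 or buffer model.

    ``known`` supplies the fixed parameters: N, T, and either k1 (syt7) or
    e + ca_i (buffer).
    """
    m = PairedPulseModel(mechanism=mechanism, n_starts=n_starts, seed=seed, **known)
    m.fit(data[["tau_int_ms"]].values, data["ppr"].values)
    return m.result_


def fit_power_law(data: pd.DataFrame, exponent: float = 4.0) -> FitResult:
    """Empirical power-law comparison fit, k = B * ca**exponent (log-space LSQ).

    The classical fourth-power description of release vs calcium; kept as a
    nested baseline to quantify how much the saturating barrier-crossing
    rate law improves on it.
    """
    ca = data["ca_uM"].values
    col = "k1_per_ms" if "k1_per_ms" in data else "peak_rate_per_ms"
    y = data[col].values
    logB = float(np.mean(np.log(y) - exponent * np.log(ca)))
    resid = logB + exponent * np.log(ca) - np.log(y)
    return FitResult(
        params={"B": float(np.exp(logB)), "exponent": exponent},
        units={"B": f"1/(ms uM^{exponent:g})", "exponent": ""},
        resid_ss=float(np.sum(resid**2)),
        n_obs=len(y),
        converged=True,
        n_starts=1,
    )


def collapse_pipeline(
    tables: dict[str, pd.DataFrame],
    fits: dict[str, DoseResponseModel] | None = None,
    N=2,
    n_starts=16,
    seed=0,
) -> tuple[pd.DataFrame, float]:
    """Rescale per-synapse dose-response tables onto the universal plane.

    Each synapse's table is fitted (unless a fitted model is supplied), its
    points are mapped to (c, r) with the fitted {dG, nCa, A}, and the RMS
    deviation of r from the master curve is reported.  Points with c >= 1
    are excluded and counted in the returned table's attrs.
    """
    rows = []
    n_excluded = 0
    for sid, df in tables.items():
        if fits is not None and sid in fits:
            m = fits[sid]
        else:
            m = DoseResponseModel(N=N, n_starts=n_starts, seed=seed)
            m.fit(df[["ca_uM"]].values, df["peak_rate_per_ms"].values)
        e = m.energetics_  # k0 slot carries A = ntot1 k0; pools below use ntot1 = 1
        kin = FusionKinetics(N=m.N if isinstance(m.N, int) else m.N_, k1=e.k0, k2=1e-6 * e.k0)
        pools = VesiclePools(ntot1=1.0, ntot2=0.0)
        for ca, peak in zip(df["ca_uM"].values, df["peak_rate_per_ms"].values):
            c = dimensionless_c(ca, e)
            if c >= 1.0:
                n_excluded += 1
                continue
            pt = rescale_peak(peak, c, pools, kin, e)
            rows.append({"synapse_id": sid, "c": pt.c, "r": pt.r})
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = n_excluded
    rms = float(np.sqrt(np.mean((out["r"].values - master_curve(out["c"].values)) ** 2)))
    return out, rms
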