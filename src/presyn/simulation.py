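"""Exact stochastic simulation of the two-pathway fusion scheme.

Doubles as the synthetic-data generator for fitting and distribution tests.

Baseline dynamics are simulated per vesicle: a fast-pool vesicle fuses when
all N of its independent exponential(k1) SNARE clocks have fired (fusion
time = max of N exponentials); a slow-pool vesicle first waits an
exponential(k2) replenishment step.  The slow step preceding the fast steps
(in vivo ordering) or following them (in vitro hemifusion escape) gives the
same fusion-time law, since the steps are independent exponentials and
convolution commutes.  The equivalent sequential scheme with rates
``N k1, (N-1) k1, ..., k1`` is available via ``scheme="sequential"`` for
equivalence checks.

Two robustness variants couple or perturb the vesicles:

- ``finite_capacity``: replenishment (R -> D) is blocked whenever the number
  of docked, unfused fast-pathway vesicles has reached the docking-site
  capacity; implemented as an event-driven Gillespie loop with a global
  docked counter.
- ``heterogeneous_ca``: each vesicle is assigned a release-site calcium
  concentration by weight and uses k1 = snare_rate(ca_site).

Reproducibility: one root seed; per-trial generators are derived as
``SeedSequence(seed, spawn_key=(trial,))`` so that changing ``n_trials``
never reshuffles earlier trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import FusionKinetics, VesiclePools
from .plasticity import PairedPulseProtocol, ppr_buffer, ppr_syt7
from .snare import SNAREEnergetics, snare_rate

__all__ = [
    "SimulationProtocol",
    "SimulationResult",
    "simulate",
    "simulate_finite_capacity",
    "simulate_heterogeneous_ca",
    "sample_fusion_times",
    "generate_fixture",
]

_VARIANTS = ("baseline", "finite_capacity", "heterogeneous_ca")


@dataclass(frozen=True)
class SimulationProtocol:
    """Configuration of a simulation run."""

    pools: VesiclePools
    kin: FusionKinetics
    t_end: float
    n_trials: int
    seed: int
    variant: str = "baseline"
    capacity: int | None = None
    ca_sites: tuple[float, ...] | None = None
    ca_weights: tuple[float, ...] | None = None
    n_grid: int = 200
    checkpoints: tuple[float, ...] | None = None
    scheme: str = "concurrent"

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {_VARIANTS}")
        if not (np.isfinite(self.t_end) and self.t_end > 0):
            raise ValueError("t_end must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        self.pools.as_integers()  # raises for non-integer pools
        if self.variant == "finite_capacity":
            if self.capacity is None:
                raise ValueError("variant 'finite_capacity' requires capacity")
            if self.capacity < 0:
                raise ValueError("capacity must be >= 0")
        if self.variant == "heterogeneous_ca":
            if not self.ca_sites:
                raise ValueError("variant 'heterogeneous_ca' requires ca_sites")
            w = self.ca_weights or tuple([1.0 / len(self.ca_sites)] * len(self.ca_sites))
            if len(w) != len(self.ca_sites):
                raise ValueError("ca_weights must match ca_sites in length")
            if abs(sum(w) - 1.0) > 1e-12:
                raise ValueError("ca_weights must sum to 1 within 1e-12")
        if self.scheme not in ("concurrent", "sequential"):
            raise ValueError("scheme must be 'concurrent' or 'sequential'")

    def time_grid(self) -> np.ndarray:
        return np.geomspace(1e-3 / self.kin.k1, self.t_end, self.n_grid)

    def checkpoint_times(self) -> np.ndarray:
        if self.checkpoints is not None:
            return np.asarray(self.checkpoints, dtype=float)
        g = self.time_grid()
        idx = np.linspace(0, len(g) - 1, 5).round().astype(int)
        return g[idx]


@dataclass(frozen=True)
class SimulationResult:
    """Trial-averaged summaries on a fixed time grid."""

    t_grid: np.ndarray
    mean_cumulative: np.ndarray
    mean_rate: np.ndarray
    se_cumulative: np.ndarray
    checkpoint_times: np.ndarray
    count_histograms: np.ndarray  # (n_checkpoints, ntot + 1), row sums = n_trials
    n_trials: int


def _trial_rng(seed: int, trial: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(trial,)))


def _fast_times(rng, n_vesicles: int, N: int, k1, scheme: str) -> np.ndarray:
    """Fusion-time samples for the fast (N-step) part of the pathway.

    k1 may be a scalar or a per-vesicle array (heterogeneous calcium).
    """
    if n_vesicles == 0:
        return np.empty(0)
    scale = 1.0 / np.asarray(k1, dtype=float)
    if scheme == "sequential":
        # sum of Exp(N k1), Exp((N-1) k1), ..., Exp(k1)
        steps = rng.exponential(1.0, size=(n_vesicles, N))
        rates = np.arange(N, 0, -1, dtype=float)
        return (steps / rates).sum(axis=1) * scale
    # concurrent: all N clocks must fire
    return rng.exponential(1.0, size=(n_vesicles, N)).max(axis=1) * scale


def sample_fusion_times(protocol: SimulationProtocol, trial: int) -> np.ndarray:
    """Fusion times of every vesicle in one trial (baseline/heterogeneous)."""
    rng = _trial_rng(protocol.seed, trial)
    n1, n2 = protocol.pools.as_integers()
    kin = protocol.kin
    if protocol.variant == "heterogeneous_ca":
        raise ValueError("use simulate_heterogeneous_ca, which needs SNAREEnergetics")
    if protocol.variant == "finite_capacity":
        return _gillespie_finite_capacity(rng, protocol)
    tf = _fast_times(rng, n1, kin.N, kin.k1, protocol.scheme)
    ts = rng.exponential(1.0 / kin.k2, size=n2) + _fast_times(
        rng, n2, kin.N, kin.k1, protocol.scheme
    )
    return np.concatenate([tf, ts])


def _gillespie_finite_capacity(rng, protocol: SimulationProtocol) -> np.ndarray:
    """Event-driven simulation with a shared docking-site counter.

    State: ``reserve`` undocked slow-pool vesicles; ``staged[i]`` docked
    vesicles with i completed SNARE transitions.  Replenishment fires at
    rate k2 * reserve while the docked count is strictly below capacity.
    """
    n1, n2 = protocol.pools.as_integers()
    N, k1, k2 = protocol.kin.N, protocol.kin.k1, protocol.kin.k2
    cap = int(protocol.capacity)
    staged = np.zeros(N, dtype=np.int64)
    staged[0] = n1
    reserve = n2
    t = 0.0
    fusion_times = []
    flip_rates = np.arange(N, 0, -1, dtype=float) * k1  # rate (N-i) k1 per vesicle at stage i
    while True:
        docked = int(staged.sum())
        props = staged * flip_rates
        a_refill = k2 * reserve if docked < cap else 0.0
        a_tot = props.sum() + a_refill
        if a_tot == 0.0:
            break
        t += rng.exponential(1.0 / a_tot)
        if t > protocol.t_end:
            break
        u = rng.uniform(0.0, a_tot)
        if u < a_refill:
            reserve -= 1
            staged[0] += 1
            continue
        u -= a_refill
        i = int(np.searchsorted(np.cumsum(props), u, side="right"))
        staged[i] -= 1
        if i + 1 == N:
            fusion_times.append(t)
        else:
            staged[i + 1] += 1
    return np.asarray(fusion_times)


def _summarise(all_times, protocol: SimulationProtocol, ntot: int) -> SimulationResult:
    grid = protocol.time_grid()
    cps = protocol.checkpoint_times()
    s = np.zeros(len(grid))
    s2 = np.zeros(len(grid))
    hists = np.zeros((len(cps), ntot + 1), dtype=np.int64)
    for times in all_times:
        times = np.sort(times)
        counts = np.searchsorted(times, grid, side="right")
        s += counts
        s2 += counts.astype(float) ** 2
        cp_counts = np.searchsorted(times, cps, side="right")
        for k, m in enumerate(cp_counts):
            hists[k, m] += 1
    n = protocol.n_trials
    mean = s / n
    var = np.maximum(s2 / n - mean**2, 0.0)
    se = np.sqrt(var / n)
    rate = np.gradient(mean, grid)
    return SimulationResult(
        t_grid=grid,
        mean_cumulative=mean,
        mean_rate=rate,
        se_cumulative=se,
        checkpoint_times=cps,
        count_histograms=hists,
        n_trials=n,
    )


def simulate(protocol: SimulationProtocol) -> SimulationResult:
    """Run the configured number of independent trials and summarise them."""
    if protocol.variant == "heterogeneous_ca":
        raise ValueError("heterogeneous_ca requires simulate_heterogeneous_ca(protocol, e)")
    n1, n2 = protocol.pools.as_integers()
    all_times = (sample_fusion_times(protocol, i) for i in range(protocol.n_trials))
    return _summarise(all_times, protocol, n1 + n2)


def simulate_finite_capacity(protocol: SimulationProtocol) -> SimulationResult:
    if protocol.variant != "finite_capacity":
        raise ValueError("protocol.variant must be 'finite_capacity'")
    return simulate_with_variant_dispatch(protocol)


def simulate_with_variant_dispatch(protocol: SimulationProtocol) -> SimulationResult:
    n1, n2 = protocol.pools.as_integers()
    all_times = (sample_fusion_times(protocol, i) for i in range(protocol.n_trials))
    return _summarise(all_times, protocol, n1 + n2)


def simulate_heterogeneous_ca(
    protocol: SimulationProtocol, e: SNAREEnergetics
) -> SimulationResult:
    """Mixture over release sites: each vesicle's k1 = snare_rate(its site's ca)."""
    if protocol.variant != "heterogeneous_ca":
        raise ValueError("protocol.variant must be 'heterogeneous_ca'")
    rates = np.array([snare_rate(ca, e) for ca in protocol.ca_sites])  # validates c < 1
    weights = np.asarray(
        protocol.ca_weights or [1.0 / len(rates)] * len(rates), dtype=float
    )
    n1, n2 = protocol.pools.as_integers()
    N, k2 = protocol.kin.N, protocol.kin.k2

    def one_trial(trial):
        rng = _trial_rng(protocol.seed, trial)
        site1 = rng.choice(len(rates), size=n1, p=weights)
        site2 = rng.choice(len(rates), size=n2, p=weights)
        tf = _fast_times(rng, n1, N, rates[site1], protocol.scheme)
        ts = rng.exponential(1.0 / k2, size=n2) + _fast_times(
            rng, n2, N, rates[site2], protocol.scheme
        )
        return np.concatenate([tf, ts])

    all_times = (one_trial(i) for i in range(protocol.n_trials))
    return _summarise(all_times, protocol, n1 + n2)


# ---------------------------------------------------------------------------
# synthetic tabular fixtures


def _noise_factors(rng, cv: float, size: int, model: str) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    if model == "lognormal":
        sigma2 = np.log1p(cv**2)
        return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)
    if model == "gaussian":
        return 1.0 + cv * rng.standard_normal(size)
    raise ValueError(f"unknown noise model {model!r}")


def generate_fixture(
    kind: str,
    truth: dict,
    noise_cv: float = 0.0,
    n_points: int = 12,
    seed: int = 0,
    noise_model: str = "lognormal",
) -> pd.DataFrame:
    """Emit a synthetic experimental-style table from known ground truth.

    kind = "dose_response": columns (ca_uM, peak_rate_per_ms); the peak rate
        follows the closed-form peak with k1 = snare_rate(ca).  truth keys:
        ``e`` (SNAREEnergetics), ``kin`` (FusionKinetics; its k1 is replaced
        per concentration), ``pools``, optional ``ca_range`` (lo, hi) uM.
    kind = "cumulative_traces": columns (t_ms, n_cum, ca_uM), one trace per
        concentration from the exact mean cumulative release.  truth keys:
        ``e``, ``kin``, ``pools``, ``ca_list``, optional ``t_range``.
    kind = "ppr_curve": columns (tau_int_ms, ppr) from the syt7 or
        buffer-saturation paired-pulse model.  truth keys: ``mechanism``,
        ``protocol`` (PairedPulseProtocol), ``kin``, ``e``, optional
        ``tau_range`` (lo, hi) ms.

    Noise is multiplicative with coefficient of variation ``noise_cv``
    (lognormal by default, mean-one; gaussian available).
    """
    from .kinetics import cumulative_release, peak_release

    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)

    if kind == "dose_response":
        e, kin, pools = truth["e"], truth["kin"], truth["pools"]
        lo, hi = truth.get("ca_range", (1.0, 100.0))
        ca = np.geomspace(lo, hi, n_points)
        peaks = np.array(
            [
                peak_release(
                    pools,
                    FusionKinetics(N=kin.N, k1=snare_rate(c, e), k2=kin.k2),
                    method="approx",
                ).peak_rate
                for c in ca
            ]
        )
        peaks = peaks * _noise_factors(rng, noise_cv, len(ca), noise_model)
        return pd.DataFrame({"ca_uM": ca, "peak_rate_per_ms": peaks})

    if kind == "cumulative_traces":
        e, kin, pools = truth["e"], truth["kin"], truth["pools"]
        ca_list = truth["ca_list"]
        frames = []
        for ca in ca_list:
            k1 = snare_rate(ca, e)
            kin_ca = FusionKinetics(N=kin.N, k1=k1, k2=kin.k2)
            lo, hi = truth.get("t_range", (0.05 / k1, 5.0 / kin.k2))
            t = np.geomspace(lo, hi, n_points)
            n = cumulative_release(t, pools, kin_ca)
            n = n * _noise_factors(rng, noise_cv, len(t), noise_model)
            frames.append(pd.DataFrame({"t_ms": t, "n_cum": n, "ca_uM": ca}))
        return pd.concat(frames, ignore_index=True)

    if kind == "ppr_curve":
        mechanism = truth["mechanism"]
        base: PairedPulseProtocol = truth["protocol"]
        kin, e = truth["kin"], truth["e"]
        lo, hi = truth.get("tau_range", (1.0, 1e4))
        tau = np.geomspace(lo, hi, n_points)
        fn = {"syt7": ppr_syt7, "buffer": ppr_buffer}.get(mechanism)
        if fn is None:
            raise ValueError(f"unknown mechanism {mechanism!r}")
        ppr = np.array([fn(base.with_interval(ti), kin, e) for ti in tau])
        ppr = ppr * _noise_factors(rng, noise_cv, len(tau), noise_model)
        return pd.DataFrame({"tau_int_ms": tau, "ppr": ppr})

    raise ValueError(f"unknown fixture kind {kind!r}")
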