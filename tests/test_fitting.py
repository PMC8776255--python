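"""Parameter extraction: self-consistency, recovery under noise,
identifiability, and model discrimination."""

import numpy as np
import pandas as pd
import pytest

from presyn import (
    CumulativeTraceModel,
    DoseResponseModel,
    FusionKinetics,
    K1CurveModel,
    PairedPulseProtocol,
    SNAREEnergetics,
    VesiclePools,
    collapse_pipeline,
    cumulative_release,
    fit_cumulative_traces,
    fit_dose_response,
    fit_k1_curve,
    fit_power_law,
    fit_ppr,
    generate_fixture,
    snare_rate,
)


TRUTH_E = SNAREEnergetics(dG=20.0, nCa=4.0, k0=0.01, ca0=1.0)
TRUTH_KIN = FusionKinetics(N=2, k1=1.0, k2=1e-4)
TRUTH_POOLS = VesiclePools(100.0, 0.0)  # A = ntot1 k0 = 1 vesicle/ms


def dose_fixture(noise_cv=0.0, seed=0, n_points=10, ca_range=(1.0, 50.0)):
    return generate_fixture(
        "dose_response",
        {"e": TRUTH_E, "kin": TRUTH_KIN, "pools": TRUTH_POOLS, "ca_range": ca_range},
        noise_cv=noise_cv, n_points=n_points, seed=seed,
    )


def trace_fixture(noise_cv=0.0, seed=0, n_points=20, k1s=(0.5, 1.0, 2.0, 4.0),
                  t_max=500.0, ntot=(1500.0, 3000.0), k2=0.01):
    rng = np.random.default_rng(seed)
    frames = []
    for k1 in k1s:
        kin = FusionKinetics(N=2, k1=k1, k2=k2)
        pools = VesiclePools(*ntot)
        t = np.geomspace(0.05 / k1, t_max, n_points)
        n = cumulative_release(t, pools, kin)
        if noise_cv:
            s2 = np.log1p(noise_cv**2)
            n = n * rng.lognormal(-s2 / 2, np.sqrt(s2), len(t))
        frames.append(pd.DataFrame({"t_ms": t, "n_cum": n, "ca_uM": k1}))
    return pd.concat(frames, ignore_index=True)


class TestDoseResponse:
    def test_noiseless_self_consistency(self):
        res = fit_dose_response(dose_fixture(), ca0=1.0, N=2, seed=0)
        assert res.params["dG"] == pytest.approx(20.0, rel=1e-6)
        assert res.params["nCa"] == pytest.approx(4.0, rel=1e-6)
        assert res.params["A"] == pytest.approx(1.0, rel=1e-6)
        assert res.converged

    def test_recovery_under_noise(self):
        errs = {"dG": [], "nCa": [], "A": []}
        for seed in range(10):
            df = dose_fixture(noise_cv=0.05, seed=seed, n_points=12, ca_range=(1, 100))
            res = fit_dose_response(df, ca0=1.0, N=2, seed=seed)
            for k, truth in (("dG", 20.0), ("nCa", 4.0), ("A", 1.0)):
                errs[k].append(abs(res.params[k] - truth) / truth)
        for k in errs:
            assert np.median(errs[k]) < 0.10

    def test_super_assembly_flag_raised_for_steep_sensors(self):
        e6 = SNAREEnergetics(dG=25.0, nCa=6.0, k0=0.01, ca0=1.0)
        df = generate_fixture(
            "dose_response",
            {"e": e6, "kin": TRUTH_KIN, "pools": TRUTH_POOLS, "ca_range": (1, 30)},
            noise_cv=0.02, n_points=12, seed=3,
        )
        m = DoseResponseModel(N=2, ca0=1.0, seed=3).fit(
            df[["ca_uM"]].values, df["peak_rate_per_ms"].values
        )
        assert m.nCa_ > 5.0
        assert m.super_assembly_
        assert any("super-assembly" in w for w in m.result_.warnings)

    def test_row_order_and_amplitude_invariance(self):
        df = dose_fixture(noise_cv=0.05, seed=1)
        res = fit_dose_response(df, ca0=1.0, N=2, seed=5)
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        res_shuf = fit_dose_response(shuffled, ca0=1.0, N=2, seed=5)
        assert res_shuf.params["dG"] == pytest.approx(res.params["dG"], rel=1e-6)
        scaled = df.assign(peak_rate_per_ms=df.peak_rate_per_ms * 1e3)
        res_scaled = fit_dose_response(scaled, ca0=1.0, N=2, seed=5)
        assert res_scaled.params["A"] == pytest.approx(1e3 * res.params["A"], rel=1e-6)
        assert res_scaled.params["dG"] == pytest.approx(res.params["dG"], rel=1e-4)

    def test_deterministic_for_fixed_seed(self):
        df = dose_fixture(noise_cv=0.05, seed=2)
        a = fit_dose_response(df, ca0=1.0, N=2, seed=9)
        b = fit_dose_response(df, ca0=1.0, N=2, seed=9)
        assert a.params == b.params

    def test_amplitude_degeneracy_reported_not_resolved(self):
        # the dose-response curve constrains only A = ntot1 k0: moving along
        # the ridge leaves the predicted curve (hence resid_ss) unchanged
        df = dose_fixture()
        m = DoseResponseModel(N=2, ca0=1.0, seed=0).fit(
            df[["ca_uM"]].values, df["peak_rate_per_ms"].values
        )
        assert "ntot1" not in m.result_.params and "k0" not in m.result_.params
        pred = m.predict(df[["ca_uM"]].values)
        for scale in (0.1, 10.0):
            e = SNAREEnergetics(dG=m.dG_, nCa=m.nCa_, k0=m.A_ / scale, ca0=m.ca0_)
            # ntot1 = scale, k0 = A/scale: same product, same curve
            alt = scale * np.array([snare_rate(c, e) for c in df.ca_uM]) / e.k0 * e.k0 * 0.5
            assert np.allclose(alt, pred, rtol=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4"):
            fit_dose_response(dose_fixture(n_points=3), ca0=1.0)

    def test_default_reference_is_geometric_mean(self):
        df = dose_fixture()
        m = DoseResponseModel(N=2, seed=0).fit(
            df[["ca_uM"]].values, df["peak_rate_per_ms"].values
        )
        assert m.ca0_ == pytest.approx(float(np.exp(np.mean(np.log(df.ca_uM)))))


class TestK1Curve:
    def test_noiseless_self_consistency(self):
        ca = np.geomspace(1.0, 50.0, 10)
        df = pd.DataFrame({"ca_uM": ca, "k1_per_ms": [snare_rate(c, TRUTH_E) for c in ca]})
        res = fit_k1_curve(df, ca0=1.0, seed=0)
        assert res.params["dG"] == pytest.approx(20.0, rel=1e-6)
        assert res.params["nCa"] == pytest.approx(4.0, rel=1e-6)
        assert res.params["k0"] == pytest.approx(0.01, rel=1e-6)

    def test_recovery_under_noise(self):
        rng = np.random.default_rng(0)
        errs = []
        for seed in range(8):
            ca = np.geomspace(1.0, 50.0, 12)
            k = np.array([snare_rate(c, TRUTH_E) for c in ca])
            s2 = np.log1p(0.05**2)
            k = k * rng.lognormal(-s2 / 2, np.sqrt(s2), len(k))
            res = fit_k1_curve(pd.DataFrame({"ca_uM": ca, "k1_per_ms": k}), ca0=1.0, seed=seed)
            errs.append(abs(res.params["nCa"] - 4.0) / 4.0)
        assert np.median(errs) < 0.10

    def test_beats_fourth_power_model_under_saturation(self):
        # fixture generated from the saturating rate law with c up to ~0.7
        e = SNAREEnergetics(dG=15.0, nCa=4.0, k0=0.01, ca0=1.0)
        ca_hi = float(np.exp(0.7 * 3 * 15.0 / (2 * 4.0)))
        ca = np.geomspace(1.0, ca_hi, 14)
        df = pd.DataFrame({"ca_uM": ca, "k1_per_ms": [snare_rate(c, e) for c in ca]})
        barrier = fit_k1_curve(df, ca0=1.0, seed=0)
        power4 = fit_power_law(df, exponent=4.0)
        assert barrier.resid_ss < power4.resid_ss


class TestCumulativeTraces:
    def test_noiseless_joint_recovery(self):
        df = trace_fixture()
        res, _ = fit_cumulative_traces(df, N=2, seed=0)
        assert res.params["ntot1"] == pytest.approx(1500.0, rel=1e-4)
        assert res.params["ntot2"] == pytest.approx(3000.0, rel=1e-4)
        assert res.params["k2"] == pytest.approx(0.01, rel=1e-4)
        for k1 in (0.5, 1.0, 2.0, 4.0):
            assert res.params[f"k1@{k1:g}uM"] == pytest.approx(k1, rel=1e-4)

    def test_model_selection_prefers_true_stoichiometry(self):
        wins = 0
        for seed in range(5):
            df = trace_fixture(noise_cv=0.03, seed=seed)
            m = CumulativeTraceModel(N="select", N_candidates=(1, 2, 3, 4), n_starts=4,
                                     seed=seed)
            m.fit(df[["t_ms", "ca_uM"]].values, df["n_cum"].values)
            wins += m.N_ == 2
        assert wins >= 4
        assert set(m.selection_table_["N"]) == {1, 2, 3, 4}
        assert m.selection_table_.loc[m.selection_table_.resid_ss.idxmin(), "N"] == m.N_

    def test_truncated_traces_identify_rrp_but_only_replenishment_product(self):
        # no slow phase: <n> ~ ntot1 + (ntot2 k2) t, so k2 is fixed to the
        # prior and only the product ntot2 * k2 is meaningful
        df = trace_fixture(t_max=5.0, n_points=14)
        with pytest.warns(UserWarning, match="k2"):
            res, _ = fit_cumulative_traces(df, N=2, seed=0, k2_prior=0.02)
        assert res.params["ntot1"] == pytest.approx(1500.0, rel=0.05)
        product = res.params["ntot2"] * res.params["k2"]
        assert product == pytest.approx(3000.0 * 0.01, rel=0.05)
        assert res.params["k2"] == 0.02  # pinned to the prior

    def test_short_traces_rejected(self):
        df = trace_fixture(n_points=5)
        with pytest.raises(ValueError, match="8"):
            fit_cumulative_traces(df, N=2)


class TestPairedPulseFits:
    KNOWN_SYT7 = {"N": 2, "T": 1.0, "k1": 1.0}
    E10 = SNAREEnergetics(dG=20.0, nCa=4.0, k0=1.0, ca0=10.0)

    def syt7_fixture(self, noise_cv=0.0, seed=0):
        proto = PairedPulseProtocol(
            T=1.0, tau_int=1.0, tau_RRP=200.0, tau_res=50.0, sigma=2.0, ca_i=10.0
        )
        # facilitating synapses run at moderate release probability
        # (k1 T = 1): saturated release would mask sigma, while very weak
        # depletion would leave tau_RRP unconstrained
        kin = FusionKinetics(N=2, k1=1.0, k2=0.01)
        # 25 intervals over 2 ms - 2 s: dense enough that the facilitation
        # decay (tau_res) and RRP recovery (tau_RRP) are each resolved at
        # 5% measurement noise
        return generate_fixture(
            "ppr_curve",
            {"mechanism": "syt7", "protocol": proto, "kin": kin, "e": self.E10,
             "tau_range": (2.0, 2000.0)},
            noise_cv=noise_cv, n_points=25, seed=seed,
        )

    def buffer_fixture(self, noise_cv=0.0, seed=0):
        proto = PairedPulseProtocol(
            T=1.0, tau_int=1.0, tau_RRP=200.0, tau_Ca=100.0, I_Ca=3.0, ca_i=10.0
        )
        kin = FusionKinetics(N=2, k1=1.0, k2=0.01)
        return generate_fixture(
            "ppr_curve", {"mechanism": "buffer", "protocol": proto, "kin": kin, "e": self.E10},
            noise_cv=noise_cv, n_points=14, seed=seed,
        )

    def test_noiseless_syt7_recovery(self):
        res = fit_ppr(self.syt7_fixture(), "syt7", self.KNOWN_SYT7, seed=0)
        assert res.params["sigma"] == pytest.approx(2.0, rel=1e-5)
        assert res.params["tau_res"] == pytest.approx(50.0, rel=1e-5)
        assert res.params["tau_RRP"] == pytest.approx(200.0, rel=1e-5)

    def test_syt7_recovery_under_noise(self):
        errs = {"sigma": [], "tau_res": [], "tau_RRP": []}
        for seed in range(50):
            res = fit_ppr(self.syt7_fixture(noise_cv=0.05, seed=seed), "syt7",
                          self.KNOWN_SYT7, seed=seed)
            for k, truth in (("sigma", 2.0), ("tau_res", 50.0), ("tau_RRP", 200.0)):
                errs[k].append(abs(res.params[k] - truth) / truth)
        for k in errs:
            assert np.median(errs[k]) < 0.15

    def test_wrong_mechanism_fits_worse(self):
        wins = 0
        for seed in range(5):
            df = self.buffer_fixture(noise_cv=0.05, seed=seed)
            right = fit_ppr(df, "buffer", {"N": 2, "T": 1.0, "e": self.E10, "ca_i": 10.0},
                            seed=seed)
            wrong = fit_ppr(df, "syt7", self.KNOWN_SYT7, seed=seed)
            wins += right.resid_ss < wrong.resid_ss
        assert wins >= 4

    def test_interval_range_requirement(self):
        df = self.syt7_fixture().head(6)
        narrow = df.assign(tau_int_ms=np.linspace(10, 20, 6))
        with pytest.raises(ValueError, match="decade"):
            fit_ppr(narrow, "syt7", self.KNOWN_SYT7)


class TestCollapsePipeline:
    def make_tables(self, noise_cv, seeds):
        rng = np.random.default_rng(1234)
        tables = {}
        for sid in range(10):
            e = SNAREEnergetics(
                dG=rng.uniform(10, 30), nCa=rng.uniform(2, 6),
                k0=10 ** rng.uniform(-2, 0), ca0=10 ** rng.uniform(0, 1),
            )
            kin = FusionKinetics(N=2, k1=1.0, k2=1e-4)
            pools = VesiclePools(rng.uniform(50, 500), 0.0)
            ca_range = (e.ca0 * 0.5, e.ca0 * float(np.exp(0.8 * 3 * e.dG / (2 * e.nCa))))
            tables[f"syn{sid}"] = generate_fixture(
                "dose_response", {"e": e, "kin": kin, "pools": pools, "ca_range": ca_range},
                noise_cv=noise_cv, n_points=10, seed=seeds + sid,
            )
        return tables

    def test_noiseless_synapses_collapse(self):
        points, rms = collapse_pipeline(self.make_tables(0.0, 0), N=2, seed=0)
        assert rms < 1e-3
        assert len(points) == 100

    def test_noisy_collapse_consistent_with_noise_level(self):
        points, rms = collapse_pipeline(self.make_tables(0.05, 100), N=2, seed=0)
        # r ~ (noisy peak)^(1/dG): 5% rate noise maps to ~0.05 r/dG spread
        assert 1e-4 < rms < 0.05

    def test_single_point_at_reference_maps_to_unity(self):
        df = dose_fixture()
        m = DoseResponseModel(N=2, ca0=1.0, seed=0).fit(
            df[["ca_uM"]].values, df["peak_rate_per_ms"].values
        )
        points, _ = collapse_pipeline({"s": df.iloc[:1]}, fits={"s": m})
        assert points.c.iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert points.r.iloc[0] == pytest.approx(1.0, rel=1e-6)
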