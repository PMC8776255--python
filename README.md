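# presyn

Analytic theory of action-potential-evoked neurotransmitter release at the
chemical synapse, as a reusable Python library and CLI.

Neurotransmitter release happens when docked synaptic vesicles fuse with the
presynaptic membrane within a millisecond of calcium influx. `presyn`
implements a unifying kinetic description of this process — closed-form
release kinetics, a calcium-dependent SNARE conformational rate, a universal
rescaling of dose-response data, short-term-plasticity models, and
transmission fidelity/efficacy metrics — together with an exact stochastic
simulator and least-squares machinery to extract the molecular parameters of
a synapse from reduced experimental tables. It is written for computational
neuroscientists and biophysicists who want to fit release data, test
facilitation hypotheses, or generate calibrated synthetic data.

## The model

Vesicle fusion proceeds through two parallel pathways. A fast-pool (readily
releasable, RRP) vesicle of which there are `ntot1` fuses when all `N`
independent SNARE assemblies tethering it complete a calcium-triggered
conformational step at rate `k1`; a slow-pool (reserve) vesicle of which
there are `ntot2` first waits one slow step at rate `k2 << k1`
(replenishment in vivo, hemifusion escape in vitro). The mean release rate
and cumulative release are exact sums of exponentials; the fast-pathway
fusion probability is `F1(t) = (1 - e^(-k1 t))^N`.

The calcium dependence of `k1` follows from barrier-crossing (Kramers)
kinetics with the logarithm of calcium concentration acting as the force
that tilts the energy profile:

    k1([Ca]) = k0 (1 - c)^(1/2) exp[ (ΔG‡/kBT) (1 - (1 - c)^(3/2)) ],
    c = (2 nCa‡ kBT / 3 ΔG‡) ln([Ca]/[Ca]0)

with barrier `ΔG‡`, transition-state calcium occupancy `nCa‡`, and reference
rate `k0` at `[Ca]0`. At low concentration this reduces to the power law
`(Ca/Ca0)^nCa‡`; at high concentration it saturates, which a fixed power law
cannot do. Rescaling the peak release rate by
`r = (a (1-c)^(-1/2) · peak)^(kBT/ΔG‡)` with
`a = (1 + 1/(N-1))^(N-1)/(ntot1 k0)` collapses any synapse's dose-response
curve onto the single master curve `r = exp[1 - (1-c)^(3/2)]`.

On top of the kinetics the package provides paired-pulse-ratio models for
three facilitation mechanisms (pure residual calcium, syt7 facilitation
sensor, calcium-buffer saturation), the binomial failure probability of
transmission with its Chernoff bound, the total error probability balancing
failures against spontaneous "error reads", and the optimal RRP size.

## Worked example

Generate a noisy synthetic dose-response table from known ground truth and
recover the parameters:

```python
from presyn import (SNAREEnergetics, FusionKinetics, VesiclePools,
                    generate_fixture, fit_dose_response)

truth = SNAREEnergetics(dG=20.0, nCa=4.0, k0=0.01, ca0=1.0)   # kBT, ions, 1/ms, uM
kin = FusionKinetics(N=2, k1=1.0, k2=1e-4)
pools = VesiclePools(ntot1=100.0, ntot2=0.0)                  # A = ntot1*k0 = 1

table = generate_fixture(
    "dose_response",
    {"e": truth, "kin": kin, "pools": pools, "ca_range": (1, 100)},
    noise_cv=0.05, n_points=12, seed=11,
)
result = fit_dose_response(table, ca0=1.0, N=2, seed=11)
print(result.params)
```

This prints (5% multiplicative noise, seed 11):

```
{'dG': 20.228, 'nCa': 3.973, 'A': 1.037, 'ca0': 1.0}
```

i.e. the activation barrier is recovered as 20.2 kBT (truth 20), the
transition-state occupancy as 3.97 calcium ions (truth 4), and the amplitude
`A = ntot1·k0` as 1.04 vesicles/ms (truth 1). `ntot1` and `k0` are reported
only as their product because a dose-response curve cannot separate them. A
fitted `nCa > 5` would set the `super_assembly` flag: a single SNARE binds at
most five calcium ions, so a larger exponent indicates cooperative
multi-SNARE super-assemblies.

The same estimators are available in scikit-learn form
(`DoseResponseModel`, `K1CurveModel`, `CumulativeTraceModel`,
`PairedPulseModel` with `fit`/`predict`), and the command line mirrors the
library:

```bash
presyn fixture --kind dose_response --seed 7 --out dose.csv
presyn fit-dose --data dose.csv --seed 7 --report fit.json
presyn ppr --mechanism buffer --out ppr.csv --report ppr.json
```

## Layout

- `presyn.kinetics` — exact release rate, cumulative release, fusion-time
  and release-count distributions, peak characteristics
- `presyn.snare` — calcium-dependent SNARE rate, dimensionless rescaling,
  master curve
- `presyn.simulation` — stochastic simulator (baseline, finite docking
  capacity, heterogeneous calcium) and synthetic fixture generator
- `presyn.fitting` — sklearn-style estimators and functional fitting API,
  data-collapse pipeline
- `presyn.plasticity` — paired-pulse ratio models and optimal-interval search
- `presyn.transmission` — fidelity, error probability, Chernoff bounds,
  optimal RRP size
- `presyn.io` / `presyn.cli` — CSV schemas, validated JSON config, CLI

See `docs/methods.md` for modelling assumptions, parameter conventions,
numerical choices and known limitations.
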