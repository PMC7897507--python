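# ssbkin

Kinetics of *E. coli* single-stranded-DNA binding protein (EcSSB) on long
ssDNA under tension: a two-step competitive binding model with
near-neighbour stimulated unwrapping and dissociation, plus the simulation
and fitting machinery of constant-force optical-tweezers experiments.

## The science

EcSSB tetramers occupy ssDNA in two classes of states at forces above
~8 pN: a **bound-but-unwrapped** state (one OB-fold domain, footprint
n_b = 8 nt, compaction x_b = 0.0159 nm/nt of occupancy) and a **wrapped**
state (n_w = 17 nt at 12 pN, x_w = 0.083 nm/nt; 35 nt at 7 pN).  The
occupancy fractions Θ₀ (free), Θ_b and Θ_w evolve through the chain

    Θ₀  ⇌(k_b·c / k₋b)  Θ_b  ⇌(k_w·Θ₀ / k₋w)  Θ_w

with the twist that both back rates are *stimulated* by crowding:

    k₋b(Θ_b) = k_off + k_off_stim · Θ_b
    k₋w(Θ_b) = k_unw + k_unw_stim · Θ_b

A lattice loaded at high free-protein concentration therefore compacts
rapidly (bind-wrap), then partially re-extends as oversaturation stimulates
unwrapping (bind-unwrap); removing free protein lets excess protein leave
and the remainder wrap fully (unbind-wrap, plateau ≈ x_w ≈ 0.08 nm/nt).
The model tracks protein densities β (bound) and ω (wrapped) per
nucleotide; binding flux has a capacity-loading channel (fractional fill at
k_b·c, the calibrated on-rate) and a per-nucleotide competitive channel
once the wrapped capacity u = n_w·(β+ω) saturates, which sets the critical
concentration (~3.4 nM for the calibrated set) where Θ_b = Θ_w at
equilibrium.

The package provides:

* `model_core` — the mean-field ODE, equilibrium and critical-concentration
  solvers, force-regime table, analytic helpers;
* `protocols` — piecewise concentration/force protocols → ideal compaction
  traces, force jumps, the non-wrapping (H55Y mutant) limit;
* `synthetic_data` — seeded noisy traces, replicated concentration series,
  RecA saturation curves;
* `fitting` — phase segmentation, exponential rate fits, serial two-step
  rate-curve recovery of (k_b, k_w), isotherm fits, step detection;
* `lattice_oracle` — exact stochastic (Gillespie) simulation of individual
  footprint-carrying proteins on an 8.1-knt lattice;
* `reca` — RecA filamentation on bare vs SSB-coated ssDNA (SSB-dissociation
  rate-limited);
* a `ssbkin` command line (`simulate`, `noise`, `fit`, `sweep`, `oracle`,
  `reca`, `report`).

## Worked example

```python
import ssbkin as sk

params = sk.table1_parameters()          # calibrated 12 pN parameter set
print(sk.critical_concentration(params))  # 3.4216

proto = sk.incubate_rinse_protocol(50.0, t_incubate=300, t_rinse=300)
trace = sk.simulate_protocol(proto, params)
print(trace.compaction[-1])               # 0.0830  (nm/nt after rinse)

for fit in sk.analyze_trace(trace):
    print(fit.label, round(fit.rate, 4))
# bind-wrap 2.3202      fast loading at 50 nM
# bind-unwrap 0.0788    stimulated unwrapping of the oversaturated complex
# unbind-wrap 0.1154    dissociation-limited re-wrapping after the rinse
```

The critical concentration (3.4 nM) is where bound-unwrapped and wrapped
occupancies balance; the 0.083 nm/nt plateau is the compaction of a fully
wrapped lattice; 0.115 s⁻¹ is the stimulated-dissociation-limited rinse
relaxation.  A parameter round trip through noisy synthetic data:

```python
series = sk.generate_concentration_series(sk.prose_parameters(),
                                          noise=sk.NoiseModel(seed=0))
rc = sk.fit_rate_curve(series)
print(rc.k_b, rc.k_w)   # ~0.18 nM^-1 s^-1, ~1.9 s^-1
```

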