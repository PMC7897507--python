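# Methods

## Model

State variables are protein densities per nucleotide on a long ssDNA
lattice held at constant tension: β (bound-unwrapped tetramers, footprint
n_b = 8 nt) and ω (wrapped tetramers, footprint n_w = 17 nt at 12 pN).
Occupancy fractions are Θ_b = n_b·β, Θ_w = n_w·ω, Θ₀ = 1 − Θ_b − Θ_w, so
conservation holds identically.  The dynamics are

    dβ/dt = J(c, β, ω) − k₋b(Θ_b)·β − k_w·φ·β + k₋w(Θ_b)·ω
    dω/dt = k_w·φ·β − k₋w(Θ_b)·ω

with stimulated back rates linear in the bound-unwrapped occupancy,

    k₋b = k_off + k_off_stim·Θ_b,     k₋w = k_unw + k_unw_stim·Θ_b,

the minimal law consistent with rates proportional to the fraction of
substrate held by bound-but-unwrapped protein.  Intrinsic unwrapping k_unw
is pinned to zero (only an upper bound, <0.01 s⁻¹, is calibrated); it can
be overridden per parameter set.

**Binding flux.**  Two channels:

    J = k_b·c·[ (1 − u)₊ / n_w  +  Θ₀·σ(u) ],        u = n_w·(β + ω)

u is the *wrapped-capacity saturation* — the fraction of the lattice the
current protein complement would occupy if fully wrapped.  The first
(capacity) channel describes loading of unsaturated substrate: proteins
occupy effectively independent sites and the fractional filling rate is
exactly k_b·c, which is how the bimolecular on-rate is calibrated (0.150
s⁻¹ at 1 nM for the reference set).  The second channel switches on as the
capacity saturates (σ is a smoothstep over u ∈ [0.98, 1.04]) and counts
every free nucleotide as a competitive rebinding target; it governs the
oversaturated equilibria and reproduces the calibrated critical
concentration (3.42 nM computed vs 3.40 published for the same rates).  A
single-channel flux cannot do both: per-nucleotide binding alone
reproduces the equilibria but fills the lattice n_w-fold too fast (no
biphasic transient, wrong apparent-rate slope), while capacity-normalised
binding alone shifts the critical concentration ~17-fold.

**Wrapping availability.**  Wrapping consumes n_w − n_b = 9 extra nt, so
free substrate is rationed among candidates:

    φ = min(1, Θ₀ / ((n_w − n_b)·β))        (φ = 1 when β = 0)

multiplied by a smoothstep stall for Θ₀ below ~0.2% (between 5·10⁻⁴ and
2·10⁻³): the last sub-footprint gaps cannot be consolidated even with
sliding, which leaves a small free-substrate seed so that re-introduced
protein can invade a maximally wrapped lattice (the repeatable
concentration-cycling behaviour).  All calibrated equilibria sit at
Θ₀ ≥ 0.2% and are unaffected by the stall.

**Force regimes.**  7 pN: n_w = 35, x_w = 5 nm/35 nt; 12 pN: n_w = 17 with
the calibrated x_w = 0.083 nm/nt (the geometric 2 nm/17 nt ≈ 0.118 is kept
as a cross-check only); ≥15 pN: wrapping disabled.  In disabled regimes
(and for the non-tetramerising H55Y mutant, modelled simply as k_w = 0)
stimulation is also inactive — it is mediated by a neighbour wrapping into
freed substrate, which is impossible without wrapping — and pre-existing
wrapped protein unwinds at a fast nominal rate (1 s⁻¹; any value ≫ k_off
gives identical observables).  This yields the observed single-exponential
dissociation at the slow intrinsic rate (0.017 s⁻¹) at 20 pN and for the
mutant, and exp(−k_off·t) survival in 60 pN force jumps.

**Metastable full wrapping at low concentration.**  Below
c* = (k_off + k_w)/(9·k_b) ≈ 1 nM, a lattice loaded from empty arrests in
the fully wrapped state: freed substrate is reclaimed by wrapping faster
than solution protein can compete.  This reproduces the observed loss of
the second (unwrapping) phase at ~0.1 nM and the inert rinse there.
Consequence: the steady state is start-independent only above c*;
`equilibrate` defaults to the empty (loading-experiment) start and the
start-independence property is guaranteed (and tested) for c > c*.

## Parameters

Two shipped sets (JSON, unit-bearing field names):

| set | k_b (nM⁻¹s⁻¹) | k_off | k_w | k_off_stim | k_unw_stim |
|-----|------|------|------|------|------|
| `table1_12pN` | 0.150 | 0.0171 | 1.40 | 0.113 | 0.095 |
| `prose_12pN`  | 0.18  | 0.017  | 1.8  | 0.1   | 0.10  |

Both use n_b = 8, n_w = 17, x_b = 0.0159, x_w = 0.083 (compactions stored
as positive shortening magnitudes).  The two sets reflect the two
calibrations reported for the same system; the first is the simulation
calibration (critical concentration 3.40 nM), the second the directly
fitted phase-rate values.

## Numerics

LSODA with rtol 10⁻⁹ / atol 10⁻¹²; equilibria are integrated to steady
state and polished with a Newton solve (residual < 10⁻⁹ enforced, < 10⁻¹²
achieved).  The critical concentration brackets the sign change of
Θ_b − Θ_w on a 25-point log grid over 0.01–1000 nM and bisects to 10⁻³ nM.
Occupancies remain in [0, 1] along trajectories without clamping (asserted
to 10⁻⁹ in tests).  Solution exchange at protocol boundaries is
instantaneous by default (the emulated flow cell exchanges in ~1 s, below
every analysed phase timescale); a linear mixing ramp is available
(`exchange_ramp`) for sensitivity checks.  On force changes between
wrapping regimes the wrapped density is preserved and re-labelled into the
new footprint, capped so occupancy cannot exceed the lattice; no 17↔35
interconversion kinetics are calibrated, so the re-labelling is
instantaneous.

## Synthetic data

The generator emulates constant-force extension-per-nucleotide records at
10 Hz: additive white noise (σ = 0.005 nm/nt) plus slow linear drift
(0.002 nm/nt per 100 s).  No instrument noise figure is published for this
class of measurement; the defaults keep the shortest fitted phases at
signal-to-noise ≈ 5–10 per point, visibly noisy on single traces.  What the
generator does *not* emulate: bead Brownian-motion spectra, force-feedback
artefacts, flow disturbance during exchange, low-frequency non-linear
drift, and attachment rupture.  Passing round-trip tests therefore
demonstrate estimator correctness under the stated noise model, not
robustness to every instrumental pathology.  Per-trace seeds derive from a
master seed and stable (concentration, replicate) counters, so enlarging a
dataset never changes existing traces.  Default concentration series:
{0.1, 0.5, 1, 2, 5, 10, 20, 50} nM × 3 replicates of a 300 s incubation,
200 s rinse, 150 s re-incubation.

## Fitting

Phases are segmented at protocol boundaries; within an incubation segment
the bind-wrap/bind-unwrap split sits at the global compaction maximum
(robust to noise).  Each phase is fit with y = A·exp(−k(t−t₀)) + B
(k ∈ [10⁻⁴, 100] s⁻¹, initialised from the 63% crossing time); slow phases
occupying long windows are refit with a bounded linear drift term, since
drift competes with signals whose time constant approaches the window
length (the 0.017 s⁻¹ dissociation fit is unbiased this way; without the
drift term it reads ~50% high).  Offsets are per-phase (whether they
should be shared across phases is not established; per-phase is the
conservative choice).

Apparent bind-wrap rates across a concentration series are combined by
inverse-variance weighting over replicates and fit with the serial
two-step relation k_app = c·k_b·k_w/(c·k_b + k_w), with the largest
resolved rate as a lower bound on the asymptote (k_app < k_w strictly).
Rates whose fitted time constant is below 10 samples (1 s at 10 Hz) are
discarded as unresolved: they sit at the sampling limit and below the ~1 s
solution-exchange time of the emulated instrument, and their inclusion
biases the recovered k_w upward by ~25%.  A nonparametric option (slope of
the three lowest concentrations; plateau of the highest resolved ones) is
provided as a model-free cross-check.  The bind-unwrap asymptote and the
unbind-wrap rate are read off the most oversaturated (highest
concentration) series, where the stimulated pathway dominates.

Step detection uses a sliding two-sample t statistic with a Bonferroni
threshold; change points are local maxima separated by at least one window,
and step sizes are differences of level means (default minimum 1 nm).  The
published event-detection procedure for compaction staircases is not
available, so this is a standard change-point construction.

## Lattice oracle

The Gillespie simulation realises the same reaction network as the ODE for
individual proteins with explicit footprints on an L-nt lattice, adding
what the mean field ignores: footprint exclusion, parking-lot gap
statistics and spatial stimulation.  Stimulated rates use the
bound-unwrapped occupancy of the ±55 nt neighbourhood (the distance a
tetramer diffuses, √(D·t) with D = 300 nt²/s, during the ~10 s stimulated
dissociation timescale), excluding the protein itself; a binary
"any neighbour within the window" variant is selectable.  Fast reptational
sliding is coarse-grained as (i) uniform resampling of the gap composition
every 0.1 s — the stationary law of fast single-file diffusion, applied
well below the fastest reaction time 1/k_w ≈ 0.7 s — and (ii) footprint
gathering: binding and wrapping may assemble their nucleotides from gaps
within the ±55 nt window ("reorganisation maximises saturation").  With
sliding disabled, strict contiguity applies, nucleation is per contiguous
position, and the lattice jams with McGhee–von Hippel parking-lot gaps —
the reference for the coverage-ordering property.

Agreement with the mean field (20-replicate means, L = 8100, 60 s):
loading transients agree to a few percent at 0.1, 1 and 50 nM, and the
wrapped occupancy stays within 10% of the ODE throughout at 0.1 nM.  Two
regimes deviate beyond 10%: at 1 nM (just below c*) the stochastic lattice
escapes the metastable fully wrapped state by fluctuation on the
tens-of-seconds scale, which the deterministic mean field cannot, and at
50 nM the small wrapped fraction (Θ_w ≈ 0.05) depends on the
wrap-availability closure at near-zero free substrate, where resource
rationing (mean field) and window availability (lattice) genuinely differ
— the absolute deviation stays below 0.03 occupancy.  Both deviations are
properties of the mean-field approximation, not of the integrator, and are
left visible in the acceptance checks rather than absorbed into wider
tolerances.

## RecA competition

Filamentation on an idealised array of sites filling at rate r gives
S(t) = 1 − exp(−r·t); bare-ssDNA default r = 0.1 s⁻¹ (~10 s saturation).
On an SSB-coated substrate the effective rate is min(r, r_release) with
r_release = 0.003 s⁻¹ — the observed coated-filamentation rate, slower
even than the free dissociation rate 0.017 s⁻¹ because SSB additionally
inhibits RecA nucleation; that inhibition is folded into the single
effective release rate rather than modelled separately.  The exponential
(distributed-dissociation) shape, the ≥10× bare/coated ratio and the rate
ordering 0.003 < 0.017 < ~0.1 are asserted as properties.  A coupled mode
evolves (S, β, ω) jointly with RecA claiming free substrate; with the
calibrated sets (k_unw = 0) a maximally wrapped layer releases substrate
only through the stimulated pathway, so coupled filamentation stalls after
the initial free substrate is consumed — a qualitative illustration of
SSB-limited growth, not used for any quantitative result.

## Known limitations

* The mean-field binding closure (two channels, oversaturation gate) is a
  reconstruction validated against the published calibration outputs; the
  original coupled equations are not public.
* At saturating concentration the simulated loading is faster than the
  serial two-step idealisation, so the 50 nM bind-wrap rate exceeds the
  serial prediction; the resolution cutoff keeps this out of the recovered
  asymptote.
* The ablation of stimulated dissociation slows the simulated rinse
  relaxation 3.7×, not the full rate-constant ratio 7.6×: the unstimulated
  relaxation is paced by k_off·(1 + n_b/(n_w−n_b)) because every
  dissociation feeds wrap conversion of further bound protein.
* No Mg²⁺-dependent corrections, no 56/65-nt zero-force wrapping modes, no
  free-energy landscape reconstruction, no polymer (WLC/FJC) mechanics —
  extension is handled only as compaction in nm/nt.
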