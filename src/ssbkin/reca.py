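"""RecA filamentation on bare versus SSB-coated ssDNA.

RecA (with ATPgammaS) coats ssDNA effectively irreversibly; on a long
substrate the normalised extension follows a simple exponential saturation
S(t) = 1 - exp(-r t), the signature of an idealised array of sites filling
at a set rate — distributed, not sequential, occupation.  On an SSB-coated
substrate the same exponential shape appears but with the rate capped by
the rate at which SSB releases substrate, demonstrating that filamentation
is rate-limited by SSB dissociation.  The defaults encode the measured
values: bare-ssDNA filling at 0.1 s^-1 (~10 s saturation) and an effective
SSB-limited release at 0.003 s^-1 (~10x slower full saturation; slower even
than the 0.017 s^-1 free dissociation rate because SSB also inhibits RecA
nucleation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .model_core import ParameterSet, integrate
from .protocols import Trace
from .synthetic_data import NoiseModel, generate_reca_curve

__all__ = [
    "FilamentationParams",
    "simulate_filamentation",
    "simulate_filamentation_coupled",
    "fit_filamentation_rate",
]


@dataclass(frozen=True)
class FilamentationParams:
    bare_rate: float = 0.1          # site-filling rate on bare ssDNA (s^-1)
    ssb_release_rate: float = 0.003  # effective SSB-limited release (s^-1)
    duration: float = 1500.0         # s

    def __post_init__(self) -> None:
        if self.bare_rate <= 0 or self.ssb_release_rate <= 0:
            raise ValueError("rates must be positive")

    def effective_rate(self, ssb_coated: bool) -> float:
        return min(self.bare_rate, self.ssb_release_rate) if ssb_coated else self.bare_rate


def simulate_filamentation(
    ssb_coated: bool,
    fparams: FilamentationParams = FilamentationParams(),
    noise: NoiseModel | None = None,
    seed: int | None = None,
    sampling_rate: float = 10.0,
) -> Trace:
    """Saturation trace dS/dt = r_eff (1 - S) with S(0) = 0, S(inf) = 1.

    ``noise`` adds the usual white noise and drift (seed override via
    ``seed``); without it the ideal exponential is returned.
    """
    r = fparams.effective_rate(ssb_coated)
    duration = fparams.duration if ssb_coated else min(fparams.duration, 6.0 / r)
    if noise is None:
        t = np.arange(0.0, duration, 1.0 / sampling_rate)
        return Trace(t, 1.0 - np.exp(-r * t), noisy=False,
                     meta={"kind": "saturation", "rate_s_inv": r,
                           "ssb_coated": ssb_coated})
    nm = NoiseModel(noise.sigma, noise.drift_rate, noise.seed if seed is None else seed)
    tr = generate_reca_curve(r, nm, duration=duration, sampling_rate=sampling_rate)
    tr.meta["ssb_coated"] = ssb_coated
    return tr


def simulate_filamentation_coupled(
    params: ParameterSet,
    fparams: FilamentationParams = FilamentationParams(),
    start_omega: float | None = None,
    sampling_rate: float = 10.0,
) -> Trace:
    """Mechanistically coupled mode: RecA claims free substrate while the
    SSB layer evolves under the mean-field model on the shrinking remainder.

    State (S, beta, omega): RecA converts free substrate at the bare filling
    rate, dS/dt = r (1 - S - theta_b - theta_w); SSB sees an effective free
    fraction reduced by S, so growing filaments oversaturate the remaining
    lattice and stimulate unwrapping/dissociation.  With the calibrated sets
    (intrinsic unwrapping pinned to zero) a maximally wrapped layer releases
    substrate only through the stimulated pathway, so filamentation slows
    drastically once the initial free substrate is consumed — the
    qualitative statement that SSB release limits RecA growth.
    """
    p = params
    r = fparams.bare_rate
    if start_omega is None:
        start_omega = 0.98 / p.n_w  # maximally wrapped layer after a rinse

    def rhs3(t, y):
        S, b, w = (max(v, 0.0) for v in y)
        tb, tw = p.n_b * b, p.n_w * w
        t0 = max(1.0 - S - tb - tw, 0.0)
        koff_e = p.k_off + p.k_off_stim * tb
        kunw_e = p.k_unw + p.k_unw_stim * tb
        # wrapping competes with RecA for the same free substrate
        phi = min(1.0, t0 / ((p.n_w - p.n_b) * b)) if b > 0 else 1.0
        wrap = p.k_w * phi * b if p.wrapping_enabled else 0.0
        dS = r * t0
        db = -koff_e * b - wrap + kunw_e * w
        dw = wrap - kunw_e * w
        return [dS, db, dw]

    from scipy.integrate import solve_ivp
    sol = solve_ivp(rhs3, (0.0, fparams.duration), [0.0, 0.0, start_omega],
                    method="LSODA", rtol=1e-9, atol=1e-12, dense_output=True)
    t = np.arange(0.0, fparams.duration, 1.0 / sampling_rate)
    S = np.clip(sol.sol(t)[0], 0.0, 1.0)
    return Trace(t, S, noisy=False,
                 meta={"kind": "saturation", "coupled": True,
                       "params": p.to_dict(), "bare_rate_s_inv": r})


def fit_filamentation_rate(trace: Trace) -> float:
    """Rate of exponential saturation S(t) = A (1 - exp(-r t)); exact on
    noiseless input."""
    t, y = trace.time, trace.compaction
    p, _ = curve_fit(lambda t, A, r: A * (1.0 - np.exp(-r * t)), t, y,
                     p0=[1.0, 1.0 / max(t[-1] / 3, 1e-6)], maxfev=20000)
    return float(p[1])
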