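"""Mean-field two-step competitive binding model of EcSSB on long ssDNA.

The E. coli single-stranded-DNA binding protein (EcSSB) tetramer occupies
ssDNA in two classes of states under tension: a bound-but-unwrapped state in
which a single OB-fold domain contacts ~8 nt, and a wrapped state occluding
17 nt at 12 pN (35 nt at 7 pN).  A protein first binds bimolecularly from
solution and then wraps using additional free substrate; crowding by other
bound-unwrapped proteins *stimulates* both unwrapping and dissociation, so a
lattice loaded at high protein concentration oversaturates and then sheds
protein.  This module holds the kinetic state representation, the stimulated
rate law, the ODE right-hand side, equilibrium and critical-concentration
solvers, and the mapping from occupancies to per-nucleotide compaction.

State variables are protein densities (tetramers per nucleotide):

    beta   bound-unwrapped proteins / nt        theta_b = n_b * beta
    omega  wrapped proteins / nt                theta_w = n_w * omega

with theta_0 = 1 - theta_b - theta_w the free substrate fraction, so
occupancy conservation holds identically.

Binding flux uses two channels.  While the wrapped capacity
u = n_w * (beta + omega) is unsaturated, proteins load onto effectively
independent sites and the fractional filling rate is k_b * c, the value
Table-1-style calibrations quote at 1 nM.  Once u approaches one
(oversaturation: more protein bound than can simultaneously wrap) additional
binding competes per free nucleotide, k_b * c * theta_0, which is the regime
that sets the critical concentration where theta_b = theta_w.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

__all__ = [
    "ParameterSet",
    "StateVector",
    "ForceRegime",
    "FORCE_REGIMES",
    "ConvergenceError",
    "table1_parameters",
    "prose_parameters",
    "load_parameters",
    "save_parameters",
    "apply_force_regime",
    "effective_rates",
    "rhs",
    "integrate",
    "equilibrate",
    "critical_concentration",
    "extension_change",
    "per_nt_compaction",
    "dissociation_Kd",
    "diffusion_length",
]

# -- numerical configuration -------------------------------------------------

#: adaptive integrator tolerances (stiff-capable LSODA)
ODE_RTOL = 1e-9
ODE_ATOL = 1e-12
#: steady state declared when |d theta / dt| falls below this
EQUILIBRIUM_RESIDUAL = 1e-9
#: bracket scanned for the critical concentration (nM)
CRITICAL_BRACKET = (0.01, 1000.0)
#: onset and completion of the oversaturated-binding channel in u = n_w*(beta+omega)
OVERSATURATION_GATE = (0.98, 1.04)
#: free-substrate fractions between which wrapping stalls (residual sub-footprint
#: gaps that sliding cannot consolidate; well below every calibrated equilibrium)
WRAP_STALL_THETA0 = (5e-4, 2e-3)
#: fast unwrapping applied when a force regime destabilises wrapping (s^-1);
#: any value >> k_off gives the same observable kinetics
FORCED_UNWRAP_RATE = 1.0


class ConvergenceError(RuntimeError):
    """Steady-state iteration failed; carries the residual reached."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (residual={residual:.3e})")
        self.residual = residual


def _smoothstep(x: float) -> float:
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    return x * x * (3.0 - 2.0 * x)


# -- domain types ------------------------------------------------------------


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic rates, footprints and compactions for one condition.

    Rates are first-order (s^-1) except ``k_b`` (nM^-1 s^-1).  ``k_off_stim``
    and ``k_unw_stim`` scale the stimulation terms, linear in theta_b.
    Compactions are stored as positive shortening magnitudes (nm per nt of
    state occupancy); published tables list them negative as a display
    convention.
    """

    k_b: float
    k_off: float
    k_w: float
    k_unw: float = 0.0
    k_off_stim: float = 0.0
    k_unw_stim: float = 0.0
    n_b: int = 8
    n_w: int = 17
    x_b: float = 0.0159
    x_w: float = 0.083
    force: float = 12.0
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("k_b", "k_off", "k_w", "k_unw", "k_off_stim", "k_unw_stim"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.k_b <= 0:
            raise ValueError("k_b must be positive for any binding to occur")
        if not (0 < self.n_b < self.n_w):
            raise ValueError("footprints must satisfy 0 < n_b < n_w")
        if not (0 <= self.x_b < self.x_w):
            raise ValueError("compactions must satisfy 0 <= x_b < x_w")

    @property
    def wrapping_enabled(self) -> bool:
        return self.k_w > 0.0

    def without_wrapping(self) -> "ParameterSet":
        """Variant with wrapping (and hence all stimulation) disabled.

        Models the H55Y non-tetramerising mutant and high-tension regimes:
        stimulation requires a neighbour able to wrap into freed substrate,
        so it is inactive whenever wrapping is.
        """
        return replace(
            self, k_w=0.0, k_off_stim=0.0, k_unw_stim=0.0,
            label=(self.label + "+nowrap") if self.label else "nowrap",
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "force_pN": self.force,
            "k_b_per_nM_s": self.k_b,
            "rates_s_inv": {
                "k_off": self.k_off,
                "k_w": self.k_w,
                "k_unw": self.k_unw,
                "k_off_stim": self.k_off_stim,
                "k_unw_stim": self.k_unw_stim,
            },
            "footprints_nt": {"n_b": self.n_b, "n_w": self.n_w},
            "compaction_nm_per_nt": {"x_b": self.x_b, "x_w": self.x_w},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        r = d["rates_s_inv"]
        return cls(
            k_b=d["k_b_per_nM_s"],
            k_off=r["k_off"],
            k_w=r["k_w"],
            k_unw=r.get("k_unw", 0.0),
            k_off_stim=r.get("k_off_stim", 0.0),
            k_unw_stim=r.get("k_unw_stim", 0.0),
            n_b=d["footprints_nt"]["n_b"],
            n_w=d["footprints_nt"]["n_w"],
            x_b=d["compaction_nm_per_nt"]["x_b"],
            x_w=d["compaction_nm_per_nt"]["x_w"],
            force=d.get("force_pN", 12.0),
            label=d.get("label", ""),
        )


@dataclass(frozen=True)
class StateVector:
    """Protein densities on the lattice with derived occupancy fractions."""

    beta: float
    omega: float
    n_b: int = 8
    n_w: int = 17

    def __post_init__(self) -> None:
        if self.beta < 0 or self.omega < 0:
            raise ValueError("densities must be non-negative")

    @property
    def theta_b(self) -> float:
        return self.n_b * self.beta

    @property
    def theta_w(self) -> float:
        return self.n_w * self.omega

    @property
    def theta_0(self) -> float:
        return 1.0 - self.theta_b - self.theta_w

    @classmethod
    def empty(cls, params: ParameterSet) -> "StateVector":
        return cls(0.0, 0.0, params.n_b, params.n_w)

    @classmethod
    def from_densities(cls, beta: float, omega: float, params: ParameterSet) -> "StateVector":
        return cls(beta, omega, params.n_b, params.n_w)


@dataclass(frozen=True)
class ForceRegime:
    """Wrapping geometry at one applied tension."""

    force: float            # pN
    n_w: int                # wrapped footprint at this force (nt)
    dx_per_protein: float   # compaction per wrapped tetramer (nm)
    wrapping_enabled: bool


#: Regimes observed under tension: 35-nt wrapping at 7 pN (5 nm per tetramer),
#: 17-nt wrapping at 12 pN (2 nm geometric; the calibrated per-nt value is taken
#: from the parameter set), and no stable wrapping at >= 15 pN.
FORCE_REGIMES: tuple[ForceRegime, ...] = (
    ForceRegime(force=7.0, n_w=35, dx_per_protein=5.0, wrapping_enabled=True),
    ForceRegime(force=12.0, n_w=17, dx_per_protein=2.0, wrapping_enabled=True),
    ForceRegime(force=20.0, n_w=17, dx_per_protein=0.0, wrapping_enabled=False),
    ForceRegime(force=60.0, n_w=17, dx_per_protein=0.0, wrapping_enabled=False),
)

WRAPPING_DISABLED_ABOVE_PN = 15.0


def force_regime(force: float) -> ForceRegime:
    """Look up the wrapping regime for an applied tension.

    Any force at or above 15 pN maps to a wrapping-disabled regime; below
    that only the tabulated forces (7 and 12 pN) are calibrated.
    """
    if force >= WRAPPING_DISABLED_ABOVE_PN:
        return ForceRegime(force=force, n_w=17, dx_per_protein=0.0, wrapping_enabled=False)
    for reg in FORCE_REGIMES:
        if math.isclose(reg.force, force):
            return reg
    raise KeyError(
        f"no force regime calibrated at {force} pN; known: 7, 12, >=15 pN"
    )


def apply_force_regime(params: ParameterSet, force: float) -> ParameterSet:
    """Return the parameter set as modified by the regime at ``force``.

    At 12 pN the set is returned with the force stamped (its own x_w is the
    calibrated value).  At 7 pN the wrapped footprint widens to 35 nt with
    x_w = 5 nm / 35 nt.  In destabilised regimes wrapping and stimulation are
    switched off and unwrapping becomes fast, so pre-existing wrapped protein
    converts to the bound state within ~1 s of a force jump.
    """
    reg = force_regime(force)
    if not reg.wrapping_enabled:
        p = params.without_wrapping()
        return replace(p, k_unw=max(p.k_unw, FORCED_UNWRAP_RATE), force=force)
    if reg.n_w == params.n_w:
        return replace(params, force=force)
    return replace(
        params,
        n_w=reg.n_w,
        x_w=reg.dx_per_protein / reg.n_w,
        force=force,
    )


# -- shipped parameter fixtures ----------------------------------------------


def load_parameters(source) -> ParameterSet:
    """Load a parameter set from a JSON file path or file-like object."""
    if hasattr(source, "read"):
        return ParameterSet.from_dict(json.load(source))
    with open(source) as fh:
        return ParameterSet.from_dict(json.load(fh))


def save_parameters(params: ParameterSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2)
        fh.write("\n")


def _load_fixture(name: str) -> ParameterSet:
    with resources.files("ssbkin.fixtures").joinpath(name).open() as fh:
        return load_parameters(fh)


def table1_parameters() -> ParameterSet:
    """Calibrated 12 pN set (k_b 0.150, k_off 0.0171, k_w 1.40, stimulation
    scales 0.113 / 0.095; intrinsic unwrapping bounded below 0.01 and pinned
    to zero)."""
    return _load_fixture("table1_12pN.json")


def prose_parameters() -> ParameterSet:
    """12 pN set from the kinetic-phase analysis: k_b 0.18 nM^-1 s^-1,
    k_w 1.8 s^-1, saturated unwrapping 0.10 s^-1, saturated dissociation
    0.1 s^-1, slow dissociation 0.017 s^-1."""
    return _load_fixture("prose_12pN.json")


# -- rate laws and right-hand side -------------------------------------------


def effective_rates(params: ParameterSet, theta_b: float) -> tuple[float, float]:
    """Stimulated dissociation and unwrapping rates at bound-unwrapped
    occupancy ``theta_b``.

    Both are linear in theta_b: k_eff = k_intrinsic + k_stim * theta_b,
    the minimal law consistent with rates proportional to the fraction of
    substrate held by bound-unwrapped protein.
    """
    if not (0.0 <= theta_b <= 1.0):
        raise ValueError(f"theta_b must lie in [0, 1], got {theta_b}")
    k_off_eff = params.k_off + params.k_off_stim * theta_b
    k_unw_eff = params.k_unw + params.k_unw_stim * theta_b
    return k_off_eff, k_unw_eff


def _rhs_arrays(beta: float, omega: float, c: float, p: ParameterSet) -> tuple[float, float]:
    """Raw derivative evaluation on clipped densities (internal)."""
    b = beta if beta > 0.0 else 0.0
    w = omega if omega > 0.0 else 0.0
    theta_b = p.n_b * b
    theta_w = p.n_w * w
    theta_0 = 1.0 - theta_b - theta_w
    if theta_0 < 0.0:
        theta_0 = 0.0

    k_off_eff = p.k_off + p.k_off_stim * theta_b
    k_unw_eff = p.k_unw + p.k_unw_stim * theta_b

    # two-channel binding flux (proteins / nt / s)
    u = p.n_w * (b + w) if p.wrapping_enabled else p.n_b * b
    cap = p.n_w if p.wrapping_enabled else p.n_b
    lo, hi = OVERSATURATION_GATE
    sigma = _smoothstep((u - lo) / (hi - lo))
    J = p.k_b * c * (max(1.0 - u, 0.0) / cap + theta_0 * sigma)

    if p.wrapping_enabled:
        # free substrate rationed among wrap candidates (n_w - n_b extra nt
        # each), with a stall once only sub-footprint gaps remain
        if b > 0.0:
            phi = min(1.0, theta_0 / ((p.n_w - p.n_b) * b))
        else:
            phi = 1.0
        s_lo, s_hi = WRAP_STALL_THETA0
        phi *= _smoothstep((theta_0 - s_lo) / (s_hi - s_lo))
        wrap_flux = p.k_w * phi * b
    else:
        wrap_flux = 0.0

    dbeta = J - k_off_eff * b - wrap_flux + k_unw_eff * w
    domega = wrap_flux - k_unw_eff * w
    return dbeta, domega


def rhs(state: StateVector, c: float, params: ParameterSet) -> tuple[float, float]:
    """Time derivatives (d beta/dt, d omega/dt) at free concentration ``c`` (nM)."""
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if state.beta < 0 or state.omega < 0:
        raise ValueError("densities must be non-negative")
    return _rhs_arrays(state.beta, state.omega, c, params)


def integrate(
    params: ParameterSet,
    c: float | Callable[[float], float],
    t_span: tuple[float, float],
    y0: Sequence[float] = (0.0, 0.0),
    t_eval: np.ndarray | None = None,
):
    """Integrate the model; ``c`` may be a constant or a function of time.

    Returns the scipy solution object with dense output enabled.
    """
    if callable(c):
        fun = lambda t, y: _rhs_arrays(y[0], y[1], c(t), params)
        max_step = 0.25
    else:
        fun = lambda t, y: _rhs_arrays(y[0], y[1], c, params)
        max_step = np.inf
    sol = solve_ivp(
        fun, t_span, list(y0), method="LSODA",
        rtol=ODE_RTOL, atol=ODE_ATOL, dense_output=True, max_step=max_step,
    )
    if not sol.success:  # pragma: no cover - LSODA failure is pathological here
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol


# -- equilibrium solvers -----------------------------------------------------


def equilibrate(
    c: float,
    params: ParameterSet,
    start: StateVector | str = "empty",
    t_max: float = 20000.0,
) -> StateVector:
    """Steady state of the model at free concentration ``c``.

    ``start`` selects the initial condition: "empty" (bare ssDNA, the
    loading experiment), "packed" (near wrap-saturated), or an explicit
    :class:`StateVector`.  Above the escape concentration
    c* = (k_off + k_w) / (9 k_b) (~1 nM for the calibrated sets) the steady
    state is unique and start-independent; below it an empty start arrests
    in the fully wrapped state, which is what constant-force experiments
    observe at low concentration.
    """
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if isinstance(start, StateVector):
        y0 = (start.beta, start.omega)
    elif start == "empty":
        y0 = (0.0, 0.0)
    elif start == "packed":
        y0 = (0.9 / params.n_b * 0.9, 0.05 / params.n_w)
    else:
        raise ValueError(f"unknown start {start!r}")

    sol = integrate(params, c, (0.0, t_max), y0)
    y = np.maximum(sol.y[:, -1], 0.0)

    refined = root(
        lambda v: _rhs_arrays(v[0], v[1], c, params), y, method="hybr", tol=1e-13
    )
    if refined.success and np.all(refined.x > -1e-12):
        y = np.maximum(refined.x, 0.0)

    res = max(abs(d) for d in _rhs_arrays(y[0], y[1], c, params))
    if res > EQUILIBRIUM_RESIDUAL:
        raise ConvergenceError("steady state not reached", res)
    return StateVector.from_densities(float(y[0]), float(y[1]), params)


def critical_concentration(
    params: ParameterSet,
    bracket: tuple[float, float] = CRITICAL_BRACKET,
    xtol: float = 1e-3,
) -> float:
    """Concentration (nM) at which theta_b = theta_w at equilibrium.

    Found by bracketing the sign change of theta_b - theta_w on a log-spaced
    grid and bisecting.  Requires wrapping; below the root the wrapped state
    dominates, above it the bound-unwrapped state does.
    """
    if not params.wrapping_enabled:
        raise ValueError("critical concentration undefined without wrapping")

    def gap(c: float) -> float:
        s = equilibrate(c, params)
        return s.theta_b - s.theta_w

    grid = np.geomspace(bracket[0], bracket[1], 25)
    vals = [gap(grid[0])]
    for lo, hi in zip(grid[:-1], grid[1:]):
        vals.append(gap(hi))
        if vals[-2] < 0.0 <= vals[-1] or vals[-2] > 0.0 >= vals[-1]:
            return float(brentq(gap, lo, hi, xtol=xtol))
    raise ValueError(
        f"no theta_b - theta_w sign change in {bracket} nM; "
        "wrapped and bound states never exchange dominance"
    )


# -- observables -------------------------------------------------------------


def extension_change(state: StateVector, params: ParameterSet) -> float:
    """Net compaction in nm per nt (positive = shortening):
    Delta X = x_b * theta_b + x_w * theta_w."""
    return params.x_b * state.theta_b + params.x_w * state.theta_w


def per_nt_compaction(dx_per_protein: float, footprint: float) -> float:
    """Per-nucleotide compaction of a state from its per-protein compaction,
    e.g. 2 nm / 17 nt ~ 0.1 nm/nt."""
    if footprint <= 0:
        raise ValueError("footprint must be positive")
    return dx_per_protein / footprint


def dissociation_Kd(k_off: float, k_on: float) -> float:
    """Equilibrium dissociation constant k_off / k_on in nM."""
    if k_on <= 0:
        raise ValueError("k_on must be positive")
    return k_off / k_on


def diffusion_length(D: float, t: float) -> float:
    """One-dimensional diffusion length sqrt(D t) in nt; with the measured
    D = 300 nt^2/s over the ~10 s stimulated-dissociation timescale this is
    ~55 nt, the neighbourhood within which proteins interact."""
    if D < 0 or t < 0:
        raise ValueError("D and t must be non-negative")
    return math.sqrt(D * t)
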