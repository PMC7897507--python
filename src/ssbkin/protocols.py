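"""Piecewise constant-force experiment protocols and their ideal traces.

A protocol is an ordered list of segments, each holding the ssDNA at one
free-protein concentration and tension for a fixed duration: incubation,
rinse (c = 0), re-incubation, force jumps.  Solution exchange is treated as
instantaneous by default (the flow cell exchanges in ~1 s, well below the
phase timescales); an optional linear mixing ramp is available for
sensitivity checks.  Simulation produces compaction (nm per nt, positive =
shortening) on a uniform sampling grid, carrying the bound/wrapped protein
densities across segment boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .model_core import (
    ParameterSet,
    StateVector,
    apply_force_regime,
    extension_change,
    force_regime,
    integrate,
)

__all__ = [
    "Segment",
    "Protocol",
    "Trace",
    "simulate_protocol",
    "incubate_rinse_protocol",
    "force_jump_survival",
    "monomer_equivalent_concentration",
]


@dataclass(frozen=True)
class Segment:
    duration: float       # s
    concentration: float  # nM free protein
    force: float = 12.0   # pN

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")


@dataclass(frozen=True)
class Protocol:
    segments: tuple[Segment, ...]
    sampling_rate: float = 10.0  # Hz
    label: str = ""

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "segments", tuple(
            s if isinstance(s, Segment) else Segment(*s) for s in self.segments
        ))

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    def segment_windows(self) -> list[tuple[float, float]]:
        """Start/end times of each segment on the trace clock."""
        out, t = [], 0.0
        for s in self.segments:
            out.append((t, t + s.duration))
            t += s.duration
        return out

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "sampling_rate_hz": self.sampling_rate,
            "segments": [
                {"duration_s": s.duration, "concentration_nM": s.concentration,
                 "force_pN": s.force}
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        return cls(
            segments=tuple(
                Segment(s["duration_s"], s["concentration_nM"], s.get("force_pN", 12.0))
                for s in d["segments"]
            ),
            sampling_rate=d.get("sampling_rate_hz", 10.0),
            label=d.get("label", ""),
        )


@dataclass(frozen=True)
class Trace:
    """Compaction time series on a uniform grid, with provenance metadata."""

    time: np.ndarray        # s
    compaction: np.ndarray  # nm per nt
    protocol: Protocol | None = None
    noisy: bool = False
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, float)
        y = np.asarray(self.compaction, float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("time and compaction must be 1-D arrays of equal length")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "compaction", y)

    @property
    def sampling_rate(self) -> float:
        if self.protocol is not None:
            return self.protocol.sampling_rate
        return 1.0 / float(np.median(np.diff(self.time)))

    def __len__(self) -> int:
        return len(self.time)


def incubate_rinse_protocol(
    concentration: float,
    force: float = 12.0,
    t_incubate: float = 300.0,
    t_rinse: float = 200.0,
    t_reincubate: float | None = None,
    sampling_rate: float = 10.0,
) -> Protocol:
    """Standard incubate -> rinse (-> re-incubate) protocol."""
    segs = [Segment(t_incubate, concentration, force), Segment(t_rinse, 0.0, force)]
    if t_reincubate:
        segs.append(Segment(t_reincubate, concentration, force))
    return Protocol(tuple(segs), sampling_rate,
                    label=f"incubate{concentration:g}nM_{force:g}pN")


def _carry_state(beta: float, omega: float, old: ParameterSet, new: ParameterSet) -> tuple[float, float]:
    """Re-label densities across a force change.

    Between wrapping-enabled regimes with different footprints the wrapped
    density is preserved (no interconversion kinetics are calibrated) and
    capped so occupancies stay within the lattice.
    """
    if old.n_w != new.n_w and omega > 0.0:
        cap = max(0.0, (1.0 - new.n_b * beta)) / new.n_w
        omega = min(omega, cap)
    return beta, omega


def simulate_protocol(
    protocol: Protocol,
    params: ParameterSet,
    start: StateVector | None = None,
    exchange_ramp: float = 0.0,
) -> Trace:
    """Integrate the model through every segment and sample compaction.

    ``exchange_ramp`` > 0 replaces the instantaneous solution exchange with a
    linear concentration ramp of that duration (s) at the start of each
    segment whose concentration differs from the previous one.

    Only concentration and the force-regime entries change at segment
    boundaries; protein densities carry over (wrapped protein is re-labelled
    when the wrapped footprint changes, and unwraps within ~1 s after a jump
    into a destabilised regime via the fast unwrapping rate).
    """
    dt = 1.0 / protocol.sampling_rate
    times, comps = [], []
    beta, omega = (0.0, 0.0) if start is None else (start.beta, start.omega)
    t_offset = 0.0
    prev_c = 0.0
    prev_params: ParameterSet | None = None

    for seg in protocol.segments:
        p = apply_force_regime(params, seg.force)
        if prev_params is not None:
            beta, omega = _carry_state(beta, omega, prev_params, p)
        tloc = np.arange(0.0, seg.duration - dt / 2, dt)
        if exchange_ramp > 0 and not math.isclose(seg.concentration, prev_c):
            c0, c1, ramp = prev_c, seg.concentration, exchange_ramp
            cfun = lambda t: c0 + (c1 - c0) * min(t / ramp, 1.0)
            sol = integrate(p, cfun, (0.0, seg.duration), (beta, omega))
        else:
            sol = integrate(p, seg.concentration, (0.0, seg.duration), (beta, omega))
        y = np.maximum(sol.sol(tloc), 0.0)
        comps.append(p.x_b * p.n_b * y[0] + p.x_w * p.n_w * y[1])
        times.append(tloc + t_offset)
        beta, omega = np.maximum(sol.y[:, -1], 0.0)
        t_offset += seg.duration
        prev_c = seg.concentration
        prev_params = p

    return Trace(
        time=np.concatenate(times),
        compaction=np.concatenate(comps),
        protocol=protocol,
        noisy=False,
        meta={"params": params.to_dict(), "exchange_ramp_s": exchange_ramp,
              "final_state": {"beta": float(beta), "omega": float(omega)}},
    )


def force_jump_survival(params: ParameterSet, hold_force: float, hold_time: float) -> float:
    """Fraction of bound protein surviving a hold at a wrapping-disabled force.

    During the hold every protein is (or rapidly becomes) bound-unwrapped and
    dissociates at the slow intrinsic rate, so survival is exp(-k_off * t);
    on return to low force the survivors re-wrap.
    """
    if hold_time < 0:
        raise ValueError("hold time must be non-negative")
    if force_regime(hold_force).wrapping_enabled:
        raise ValueError(
            f"{hold_force} pN keeps wrapping stable; force-jump survival "
            "applies only to wrapping-disabled regimes"
        )
    return math.exp(-params.k_off * hold_time)


def monomer_equivalent_concentration(c_monomer: float) -> float:
    """Tetramer concentration binding at the same initial rate as a given
    monomer concentration (one OB fold binds first): c / 4."""
    if c_monomer < 0:
        raise ValueError("concentration must be non-negative")
    return c_monomer / 4.0
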