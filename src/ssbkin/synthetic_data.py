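"""Seedable synthetic datasets with the statistical structure the fitting
stage assumes: noisy constant-force traces, concentration series with
replicates, and RecA-style saturation curves.

The noise model is additive white noise plus a slow linear drift, the two
dominant artefacts of force-clamp extension records after instrument
corrections.  Published records do not state magnitudes, so the defaults
(sigma 0.005 nm/nt at 10 Hz, drift 0.002 nm/nt per 100 s) are chosen to keep
the shortest phases fittable while remaining clearly visible on single
traces.

Per-trace seeds derive from a master seed and a stable counter
(concentration index, replicate index), so enlarging a dataset never
perturbs existing traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model_core import ParameterSet
from .protocols import Protocol, Trace, incubate_rinse_protocol, simulate_protocol

__all__ = [
    "NoiseModel",
    "ConcentrationSeries",
    "DEFAULT_CONCENTRATIONS",
    "add_noise",
    "generate_concentration_series",
    "generate_reca_curve",
    "derive_seed",
]

#: concentration grid spanning the bind-wrap knee (nM)
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0)


@dataclass(frozen=True)
class NoiseModel:
    sigma: float = 0.005        # additive white noise std (nm/nt)
    drift_rate: float = 0.002   # slow drift (nm/nt per 100 s)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def derive_seed(master: int, *counters: int) -> int:
    """Stable per-artifact seed below 2**31 from a master seed and counters."""
    ss = np.random.SeedSequence([int(master), *map(int, counters)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def add_noise(trace: Trace, noise: NoiseModel) -> Trace:
    """White noise + linear drift on an ideal trace; seed-deterministic."""
    if trace.noisy:
        raise ValueError("trace already carries noise")
    rng = np.random.default_rng(noise.seed)
    y = trace.compaction + rng.normal(0.0, noise.sigma, len(trace)) \
        + noise.drift_rate * trace.time / 100.0
    meta = dict(trace.meta)
    meta["noise"] = {"sigma": noise.sigma, "drift_rate_per_100s": noise.drift_rate,
                     "seed": noise.seed}
    return Trace(trace.time, y, protocol=trace.protocol, noisy=True,
                 seed=noise.seed, meta=meta)


@dataclass(frozen=True)
class ConcentrationSeries:
    """Replicated incubate/rinse/re-incubate traces across concentrations."""

    concentrations: tuple[float, ...]
    n_rep: int
    traces: dict           # (concentration, replicate) -> Trace
    protocols: dict        # concentration -> Protocol
    params: ParameterSet
    noise: NoiseModel

    def __post_init__(self) -> None:
        if self.n_rep < 3:
            raise ValueError("need at least 3 replicates per concentration")

    def replicates(self, c: float) -> list[Trace]:
        return [self.traces[(c, r)] for r in range(self.n_rep)]


def generate_concentration_series(
    params: ParameterSet,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    noise: NoiseModel = NoiseModel(),
    n_rep: int = 3,
    t_incubate: float = 300.0,
    t_rinse: float = 200.0,
    t_reincubate: float = 150.0,
    force: float = 12.0,
) -> ConcentrationSeries:
    """Simulate the incubate -> rinse -> re-incubate experiment for every
    concentration and add independent noise per replicate.

    The ideal trace is computed once per concentration; replicates differ by
    their derived noise seeds only, mirroring repeated pulls on the same
    construct.
    """
    traces: dict = {}
    protocols: dict = {}
    for ci, c in enumerate(concentrations):
        proto = incubate_rinse_protocol(
            c, force=force, t_incubate=t_incubate, t_rinse=t_rinse,
            t_reincubate=t_reincubate,
        )
        ideal = simulate_protocol(proto, params)
        protocols[c] = proto
        for rep in range(n_rep):
            nm = NoiseModel(noise.sigma, noise.drift_rate,
                            derive_seed(noise.seed, ci, rep))
            traces[(c, rep)] = add_noise(ideal, nm)
    return ConcentrationSeries(
        concentrations=tuple(concentrations), n_rep=n_rep, traces=traces,
        protocols=protocols, params=params, noise=noise,
    )


def generate_reca_curve(
    rate: float,
    noise: NoiseModel = NoiseModel(),
    duration: float | None = None,
    sampling_rate: float = 10.0,
) -> Trace:
    """Noisy saturation curve S(t) = 1 - exp(-rate t), the shape of RecA
    filamentation registered as normalised extension."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if duration is None:
        duration = 5.0 / rate
    t = np.arange(0.0, duration, 1.0 / sampling_rate)
    ideal = 1.0 - np.exp(-rate * t)
    rng = np.random.default_rng(noise.seed)
    y = ideal + rng.normal(0.0, noise.sigma, len(t)) + noise.drift_rate * t / 100.0
    return Trace(t, y, protocol=None, noisy=noise.sigma > 0 or noise.drift_rate != 0,
                 seed=noise.seed,
                 meta={"kind": "saturation", "rate_s_inv": rate,
                       "noise": {"sigma": noise.sigma,
                                 "drift_rate_per_100s": noise.drift_rate,
                                 "seed": noise.seed}})
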