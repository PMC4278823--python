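"""Exact stochastic simulation of temperature-stratified microcosm experiments.

A :class:`Dataset` emulates a laboratory design in which single-species
populations are grown at several fixed temperatures, starting from low
abundance, and counted at discrete times by sampling a fraction
``frac_samp`` of the habitat.  The simulator draws one continuous
birth--death sample path per (temperature, replicate) with the Gillespie
algorithm and overlays Poisson sampling error: the count at time t is
Poisson with mean ``frac_samp * n(t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .core import (
    ArrheniusModel,
    BDPParams,
    celsius_to_kelvin,
    scale_model,
)

__all__ = [
    "TEMPSAMP_PRESETS",
    "TIMESAMP_PRESETS",
    "FRACSAMP_LEVELS",
    "ExperimentalDesign",
    "Trajectory",
    "ObservedSeries",
    "Dataset",
    "gillespie",
    "observe",
    "simulate_design",
]

#: temperature grids (degC) by number of temperatures: 18--28 degC range
TEMPSAMP_PRESETS: dict[int, tuple[float, ...]] = {
    3: (18.0, 23.0, 28.0),
    6: (18.0, 20.0, 22.0, 24.0, 26.0, 28.0),
    11: tuple(float(t) for t in range(18, 29)),
}

#: sampling-day grids by number of sampling occasions over a 15-day horizon:
#: once every three days, twice every three days, or daily
TIMESAMP_PRESETS: dict[int, tuple[float, ...]] = {
    5: (3.0, 6.0, 9.0, 12.0, 15.0),
    10: tuple(1.5 * k for k in range(1, 11)),
    15: tuple(float(d) for d in range(1, 16)),
}

#: habitat fractions counted per observation
FRACSAMP_LEVELS: tuple[float, ...] = (0.001, 0.005, 0.01)


@dataclass(frozen=True)
class ExperimentalDesign:
    """One cell of the factorial design space.

    Temperatures are stored in Kelvin; use :meth:`from_levels` to build a
    design from the preset factor levels (TEMPSAMP, REPS, TIMESAMP, FRACSAMP).
    """

    temperatures: tuple[float, ...]
    reps: int
    sample_times: tuple[float, ...]
    frac_samp: float
    n0: int = 100
    horizon: float = 15.0

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures)
        if t.size == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be non-empty and strictly increasing")
        if np.any(t <= 0):
            raise ValueError("temperatures must be positive Kelvin")
        s = np.asarray(self.sample_times)
        if s.size == 0 or np.any(np.diff(s) <= 0):
            raise ValueError("sample_times must be non-empty and strictly increasing")
        if s[0] < 0 or s[-1] > self.horizon:
            raise ValueError("sample_times must lie within [0, horizon]")
        if not (0.0 < self.frac_samp <= 1.0):
            raise ValueError(f"frac_samp must be in (0, 1], got {self.frac_samp}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.n0 < 0:
            raise ValueError("n0 must be >= 0")

    @classmethod
    def from_levels(
        cls,
        tempsamp: int,
        reps: int,
        timesamp: int,
        fracsamp: float,
        n0: int = 100,
        horizon: float = 15.0,
    ) -> "ExperimentalDesign":
        if tempsamp not in TEMPSAMP_PRESETS:
            raise ValueError(f"tempsamp must be one of {sorted(TEMPSAMP_PRESETS)}")
        if timesamp not in TIMESAMP_PRESETS:
            raise ValueError(f"timesamp must be one of {sorted(TIMESAMP_PRESETS)}")
        return cls(
            temperatures=tuple(celsius_to_kelvin(t) for t in TEMPSAMP_PRESETS[tempsamp]),
            reps=reps,
            sample_times=TIMESAMP_PRESETS[timesamp],
            frac_samp=fracsamp,
            n0=n0,
            horizon=horizon,
        )

    @property
    def levels(self) -> dict:
        """Factor levels (TEMPSAMP, REPS, TIMESAMP, FRACSAMP) of this design."""
        return {
            "TEMPSAMP": len(self.temperatures),
            "REPS": self.reps,
            "TIMESAMP": len(self.sample_times),
            "FRACSAMP": self.frac_samp,
        }


@dataclass(frozen=True)
class Trajectory:
    """One exact sample path: event times (days) and population size after each event."""

    event_times: np.ndarray
    sizes: np.ndarray

    def state_at(self, t) -> np.ndarray:
        """Population size at time(s) t: state after the last event <= t."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        if np.any(idx < 0):
            raise ValueError("lookup before the initial time of the trajectory")
        return self.sizes[idx]


@dataclass(frozen=True)
class ObservedSeries:
    """Sampled counts for one replicate at one temperature."""

    temperature: float  # Kelvin
    replicate: int
    times: np.ndarray
    counts: np.ndarray
    frac_samp: np.ndarray  # per-observation fraction in (0, 1]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        counts = np.asarray(self.counts)
        fracs = np.asarray(self.frac_samp, dtype=float)
        if not (len(times) == len(counts) == len(fracs)):
            raise ValueError("times, counts and frac_samp must have equal length")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if np.any((fracs <= 0) | (fracs > 1)):
            raise ValueError("frac_samp values must be in (0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "frac_samp", fracs)

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Dataset:
    """A collection of observed series plus simulation metadata (if simulated)."""

    series: list[ObservedSeries]
    design: ExperimentalDesign | None = None
    truth: ArrheniusModel | None = None
    seed: int | None = None
    n0: int | None = None
    N: int = 15000
    format_version: str = field(default="1", repr=False)

    def __post_init__(self) -> None:
        if not self.series:
            raise ValueError("Dataset needs at least one series")
        keys = [(s.temperature, s.replicate) for s in self.series]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (temperature, replicate) keys in Dataset")
        if self.n0 is None and self.design is not None:
            self.n0 = self.design.n0

    @property
    def temperatures(self) -> np.ndarray:
        """Sorted unique temperatures (Kelvin) present in the data."""
        return np.unique([s.temperature for s in self.series])

    def at_temperature(self, T: float, atol: float = 1e-9) -> list[ObservedSeries]:
        return [s for s in self.series if abs(s.temperature - T) <= atol]


def gillespie(
    params: BDPParams, n0: int, horizon: float, seed: int
) -> Trajectory:
    """Statistically exact Gillespie simulation of the birth--death process."""
    if n0 < 0:
        raise ValueError("n0 must be >= 0")
    n_max = int(np.floor(params.N / params.theta2))
    if n0 > n_max:
        raise ValueError(
            f"n0={n0} exceeds the zero-birth abundance floor(N/theta2)={n_max}"
        )
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    times, sizes = _kernels.gillespie_kernel(
        params.theta1, params.theta2, params.theta3, float(params.N),
        int(n0), float(horizon), np.uint32(seed),
    )
    return Trajectory(event_times=times, sizes=sizes)


def observe(
    traj: Trajectory,
    times,
    frac_samp,
    rng: np.random.Generator,
    temperature: float = np.nan,
    replicate: int = 0,
) -> ObservedSeries:
    """Poisson-sample a trajectory at given times.

    Counts are independent Poisson draws with mean ``frac_samp * n(t)`` where
    n(t) is the right-continuous trajectory state.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    fracs = np.broadcast_to(np.asarray(frac_samp, dtype=float), times.shape).copy()
    n_t = traj.state_at(times)
    counts = rng.poisson(fracs * n_t)
    return ObservedSeries(
        temperature=temperature,
        replicate=replicate,
        times=times,
        counts=counts.astype(np.int64),
        frac_samp=fracs,
    )


def simulate_design(
    model: ArrheniusModel, design: ExperimentalDesign, seed: int
) -> Dataset:
    """Simulate one full experiment: an independent trajectory per (T, replicate).

    Per-series random streams are spawned deterministically from the master
    seed, so equal seeds give bit-identical datasets and the series are
    mutually independent.
    """
    children = np.random.SeedSequence(seed).spawn(
        len(design.temperatures) * design.reps
    )
    series: list[ObservedSeries] = []
    i = 0
    for T in design.temperatures:
        params = scale_model(model, T).require_growing()
        for rep in range(design.reps):
            child = children[i]
            i += 1
            gseed = int(child.generate_state(1, dtype=np.uint32)[0])
            traj = gillespie(params, design.n0, design.horizon, gseed)
            rng = np.random.default_rng(child)
            series.append(
                observe(
                    traj,
                    design.sample_times,
                    design.frac_samp,
                    rng,
                    temperature=T,
                    replicate=rep,
                )
            )
    return Dataset(
        series=series, design=design, truth=model, seed=seed, n0=design.n0, N=model.N
    )
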