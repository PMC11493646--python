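"""Integration of the master equation dP/dt = R(V) P under voltage clamp.

Voltage-clamp protocols are piecewise constant in V, so within each
segment the master equation is a linear constant-coefficient ODE and the
matrix exponential propagates the state exactly (up to floating point).
That is the default backend; an adaptive stiff integrator is available as
an alternative. State spaces here are at most 20-dimensional, so the
exponential is cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm, null_space
from scipy.integrate import solve_ivp

from .composition import ChannelComposition
from .markov import StateSpace, build_generator, enumerate_states
from .rates import SubunitRates

#: probability-vector entries in [-NEG_TOL, 0) are clamped to 0 (float dust)
NEG_TOL = 1e-12
#: tolerated deviation of sum(P) from 1 at every output time
SUM_TOL = 1e-9


class SimulationError(RuntimeError):
    """Raised when a propagated state violates probability conservation."""


@dataclass(frozen=True)
class VoltageSegment:
    """One constant-voltage epoch of a clamp protocol."""

    V: float        # mV
    duration: float  # ms

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"segment duration must be > 0 ms, got {self.duration}")


@dataclass
class Trajectory:
    """Time-resolved model state under a protocol.

    ``states`` rows are full probability vectors (full model) or reduced
    coordinates (reduced models); ``open_probability`` is the conducting
    state's probability at each output time.
    """

    times: np.ndarray                 # ms, increasing
    states: np.ndarray                # (T, d)
    open_probability: np.ndarray      # (T,)
    state_names: list[str] = field(default_factory=list)
    segment_index: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        data = {"time_ms": self.times}
        names = self.state_names or [f"x{i}" for i in range(self.states.shape[1])]
        for i, name in enumerate(names):
            data[name] = self.states[:, i]
        data["open_probability"] = self.open_probability
        return pd.DataFrame(data)


class FullMarkovModel:
    """The full master-equation model of one channel composition.

    Parameters
    ----------
    composition, rates
        The tetramer make-up and the per-subunit-type rate laws.
    backend
        ``"expm"`` (default; exact per constant-voltage segment) or
        ``"ivp"`` (adaptive stiff integration, rtol 1e-8 / atol 1e-10).
    """

    def __init__(
        self,
        composition: ChannelComposition,
        rates: SubunitRates,
        backend: str = "expm",
        rtol: float = 1e-8,
        atol: float = 1e-10,
    ) -> None:
        if backend not in ("expm", "ivp"):
            raise ValueError(f"unknown backend {backend!r}")
        self.composition = composition
        self.rates = rates
        self.backend = backend
        self.rtol = rtol
        self.atol = atol
        self.space: StateSpace = enumerate_states(composition)
        self._gen_cache: dict[float, np.ndarray] = {}

    @property
    def n_states(self) -> int:
        return len(self.space)

    @property
    def state_names(self) -> list[str]:
        return self.space.label_names()

    def generator(self, V: float) -> np.ndarray:
        R = self._gen_cache.get(V)
        if R is None:
            R = build_generator(self.composition, self.rates, V, self.space)
            self._gen_cache[V] = R
        return R

    def stationary(self, V: float) -> np.ndarray:
        """Stationary distribution of R(V) (null-space vector, sum 1)."""
        R = self.generator(V)
        ns = null_space(R)
        if ns.shape[1] != 1:
            warnings.warn(
                "generator null space is not one-dimensional (zero rates?); "
                "falling back to long-run integration",
                RuntimeWarning,
            )
            P = np.full(self.n_states, 1.0 / self.n_states)
            return self.propagate(P, V, np.array([1e7]))[-1]
        P = ns[:, 0]
        P = P * np.sign(P.sum())
        P[(P < 0) & (P > -1e-9)] = 0.0
        if (P < 0).any():
            raise SimulationError("stationary distribution has negative entries")
        return P / P.sum()

    def propagate(self, P0: np.ndarray, V: float, times: np.ndarray) -> np.ndarray:
        """States at the given time offsets (ms) from P0 under constant V."""
        times = np.asarray(times, dtype=float)
        R = self.generator(V)
        if self.backend == "ivp":
            t_end = times[-1] if len(times) else 0.0
            sol = solve_ivp(
                lambda t, y: R @ y, (0.0, t_end), np.asarray(P0, float),
                t_eval=times, method="BDF", jac=lambda t, y: R,
                rtol=self.rtol, atol=self.atol,
            )
            if not sol.success:
                raise SimulationError(f"adaptive integration failed: {sol.message}")
            return sol.y.T
        out = np.empty((len(times), self.n_states))
        P = np.asarray(P0, dtype=float)
        prev_t = 0.0
        cache: dict[float, np.ndarray] = {}
        for idx, t in enumerate(times):
            dt = t - prev_t
            if dt > 0:
                T = cache.get(dt)
                if T is None:
                    T = expm(R * dt)
                    cache[dt] = T
                P = T @ P
            out[idx] = P
            prev_t = t
        return out

    def open_probability(self, states: np.ndarray, V: float | None = None) -> np.ndarray:
        return np.asarray(states)[..., self.space.conducting_index]


def _segment_grid(duration: float, output_dt: float) -> np.ndarray:
    n = int(np.floor(duration / output_dt + 1e-9))
    grid = np.arange(1, n + 1) * output_dt
    if not grid.size or grid[-1] < duration - 1e-9 * max(duration, 1.0):
        grid = np.append(grid, duration)
    else:
        grid[-1] = duration
    return grid


def simulate(
    model,
    segments: list[VoltageSegment],
    P0: np.ndarray | None = None,
    output_dt: float = 1.0,
    check: bool = True,
) -> Trajectory:
    """Chain constant-voltage segments, sampling every ``output_dt`` ms.

    ``model`` is any kinetic model exposing ``stationary(V)``,
    ``propagate(state, V, times)`` and ``open_probability(states, V)`` —
    the full Markov model or one of the reduced models. ``P0`` defaults to
    the stationary state at the first segment's voltage.
    """
    if P0 is None:
        if not segments:
            raise ValueError("P0 required for an empty protocol")
        P0 = model.stationary(segments[0].V)
    P0 = np.asarray(P0, dtype=float)
    times = [np.array([0.0])]
    states = [P0[None, :]]
    openp = [np.atleast_1d(model.open_probability(P0[None, :],
                                                  segments[0].V if segments else None))]
    seg_idx = [np.array([0])]
    t0 = 0.0
    P = P0
    check_probs = check and not getattr(model, "reduced", False)
    for k, seg in enumerate(segments):
        grid = _segment_grid(seg.duration, output_dt)
        S = model.propagate(P, seg.V, grid)
        if check_probs:
            _check_probabilities(S, k)
        times.append(t0 + grid)
        states.append(S)
        openp.append(np.atleast_1d(model.open_probability(S, seg.V)))
        seg_idx.append(np.full(len(grid), k))
        P = S[-1]
        t0 += seg.duration
    return Trajectory(
        times=np.concatenate(times),
        states=np.vstack(states),
        open_probability=np.concatenate(openp),
        state_names=list(getattr(model, "state_names", [])),
        segment_index=np.concatenate(seg_idx),
    )


def _check_probabilities(S: np.ndarray, segment: int) -> None:
    if S.min() < -NEG_TOL:
        raise SimulationError(
            f"segment {segment}: negative probability {S.min():.3e}"
        )
    np.clip(S, 0.0, None, out=S)
    err = np.abs(S.sum(axis=1) - 1.0).max()
    if err > SUM_TOL:
        raise SimulationError(
            f"segment {segment}: probability sum deviates from 1 by {err:.3e}"
        )


def stationary_distribution(
    composition: ChannelComposition, rates: SubunitRates, V: float
) -> np.ndarray:
    """Stationary state of the full model at a fixed voltage."""
    return FullMarkovModel(composition, rates).stationary(V)
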