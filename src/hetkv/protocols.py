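"""The three voltage-clamp protocols and their summary curves.

* **Activation**: equilibrate at the holding potential (-90 mV), step to a
  test voltage; record the peak open probability and an activation time
  constant tau from the rising phase.
* **Inactivation** (steady-state availability): a 5 s conditioning pulse P1
  at each test voltage, then a 1 s test pulse P2 at +50 mV; record the peak
  open probability during P2, normalized by default to the largest P2 peak
  across sweeps so the curve starts near 1 at hyperpolarized P1 voltages.
  The literal per-sweep P2/P1 quotient is available via
  ``normalization="per_sweep"``.
* **Recovery**: a 5 s pulse P1 at +50 mV, a gap of duration delta_t at the
  holding potential, then a test pulse P2 at +50 mV; record the per-sweep
  ratio of P2 to P1 peak open probabilities as a function of delta_t.

All functions operate on any kinetic model exposing ``stationary``,
``propagate`` and ``open_probability`` (full or reduced).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar



def default_voltage_steps() -> list[float]:
    """-90..50 mV inclusive in 10 mV increments (15 sweeps)."""
    return [float(v) for v in range(-90, 51, 10)]


def default_delta_t_grid() -> list[float]:
    """20 log-spaced interpulse intervals from 10 ms to 10 s."""
    return list(np.logspace(1.0, 4.0, 20))


@dataclass(frozen=True)
class ProtocolSpec:
    """Settings for the three clamp protocols (times in ms, voltages in mV)."""

    V_hold: float = -90.0
    V_steps: tuple[float, ...] = field(default_factory=lambda: tuple(default_voltage_steps()))
    activation_duration: float = 1000.0
    inactivation_P1_duration: float = 5000.0
    inactivation_P2_duration: float = 1000.0
    inactivation_P2_V: float = 50.0
    recovery_P1_duration: float = 5000.0
    recovery_P2_duration: float = 1000.0
    recovery_V: float = 50.0
    delta_t_grid: tuple[float, ...] = field(default_factory=lambda: tuple(default_delta_t_grid()))
    output_dt: float = 1.0

    def __post_init__(self) -> None:
        for name in ("activation_duration", "inactivation_P1_duration",
                     "inactivation_P2_duration", "recovery_P1_duration",
                     "recovery_P2_duration", "output_dt"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if any(dt <= 0 for dt in self.delta_t_grid):
            raise ValueError("delta_t_grid entries must be > 0")


@dataclass
class ProtocolCurves:
    """Summary curves of the three protocols, one row per sweep."""

    activation: pd.DataFrame   # V_mV, peak_open, tau_ms
    inactivation: pd.DataFrame  # V_mV, ratio
    recovery: pd.DataFrame     # delta_t_ms, ratio


def _parabolic_peak(t: np.ndarray, y: np.ndarray, j: int):
    """Continuous peak estimate from the sample triplet around index j.

    Quadratic interpolation makes the extracted peak value and time vary
    smoothly with model parameters instead of snapping to grid points —
    important for the fitting objective's smoothness.
    """
    if j <= 0 or j >= len(y) - 1:
        return float(y[j]), float(t[j])
    y0, y1, y2 = y[j - 1], y[j], y[j + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0 or not np.isfinite(denom):
        return float(y1), float(t[j])
    delta = 0.5 * (y0 - y2) / denom  # in grid-step units, in (-1, 1)
    delta = float(np.clip(delta, -1.0, 1.0))
    step = 0.5 * (t[j + 1] - t[j - 1])
    peak = y1 - 0.25 * (y0 - y2) * delta
    return float(peak), float(t[j] + delta * step)


def _peak_open(model, P0, V, duration, dt, refine=10):
    """Peak of O(t) during one constant-V segment, with local refinement.

    Samples every ``dt`` ms, re-evaluates the propagator on a 10x finer
    grid around the coarse maximum (peaks after a step are sharp), then
    interpolates the peak parabolically. Returns (peak, t_peak, end_state).
    """
    grid = np.arange(0.0, duration + dt / 2, dt)
    if grid[-1] < duration:
        grid = np.append(grid, duration)
    grid = grid[grid > 0]
    states = model.propagate(np.asarray(P0, float), V, grid)
    O = np.asarray(model.open_probability(states, V))
    O0 = float(model.open_probability(np.asarray(P0, float)[None, :], V)[0])
    i = int(np.argmax(O))
    peak, t_peak = float(O[i]), float(grid[i])
    if O0 >= peak:
        peak, t_peak = O0, 0.0
    lo_idx = max(i - 1, 0)
    lo_t = grid[lo_idx - 1] if lo_idx > 0 else 0.0
    hi_t = grid[min(i + 1, len(grid) - 1)]
    start = states[lo_idx - 1] if lo_idx > 0 else np.asarray(P0, float)
    fine = np.linspace(0.0, hi_t - lo_t, 2 * refine + 1)[1:]
    if fine.size:
        fs = model.propagate(start, V, fine)
        fo = np.asarray(model.open_probability(fs, V))
        j = int(np.argmax(fo))
        if fo[j] > peak:
            ft = lo_t + fine
            peak, t_peak = _parabolic_peak(ft, fo, j)
            if peak < fo[j]:  # interpolation can only refine upward
                peak, t_peak = float(fo[j]), float(ft[j])
    return peak, t_peak, states[-1]


def fit_tau(times: np.ndarray, O: np.ndarray) -> float | None:
    """Single-exponential activation time constant of a rising trace.

    Least-squares fit of ``O(t) = A (1 - exp(-t/tau))`` on
    [onset, time of peak]; for each candidate tau the amplitude A is
    profiled out analytically (the model is linear in A). Returns None for
    flat or degenerate traces.
    """
    times = np.asarray(times, float)
    O = np.asarray(O, float)
    if times.size < 3 or O.size != times.size:
        return None
    i = int(np.argmax(O))
    if i < 2:
        return None
    peak = O[i]
    if peak <= O[0] + 1e-12 or peak <= 0:
        return None
    t = times[: i + 1] - times[0]
    y = O[: i + 1]
    # initial guess from the 1 - 1/e crossing
    target = peak * (1.0 - np.exp(-1.0))
    above = np.nonzero(y >= target)[0]
    tau0 = t[above[0]] if above.size and t[above[0]] > 0 else max(t[-1] / 3.0, 1e-6)

    def sse(log_tau):
        f = 1.0 - np.exp(-t / np.exp(log_tau))
        denom = float(f @ f)
        amp = float(f @ y) / denom if denom > 0 else 0.0
        return float(np.sum((amp * f - y) ** 2))

    lo, hi = np.log(tau0) - np.log(200.0), np.log(tau0) + np.log(200.0)
    try:
        sol = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-12, "maxiter": 200})
    except Exception:
        return None
    if not sol.success:
        return None
    return float(np.exp(sol.x))


def _is_homomeric(model) -> bool:
    comp = getattr(model, "composition", None)
    return comp is not None and comp.n_inactivating in (0, comp.n_inactivating + comp.n_plain)


def run_activation(model, spec: ProtocolSpec | None = None,
                   compute_tau: bool | None = None) -> pd.DataFrame:
    """Peak open probability and activation tau per step voltage.

    ``compute_tau`` defaults to homomeric channels only (the convention for
    comparing with single-channel-type experiments); pass True to force tau
    extraction for heteromers too.
    """
    spec = spec or ProtocolSpec()
    if compute_tau is None:
        compute_tau = _is_homomeric(model)
    P_hold = model.stationary(spec.V_hold)
    rows = []
    for V in spec.V_steps:
        peak, t_peak, _ = _peak_open(model, P_hold, V, spec.activation_duration,
                                     spec.output_dt)
        tau = np.nan
        if compute_tau:
            t_end = t_peak if t_peak > 0 else spec.activation_duration
            tg = np.linspace(0.0, t_end, 400)[1:]
            states = model.propagate(np.asarray(P_hold, float), V, tg)
            O = np.asarray(model.open_probability(states, V))
            tg = np.concatenate([[0.0], tg])
            O = np.concatenate([model.open_probability(
                np.asarray(P_hold, float)[None, :], V), O])
            fitted = fit_tau(tg, O)
            tau = np.nan if fitted is None else fitted
        rows.append((V, peak, tau))
    return pd.DataFrame(rows, columns=["V_mV", "peak_open", "tau_ms"])


def run_inactivation(model, spec: ProtocolSpec | None = None,
                     normalization: str = "max_sweep") -> pd.DataFrame:
    """Steady-state inactivation (availability) curve.

    ``normalization="max_sweep"`` (default) divides each sweep's P2 peak by
    the largest P2 peak over all sweeps; ``"per_sweep"`` is the literal
    quotient of the P2 peak by the same sweep's P1 peak.
    """
    spec = spec or ProtocolSpec()
    if normalization not in ("max_sweep", "per_sweep"):
        raise ValueError(f"unknown normalization {normalization!r}")
    P_hold = model.stationary(spec.V_hold)
    need_p1_peak = normalization == "per_sweep"
    p1_peaks, p2_peaks = [], []
    for V in spec.V_steps:
        if need_p1_peak:
            pk1, _, end1 = _peak_open(model, P_hold, V, spec.inactivation_P1_duration,
                                      spec.output_dt)
            p1_peaks.append(pk1)
        else:
            end1 = model.propagate(np.asarray(P_hold, float), V,
                                   np.array([spec.inactivation_P1_duration]))[-1]
        pk2, _, _ = _peak_open(model, end1, spec.inactivation_P2_V,
                               spec.inactivation_P2_duration, spec.output_dt)
        p2_peaks.append(pk2)
    p2 = np.array(p2_peaks)
    if normalization == "max_sweep":
        norm = p2.max()
        if norm <= 0:
            raise ValueError("all P2 peaks are zero; cannot normalize")
        ratio = p2 / norm
    else:
        p1 = np.array(p1_peaks)
        if (p1 <= 0).any():
            raise ValueError("a P1 peak is zero; per-sweep normalization undefined")
        ratio = p2 / p1
    return pd.DataFrame({"V_mV": list(spec.V_steps), "ratio": ratio})


def run_recovery(model, spec: ProtocolSpec | None = None) -> pd.DataFrame:
    """Recovery-from-inactivation curve: P2/P1 peak ratio vs gap duration."""
    spec = spec or ProtocolSpec()
    P_hold = model.stationary(spec.V_hold)
    pk1, _, end1 = _peak_open(model, P_hold, spec.recovery_V,
                              spec.recovery_P1_duration, spec.output_dt)
    if pk1 <= 0:
        raise ValueError("P1 peak is zero; recovery ratio undefined")
    rows = []
    for dt_gap in spec.delta_t_grid:
        gap = model.propagate(np.asarray(end1, float), spec.V_hold,
                              np.array([float(dt_gap)]))[-1]
        pk2, _, _ = _peak_open(model, gap, spec.recovery_V,
                               spec.recovery_P2_duration, spec.output_dt)
        rows.append((float(dt_gap), pk2 / pk1))
    return pd.DataFrame(rows, columns=["delta_t_ms", "ratio"])


def run_all_protocols(model, spec: ProtocolSpec | None = None,
                      normalization: str = "max_sweep",
                      compute_tau: bool | None = None) -> ProtocolCurves:
    """Run all three protocols and collect their summary curves."""
    spec = spec or ProtocolSpec()
    return ProtocolCurves(
        activation=run_activation(model, spec, compute_tau=compute_tau),
        inactivation=run_inactivation(model, spec, normalization=normalization),
        recovery=run_recovery(model, spec),
    )
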