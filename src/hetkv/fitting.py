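"""Global least-squares fitting of C-type rate parameters to protocol curves.

The fitted channel model is forward-simulated through the three clamp
protocols and compared with target curves by a weighted sum of squared
errors over the four summary curves: activation peak open probability,
activation time constant tau, steady-state inactivation ratio, and
recovery ratio. The search is a seeded, bounded, population-based global
minimization (differential evolution over log-scaled rate prefactors and
linear voltage slopes) with a local polish of the best candidate.

Because no experimental target data ship with the package, targets are
produced by :func:`make_synthetic_target` — forward curves from known
parameters, optionally with additive Gaussian noise — which also powers
the parameter-recovery harness used in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, least_squares
from scipy.stats import qmc

from .composition import ChannelComposition, SubunitKind
from .engine import FullMarkovModel
from .protocols import ProtocolCurves, ProtocolSpec, run_all_protocols
from .rates import InactivatingRates, RateLaw, SubunitRates
from .reduction import ManifoldReducedModel

#: the six C-type rate parameters: a1 = m1 exp(n1 V), b1 = m2 exp(n2 V),
#: aI and bI voltage-insensitive constants
PARAM_NAMES = ("m1", "n1", "m2", "n2", "aI", "bI")
_LOG_SCALED = frozenset({"m1", "m2", "aI", "bI"})

DEFAULT_BOUNDS = {
    "m1": (1e-5, 1e2),
    "n1": (-0.2, 0.2),
    "m2": (1e-5, 1e2),
    "n2": (-0.2, 0.2),
    "aI": (1e-5, 1e2),
    "bI": (1e-5, 1e2),
}

DEFAULT_WEIGHTS = {"activation": 1.0, "tau": 1.0, "inactivation": 1.0, "recovery": 1.0}


class FitError(RuntimeError):
    """Raised when the search finishes without any finite-SSE evaluation."""


@dataclass(frozen=True)
class FitSpec:
    """Settings of one bounded global fit."""

    free: tuple[str, ...] = PARAM_NAMES
    fixed: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    seed: int = 0
    maxiter: int = 80
    popsize: int = 12
    tol: float = 1e-8
    polish: bool = True
    n_polish: int = 24
    n_islands: int = 2
    max_evaluations: int | None = None
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)

    def __post_init__(self) -> None:
        for name in self.free:
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r}")
            lo, hi = self.bounds[name]
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name!r} must be finite with lo < hi")
            if name in _LOG_SCALED and lo <= 0:
                raise ValueError(f"bounds for rate parameter {name!r} must be positive")


@dataclass
class FitResult:
    """Outcome of :func:`fit`."""

    params: dict
    sse: float
    trace: np.ndarray          # best-so-far SSE after each evaluation
    n_evaluations: int
    converged: bool
    seed: int


def params_to_rates(params: dict, base: SubunitRates | None = None) -> SubunitRates:
    """Assemble SubunitRates with the C-type laws given by ``params``.

    Plain-subunit laws (for heteromer fits) are carried over from ``base``.
    """
    inact = InactivatingRates(
        a1=RateLaw.exponential(params["m1"], params["n1"]),
        b1=RateLaw.exponential(params["m2"], params["n2"]),
        aI=RateLaw.constant(params["aI"]),
        bI=RateLaw.constant(params["bI"]),
    )
    return SubunitRates(plain=None if base is None else base.plain, inactivating=inact)


def forward_curves(
    composition: ChannelComposition,
    rates: SubunitRates,
    protocol: ProtocolSpec | None = None,
    compute_tau: bool | None = None,
) -> ProtocolCurves:
    """Protocol curves of a channel, via the exact reduced model where one exists."""
    if composition.inactivating_kind in (None, SubunitKind.C_TYPE):
        model = ManifoldReducedModel(composition, rates)
    else:
        model = FullMarkovModel(composition, rates)
    return run_all_protocols(model, protocol, compute_tau=compute_tau)


def _curve_residuals(sim: pd.DataFrame, tgt: pd.DataFrame, col: str,
                     weight: float) -> np.ndarray:
    a = np.asarray(sim[col], float)
    b = np.asarray(tgt[col], float)
    if a.shape != b.shape:
        raise ValueError(f"target curve {col!r} has {b.size} points, model {a.size}")
    # undefined points (e.g. no detectable rise for tau) count as zero, so a
    # candidate with degenerate kinetics cannot dodge the comparison; points
    # undefined on both sides then contribute nothing
    a = np.where(np.isfinite(a), a, 0.0)
    b = np.where(np.isfinite(b), b, 0.0)
    return math.sqrt(weight) * (a - b)


def residual_vector(
    params: dict,
    composition: ChannelComposition,
    fit_spec: FitSpec,
    target: ProtocolCurves,
    base_rates: SubunitRates | None = None,
) -> np.ndarray | None:
    """Weighted residuals of the four summary curves, or None if the
    candidate cannot be simulated."""
    w = fit_spec.weights
    include_tau = composition.n_inactivating in (0, 4)
    try:
        rates = params_to_rates(params, base_rates)
        curves = forward_curves(composition, rates, fit_spec.protocol,
                                compute_tau=include_tau)
    except Exception:
        return None
    parts = [_curve_residuals(curves.activation, target.activation, "peak_open",
                              w.get("activation", 1.0))]
    if include_tau and "tau_ms" in target.activation:
        parts.append(_curve_residuals(curves.activation, target.activation,
                                      "tau_ms", w.get("tau", 1.0)))
    parts.append(_curve_residuals(curves.inactivation, target.inactivation,
                                  "ratio", w.get("inactivation", 1.0)))
    parts.append(_curve_residuals(curves.recovery, target.recovery, "ratio",
                                  w.get("recovery", 1.0)))
    return np.concatenate(parts)


def objective(
    params: dict,
    composition: ChannelComposition,
    fit_spec: FitSpec,
    target: ProtocolCurves,
    base_rates: SubunitRates | None = None,
) -> float:
    """Weighted SSE between the model's and the target's four summary curves.

    A candidate whose simulation fails returns +inf (rejected, not raised).
    """
    res = residual_vector(params, composition, fit_spec, target, base_rates)
    if res is None:
        return math.inf
    return float(res @ res)


def _to_internal(name: str, value: float) -> float:
    return math.log10(value) if name in _LOG_SCALED else value


def _from_internal(name: str, value: float) -> float:
    return 10.0 ** value if name in _LOG_SCALED else value


def fit(
    composition: ChannelComposition,
    fit_spec: FitSpec,
    target: ProtocolCurves,
    base_rates: SubunitRates | None = None,
) -> FitResult:
    """Seeded bounded global search minimizing the protocol-curve SSE.

    Rate prefactors and constants are searched on a log10 scale, voltage
    slopes linearly. When ``max_evaluations`` is small the search degrades
    to seeded random sampling within bounds so the evaluation budget is
    honored exactly; otherwise differential evolution runs with an optional
    local polish. Two runs with the same spec and seed are identical.
    """
    names = list(fit_spec.free)
    lo = np.array([_to_internal(n, fit_spec.bounds[n][0]) for n in names])
    hi = np.array([_to_internal(n, fit_spec.bounds[n][1]) for n in names])

    trace: list[float] = []
    best = {"sse": math.inf, "x": None}
    # spatial archive: best candidate per cell of the normalized search box.
    # Ranking cells (not raw candidates) keeps start-point diversity even
    # after the evolution has piled most of its evaluations into one basin.
    archive: dict[tuple, tuple[float, np.ndarray]] = {}
    span = hi - lo

    def assemble(x: np.ndarray) -> dict:
        params = dict(fit_spec.fixed)
        params.update({n: _from_internal(n, v) for n, v in zip(names, x)})
        return params

    def record(x: np.ndarray, sse: float) -> None:
        if sse < best["sse"]:
            best["sse"] = sse
            best["x"] = np.array(x)
        if math.isfinite(sse):
            cell = tuple(np.minimum((8 * (x - lo) / span).astype(int), 7))
            held = archive.get(cell)
            if held is None or sse < held[0]:
                archive[cell] = (sse, np.array(x))
        trace.append(best["sse"])

    def func(x: np.ndarray) -> float:
        sse = objective(assemble(x), composition, fit_spec, target, base_rates)
        record(x, sse)
        return sse

    include_tau = (composition.n_inactivating in (0, 4)
                   and "tau_ms" in target.activation)
    n_res = (len(target.activation) * (2 if include_tau else 1)
             + len(target.inactivation) + len(target.recovery))

    def res_func(x: np.ndarray) -> np.ndarray:
        res = residual_vector(assemble(x), composition, fit_spec, target,
                              base_rates)
        if res is None:
            # finite sentinel: far worse than any simulatable candidate
            record(x, math.inf)
            return np.full(n_res, 1e3)
        record(x, float(res @ res))
        return res

    def archive_starts(k: int) -> list[np.ndarray]:
        ranked = sorted(archive.values(), key=lambda e: e[0])
        return [x for _, x in ranked[:k]]

    budget = fit_spec.max_evaluations
    pop_total = fit_spec.popsize * len(names)
    if budget is not None and budget < 2 * pop_total:
        rng = np.random.default_rng(fit_spec.seed)
        for _ in range(budget):
            func(lo + rng.random(len(names)) * (hi - lo))
        converged = False
    else:
        maxiter = fit_spec.maxiter
        n_islands = max(fit_spec.n_islands, 1)
        if budget is not None:
            maxiter = min(maxiter, max(budget // (n_islands * pop_total) - 1, 1))
        # quasi-random pre-scan seeds the spatial archive across the whole box
        sampler = qmc.Sobol(d=len(names), seed=fit_spec.seed)
        for x in lo + sampler.random(512) * span:
            func(x)
        converged = False
        # independently seeded evolution islands: pooling their archives makes
        # basin discovery far less sensitive to any one population's luck
        for k in range(n_islands):
            result = differential_evolution(
                func,
                bounds=list(zip(lo, hi)),
                seed=(fit_spec.seed + 1000003 * k) % (2 ** 31),
                maxiter=maxiter,
                popsize=fit_spec.popsize,
                tol=fit_spec.tol,
                init="sobol",
                polish=False,
                updating="immediate",
            )
            converged = converged or bool(result.success)
        if fit_spec.polish:
            # Gauss-Newton triage of the best archive cells: the objective is
            # a sum of squares, so trust-region least squares follows its
            # curved ridges far better than direct search; the finite-
            # difference step averages over residual extraction noise
            ls_opts = dict(bounds=(lo, hi), method="trf", diff_step=1e-4,
                           xtol=1e-15, ftol=1e-15, gtol=1e-15)
            for x0 in archive_starts(fit_spec.n_polish):
                try:
                    least_squares(res_func, x0, max_nfev=60, **ls_opts)
                except Exception:
                    continue
            # full polish with iterated restarts from the incumbent
            prev = math.inf
            for _ in range(5):
                if best["x"] is None or not best["sse"] < 0.999 * prev:
                    break
                prev = best["sse"]
                try:
                    least_squares(res_func, best["x"], max_nfev=150, **ls_opts)
                except Exception:
                    break
    if best["x"] is None or not math.isfinite(best["sse"]):
        raise FitError(
            f"no finite-SSE candidate found in {len(trace)} evaluations; "
            "check bounds and target curves"
        )
    return FitResult(
        params=assemble(best["x"]),
        sse=best["sse"],
        trace=np.asarray(trace),
        n_evaluations=len(trace),
        converged=converged,
        seed=fit_spec.seed,
    )


def make_synthetic_target(
    composition: ChannelComposition,
    true_params: dict,
    noise_sd: float = 0.0,
    seed: int = 0,
    protocol: ProtocolSpec | None = None,
    base_rates: SubunitRates | None = None,
) -> ProtocolCurves:
    """Forward protocol curves from known parameters plus Gaussian noise.

    Probability/ratio curves are clipped to [0, 1] after adding noise; the
    tau curve is left unclipped. ``noise_sd = 0`` returns the exact forward
    curves.
    """
    rates = params_to_rates(true_params, base_rates)
    include_tau = composition.n_inactivating in (0, 4)
    curves = forward_curves(composition, rates, protocol, compute_tau=include_tau)
    if noise_sd == 0.0:
        return curves
    rng = np.random.default_rng(seed)

    def noisy(df: pd.DataFrame, col: str, clip: bool) -> pd.DataFrame:
        out = df.copy()
        vals = np.asarray(out[col], float)
        jitter = rng.normal(0.0, noise_sd, size=vals.shape)
        vals = np.where(np.isfinite(vals), vals + jitter, vals)
        if clip:
            vals = np.clip(vals, 0.0, 1.0)
        out[col] = vals
        return out

    activation = noisy(curves.activation, "peak_open", clip=True)
    activation = noisy(activation, "tau_ms", clip=False)
    return ProtocolCurves(
        activation=activation,
        inactivation=noisy(curves.inactivation, "ratio", clip=True),
        recovery=noisy(curves.recovery, "ratio", clip=True),
    )
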