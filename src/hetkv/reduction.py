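"""Model reductions: quasi-steady-state (N-type) and invariant manifold (C-type).

**QSS reduction (N-type family).** When activation gating is much faster
than ball binding (a1, b1, a2, b2 >> aI, bI), the closed/open states
equilibrate instantly and their total mass X = sum of all non-inactivated
states obeys the single ODE

    dX/dt = -aI * N * X / kappa(V) + bI * (1 - X),

where N is the number of N-type subunits and kappa(V) is the reciprocal of
the conditional open fraction at fast equilibrium,

    kappa = ((a1+b1)/a1)^N * ((a2+b2)/a2)^(4-N).

The open probability is recovered as O = X / kappa(V), evaluated
adiabatically at the instantaneous voltage.

**Invariant-manifold reduction (C-type family).** Independent subunits make
the product of per-subunit distributions an exact invariant manifold of
the full master equation. With q the open probability of a single plain
subunit, and (n, h) the open and inactive probabilities of a single C-type
subunit,

    dq/dt = a2 (1-q) - b2 q
    dn/dt = -(b1 + aI) n + a1 (1-n-h) + bI h
    dh/dt = aI n - bI h,

the full state is the multinomial-times-binomial lift

    P(i,j,k) = m!/((m-i)! (i-j)! j!) (1-n-h)^(m-i) n^(i-j) h^j
               * C(p,k) q^k (1-q)^(p-k),

with m C-type and p = 4-m plain subunits. Trajectories started on the
manifold never leave it, so the 3-variable model (2 variables when p = 0)
is exact, not approximate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .composition import ChannelComposition, SubunitKind
from .markov import StateSpace, build_generator, enumerate_states
from .rates import SubunitRates


class ReductionError(ValueError):
    """Raised for reductions applied outside their domain of validity."""


# ---------------------------------------------------------------------------
# QSS reduction (N-type family)
# ---------------------------------------------------------------------------

def qss_kappa(composition: ChannelComposition, rates: SubunitRates, V: float) -> float:
    """kappa(V) >= 1: total non-inactivated mass per unit of open probability."""
    n = composition.n_inactivating
    p = composition.n_plain
    kappa = 1.0
    if n > 0:
        ir = rates.require_inactivating()
        a1, b1 = ir.a1(V), ir.b1(V)
        if a1 <= 0:
            raise ReductionError(f"a1({V} mV) = {a1}; kappa undefined")
        kappa *= ((a1 + b1) / a1) ** n
    if p > 0:
        pr = rates.require_plain()
        a2, b2 = pr.a2(V), pr.b2(V)
        if a2 <= 0:
            raise ReductionError(f"a2({V} mV) = {a2}; kappa undefined")
        kappa *= ((a2 + b2) / a2) ** p
    return kappa


class QSSReducedModel:
    """One-ODE quasi-steady-state model of an N-type-family channel.

    State vector is ``[X]``, the probability mass in non-inactivated
    states; the inactive probability is ``I = 1 - X`` and the open
    probability ``O = X / kappa(V)``.
    """

    reduced = True
    state_names = ["X"]

    def __init__(self, composition: ChannelComposition, rates: SubunitRates) -> None:
        if composition.inactivating_kind not in (None, SubunitKind.N_TYPE):
            raise ReductionError("QSS reduction applies to the N-type family")
        self.composition = composition
        self.rates = rates
        self.N = composition.n_inactivating

    def kappa(self, V: float) -> float:
        return qss_kappa(self.composition, self.rates, V)

    def _rates_at(self, V: float) -> tuple[float, float]:
        if self.N == 0:
            return 0.0, 0.0
        ir = self.rates.require_inactivating()
        return ir.aI(V), ir.bI(V)

    def stationary(self, V: float) -> np.ndarray:
        aI, bI = self._rates_at(V)
        lam = self.N * aI / self.kappa(V) + bI
        X = 1.0 if lam == 0 else bI / lam
        return np.array([X])

    def propagate(self, X0: np.ndarray, V: float, times: np.ndarray) -> np.ndarray:
        """Exact scalar relaxation X(t) = X* + (X0 - X*) exp(-lam t)."""
        times = np.asarray(times, float)
        X0 = float(np.asarray(X0).ravel()[0])
        aI, bI = self._rates_at(V)
        lam = self.N * aI / self.kappa(V) + bI
        if lam == 0:
            X = np.full_like(times, X0)
        else:
            Xinf = bI / lam
            X = Xinf + (X0 - Xinf) * np.exp(-lam * times)
        return X[:, None]

    def open_probability(self, states: np.ndarray, V: float) -> np.ndarray:
        return np.asarray(states)[..., 0] / self.kappa(V)

    def inactive_probability(self, states: np.ndarray) -> np.ndarray:
        return 1.0 - np.asarray(states)[..., 0]


# ---------------------------------------------------------------------------
# Invariant-manifold reduction (C-type family)
# ---------------------------------------------------------------------------

def _rates_at(composition: ChannelComposition, rates: SubunitRates, V: float):
    """(a1, b1, aI, bI, a2, b2) evaluated at V, zeros where a type is absent."""
    a1 = b1 = aI = bI = a2 = b2 = 0.0
    if composition.n_inactivating > 0:
        ir = rates.require_inactivating()
        a1, b1, aI, bI = ir.a1(V), ir.b1(V), ir.aI(V), ir.bI(V)
    if composition.n_plain > 0:
        pr = rates.require_plain()
        a2, b2 = pr.a2(V), pr.b2(V)
    return a1, b1, aI, bI, a2, b2


def manifold_rhs(state, composition: ChannelComposition, rates: SubunitRates,
                 V: float) -> np.ndarray:
    """(dq/dt, dn/dt, dh/dt) of the single-subunit gating variables."""
    q, n, h = (float(x) for x in state)
    a1, b1, aI, bI, a2, b2 = _rates_at(composition, rates, V)
    dq = a2 * (1.0 - q) - b2 * q
    dn = -(b1 + aI) * n + a1 * (1.0 - n - h) + bI * h
    dh = aI * n - bI * h
    return np.array([dq, dn, dh])


def _check_simplex(q: float, n: float, h: float) -> None:
    tol = 1e-12
    if not (-tol <= q <= 1 + tol and n >= -tol and h >= -tol and n + h <= 1 + tol):
        raise ReductionError(
            f"(q, n, h) = ({q}, {n}, {h}) outside the gating simplex"
        )


def _pow(x: float, e: int) -> float:
    return 1.0 if e == 0 else x ** e


def manifold_lift(state, composition: ChannelComposition,
                  space: StateSpace | None = None) -> np.ndarray:
    """Lift (q, n, h) to the full C-type-family probability vector."""
    q, n, h = (float(x) for x in state)
    _check_simplex(q, n, h)
    if space is None:
        space = enumerate_states(composition)
    m = composition.n_inactivating
    p = composition.n_plain
    c = 1.0 - n - h
    P = np.empty(len(space))
    for pos, lab in enumerate(space.labels):
        if lab[0] == "P":  # plain homomer limit (m = 0)
            k = lab[1]
            P[pos] = math.comb(p, k) * _pow(q, k) * _pow(1 - q, p - k)
            continue
        _, i, j, k = lab
        mult = (math.factorial(m)
                // (math.factorial(m - i) * math.factorial(i - j) * math.factorial(j)))
        P[pos] = (mult * _pow(c, m - i) * _pow(n, i - j) * _pow(h, j)
                  * math.comb(p, k) * _pow(q, k) * _pow(1 - q, p - k))
    return P


def manifold_lift_jacobian(state, composition: ChannelComposition,
                           space: StateSpace | None = None) -> np.ndarray:
    """Analytic Jacobian of the lift: columns dP/dq, dP/dn, dP/dh."""
    q, n, h = (float(x) for x in state)
    if space is None:
        space = enumerate_states(composition)
    m = composition.n_inactivating
    p = composition.n_plain
    c = 1.0 - n - h
    J = np.zeros((len(space), 3))

    def dpow(x: float, e: int) -> float:
        # d/dx x^e, safe at e = 0
        return 0.0 if e == 0 else e * _pow(x, e - 1)

    for pos, lab in enumerate(space.labels):
        if lab[0] == "P":
            k = lab[1]
            binom = math.comb(p, k)
            J[pos, 0] = binom * (dpow(q, k) * _pow(1 - q, p - k)
                                 - _pow(q, k) * dpow(1 - q, p - k))
            continue
        _, i, j, k = lab
        mult = (math.factorial(m)
                // (math.factorial(m - i) * math.factorial(i - j) * math.factorial(j)))
        binom = math.comb(p, k)
        f_c, f_n, f_h = _pow(c, m - i), _pow(n, i - j), _pow(h, j)
        f_q = _pow(q, k) * _pow(1 - q, p - k)
        J[pos, 0] = mult * f_c * f_n * f_h * binom * (
            dpow(q, k) * _pow(1 - q, p - k) - _pow(q, k) * dpow(1 - q, p - k))
        # dc/dn = dc/dh = -1
        J[pos, 1] = mult * binom * f_q * (dpow(n, i - j) * f_c * f_h
                                          - f_n * dpow(c, m - i) * f_h)
        J[pos, 2] = mult * binom * f_q * (dpow(h, j) * f_c * f_n
                                          - f_h * dpow(c, m - i) * f_n)
    return J


def manifold_open_probability(state, composition: ChannelComposition) -> float:
    """Conducting-state probability n^m q^(4-m) of the lifted distribution."""
    q, n, h = (float(x) for x in state)
    return _pow(n, composition.n_inactivating) * _pow(q, composition.n_plain)


def invariance_residual(composition: ChannelComposition, rates: SubunitRates,
                        V: float, state) -> float:
    """Sup-norm of R * lift - J_lift * rhs; ~0 certifies invariance at this state."""
    space = enumerate_states(composition)
    R = build_generator(composition, rates, V, space)
    P = manifold_lift(state, composition, space)
    J = manifold_lift_jacobian(state, composition, space)
    f = manifold_rhs(state, composition, rates, V)
    return float(np.abs(R @ P - J @ f).max())


class ManifoldReducedModel:
    """Exact reduced model of a C-type-family channel in (q, n, h).

    The dynamical dimension is 3 for heteromers, 2 for the C-type homomer
    (q is absent when there are no plain subunits) and 1 in the plain
    limit; the state vector is stored as (q, n, h) throughout.
    """

    reduced = True
    state_names = ["q", "n", "h"]

    def __init__(self, composition: ChannelComposition, rates: SubunitRates) -> None:
        if composition.inactivating_kind not in (None, SubunitKind.C_TYPE):
            raise ReductionError("the manifold reduction applies to the C-type family")
        self.composition = composition
        self.rates = rates
        self.m = composition.n_inactivating
        self.p = composition.n_plain
        self._V_cache: dict[float, tuple] = {}

    @property
    def dimension(self) -> int:
        if self.m == 0:
            return 1
        return 2 if self.p == 0 else 3

    def stationary(self, V: float) -> np.ndarray:
        a1, b1, aI, bI, a2, b2 = _rates_at(self.composition, self.rates, V)
        q = a2 / (a2 + b2) if (a2 + b2) > 0 else 0.0
        n = h = 0.0
        if self.m > 0:
            A, b = self._nh_system(a1, b1, aI, bI)
            try:
                n, h = np.linalg.solve(A, -b)
            except np.linalg.LinAlgError:
                warnings.warn("singular (n, h) system; using long-run integration",
                              RuntimeWarning)
                n, h = self._propagate_nh(np.zeros(2), A, b, np.array([1e7]))[-1]
        return np.array([q, n, h])

    @staticmethod
    def _nh_system(a1, b1, aI, bI):
        A = np.array([[-(a1 + b1 + aI), bI - a1], [aI, -bI]])
        b = np.array([a1, 0.0])
        return A, b

    @staticmethod
    def _nh_modes(A: np.ndarray, b: np.ndarray):
        """Closed-form spectral data of the 2x2 affine system, or None.

        Returns (zstar, lam1, lam2, Vmat, Vinv) for the generic case of a
        real, non-defective, invertible A; None signals the caller to use
        the (slower, fully general) augmented-expm path.
        """
        a00, a01, a10, a11 = A[0, 0], A[0, 1], A[1, 0], A[1, 1]
        det = a00 * a11 - a01 * a10
        scale = max(abs(a00), abs(a01), abs(a10), abs(a11), 1e-30)
        if abs(det) < 1e-14 * scale * scale:
            return None
        tr = a00 + a11
        disc = 0.25 * tr * tr - det
        if disc < 0:
            return None
        s = math.sqrt(disc)
        lam1, lam2 = 0.5 * tr + s, 0.5 * tr - s
        if abs(lam1 - lam2) < 1e-10 * scale:
            return None
        zstar = np.array([(-b[0] * a11 + b[1] * a01) / det,
                          (-b[1] * a00 + b[0] * a10) / det])
        vecs = []
        for lam in (lam1, lam2):
            v = (a01, lam - a00)
            if abs(v[0]) + abs(v[1]) < 1e-14 * scale:
                v = (lam - a11, a10)
            norm = math.hypot(*v)
            vecs.append((v[0] / norm, v[1] / norm))
        Vmat = np.array(vecs).T
        detV = Vmat[0, 0] * Vmat[1, 1] - Vmat[0, 1] * Vmat[1, 0]
        if abs(detV) < 1e-10:
            return None
        Vinv = np.array([[Vmat[1, 1], -Vmat[0, 1]], [-Vmat[1, 0], Vmat[0, 0]]]) / detV
        return zstar, lam1, lam2, Vmat, Vinv

    @staticmethod
    def _propagate_nh_expm(z0, A, b, times):
        """Augmented-expm solution of dz/dt = A z + b; handles singular A."""
        M = np.zeros((3, 3))
        M[:2, :2] = A
        M[:2, 2] = b
        out = np.empty((len(times), 2))
        aug = np.array([z0[0], z0[1], 1.0])
        prev = 0.0
        cache: dict[float, np.ndarray] = {}
        for idx, t in enumerate(times):
            dt = t - prev
            if dt > 0:
                T = cache.get(dt)
                if T is None:
                    T = expm(M * dt)
                    cache[dt] = T
                aug = T @ aug
            out[idx] = aug[:2]
            prev = t
        return out

    def _at_voltage(self, V: float):
        """Per-voltage cache of rates and (n, h) spectral data."""
        entry = self._V_cache.get(V)
        if entry is None:
            a1, b1, aI, bI, a2, b2 = _rates_at(self.composition, self.rates, V)
            A, b = self._nh_system(a1, b1, aI, bI)
            modes = self._nh_modes(A, b) if self.m > 0 else None
            entry = (a2 + b2, a2, A, b, modes)
            self._V_cache[V] = entry
        return entry

    def _propagate_nh(self, z0, A, b, times, modes=None):
        """Solution of dz/dt = A z + b at the given times (exact)."""
        if modes is None:
            modes = self._nh_modes(A, b)
        if modes is None:
            return self._propagate_nh_expm(z0, A, b, times)
        zstar, lam1, lam2, Vmat, Vinv = modes
        dz = np.asarray(z0, float) - zstar
        c1 = Vinv[0, 0] * dz[0] + Vinv[0, 1] * dz[1]
        c2 = Vinv[1, 0] * dz[0] + Vinv[1, 1] * dz[1]
        e1 = c1 * np.exp(lam1 * times)
        e2 = c2 * np.exp(lam2 * times)
        out = np.empty((len(times), 2))
        out[:, 0] = zstar[0] + Vmat[0, 0] * e1 + Vmat[0, 1] * e2
        out[:, 1] = zstar[1] + Vmat[1, 0] * e1 + Vmat[1, 1] * e2
        return out

    def propagate(self, z0: np.ndarray, V: float, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, float)
        q0, n0, h0 = (float(x) for x in np.asarray(z0).ravel())
        lam_q, a2, A, b, modes = self._at_voltage(V)
        out = np.empty((len(times), 3))
        if lam_q > 0:
            qinf = a2 / lam_q
            out[:, 0] = qinf + (q0 - qinf) * np.exp(-lam_q * times)
        else:
            out[:, 0] = q0
        if self.m > 0:
            out[:, 1:] = self._propagate_nh(np.array([n0, h0]), A, b, times, modes)
        else:
            out[:, 1] = n0
            out[:, 2] = h0
        return out

    def open_probability(self, states: np.ndarray, V: float | None = None) -> np.ndarray:
        S = np.atleast_2d(np.asarray(states, float))
        O = np.ones(S.shape[0])
        if self.m > 0:
            O *= S[:, 1] ** self.m
        if self.p > 0:
            O *= S[:, 0] ** self.p
        return O

    def lift(self, state) -> np.ndarray:
        return manifold_lift(state, self.composition)
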