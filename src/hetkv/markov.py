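"""Markov state spaces and transition-rate generators for Kv tetramers.

Subunits gate independently, so a channel's Markov state only needs to
record how many subunits of each type are in each conformation:

* plain homomer (0 inactivating subunits): states ``P0..P4`` counting open
  non-inactivating subunits; 5 states.
* N-type family (n inactivating subunits, 1 <= n <= 4): states ``(i, j)``
  with ``i`` open inactivating subunits (0..n) and ``j`` open plain
  subunits (0..4-n), plus one distinguished inactive state ``I`` reached
  from the conducting state when any one of the n tethered N-terminal
  balls occludes the pore; ``(n+1)(5-n) + 1`` states.
* C-type family (m inactivating subunits, 1 <= m <= 4): states
  ``(i, j, k)`` with ``i`` C-type subunits having reached the open state
  (0..m), ``j`` of those currently inactive (0..i), and ``k`` open plain
  subunits (0..4-m); ``(m+1)(m+2)/2 * (5-m)`` states. Each C-type subunit
  inactivates individually from its own open conformation.

The conducting state ``O`` is the unique state with every subunit open and
none inactive. The generator ``R`` collects transition rates with the
convention ``R[s_to, s_from]``; its columns sum to zero so that
``dP/dt = R P`` conserves probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .composition import TETRAMER_SIZE, ChannelComposition, SubunitKind
from .rates import RateLawError, SubunitRates

# N-type family state labels are tuples ("C", i, j) plus ("I",);
# C-type family labels are ("C", i, j, k); the plain homomer uses ("P", j).
StateLabel = tuple

INACTIVE_LABEL: StateLabel = ("I",)


def state_count(composition: ChannelComposition) -> int:
    """Number of Markov states (equivalently ODEs) of the full model."""
    n = composition.n_inactivating
    if n == 0:
        return TETRAMER_SIZE + 1
    if composition.inactivating_kind is SubunitKind.N_TYPE:
        return (n + 1) * (TETRAMER_SIZE + 1 - n) + 1
    return (n + 1) * (n + 2) // 2 * (TETRAMER_SIZE + 1 - n)


@dataclass(frozen=True)
class StateSpace:
    """Ordered Markov states of one channel composition.

    Ordering is lexicographic in the count indices — ``(i, j)`` for the
    N-type family with the inactive state ``I`` appended last, ``(i, j, k)``
    for the C-type family — so state indices are reproducible.
    """

    composition: ChannelComposition
    labels: tuple[StateLabel, ...]
    index: dict[StateLabel, int] = field(repr=False)
    conducting_index: int
    inactive_index: int | None  # N-type family only

    def __len__(self) -> int:
        return len(self.labels)

    def label_names(self) -> list[str]:
        """Human-readable state names (for CSV headers etc.).

        Homomeric channels drop the constant plain-subunit index, so the
        N-type homomer reads C0..C3, O, I.
        """
        drop_plain = self.composition.n_plain == 0
        names = []
        for pos, lab in enumerate(self.labels):
            if pos == self.conducting_index:
                names.append("O")
            elif lab == INACTIVE_LABEL:
                names.append("I")
            elif lab[0] == "P":
                names.append(f"P{lab[1]}")
            else:
                idx = lab[1:-1] if drop_plain else lab[1:]
                names.append("C" + ",".join(str(x) for x in idx))
        return names


def enumerate_states(composition: ChannelComposition) -> StateSpace:
    """Enumerate the Markov states of a composition in canonical order."""
    n = composition.n_inactivating
    p = composition.n_plain
    labels: list[StateLabel] = []
    inactive_index: int | None = None
    if n == 0:
        labels = [("P", j) for j in range(p + 1)]
        conducting = ("P", p)
    elif composition.inactivating_kind is SubunitKind.N_TYPE:
        labels = [("C", i, j) for i in range(n + 1) for j in range(p + 1)]
        conducting = ("C", n, p)
        labels.append(INACTIVE_LABEL)
        inactive_index = len(labels) - 1
    else:
        labels = [
            ("C", i, j, k)
            for i in range(n + 1)
            for j in range(i + 1)
            for k in range(p + 1)
        ]
        conducting = ("C", n, 0, p)
    index = {lab: pos for pos, lab in enumerate(labels)}
    assert len(index) == len(labels) == state_count(composition)
    return StateSpace(
        composition=composition,
        labels=tuple(labels),
        index=index,
        conducting_index=index[conducting],
        inactive_index=inactive_index,
    )


def _check_rate(name: str, value: float) -> float:
    if value < 0 or not np.isfinite(value):
        raise RateLawError(f"rate {name} evaluated to {value}; must be >= 0 and finite")
    return value


def build_generator(
    composition: ChannelComposition,
    rates: SubunitRates,
    V: float,
    space: StateSpace | None = None,
) -> np.ndarray:
    """Assemble the transition-rate generator R(V) in ms^-1.

    ``R[s_to, s_from]`` holds the rate of the transition ``s_from -> s_to``;
    diagonal entries are negative column sums, so columns sum to zero.
    """
    if space is None:
        space = enumerate_states(composition)
    n = composition.n_inactivating
    p = composition.n_plain
    S = len(space)
    R = np.zeros((S, S))

    def add(frm: StateLabel, to: StateLabel, rate: float) -> None:
        if rate == 0.0:
            return
        a, b = space.index[frm], space.index[to]
        R[b, a] += rate
        R[a, a] -= rate

    if p > 0:
        pr = rates.require_plain()
        a2, b2 = _check_rate("a2", pr.a2(V)), _check_rate("b2", pr.b2(V))
    if n > 0:
        ir = rates.require_inactivating()
        a1, b1 = _check_rate("a1", ir.a1(V)), _check_rate("b1", ir.b1(V))
        aI, bI = _check_rate("aI", ir.aI(V)), _check_rate("bI", ir.bI(V))

    if n == 0:
        for j in range(p + 1):
            if j < p:
                add(("P", j), ("P", j + 1), (p - j) * a2)
            if j > 0:
                add(("P", j), ("P", j - 1), j * b2)
        return R

    if composition.inactivating_kind is SubunitKind.N_TYPE:
        for i in range(n + 1):
            for j in range(p + 1):
                s = ("C", i, j)
                if i < n:
                    add(s, ("C", i + 1, j), (n - i) * a1)
                if i > 0:
                    add(s, ("C", i - 1, j), i * b1)
                if j < p:
                    add(s, ("C", i, j + 1), (p - j) * a2)
                if j > 0:
                    add(s, ("C", i, j - 1), j * b2)
        # any one of the n tethered balls can occlude the open pore
        conducting = ("C", n, p)
        add(conducting, INACTIVE_LABEL, n * aI)
        add(INACTIVE_LABEL, conducting, bI)
        return R

    # C-type family: each of the i-j open, non-inactive C-type subunits can
    # close (rate b1 each) or inactivate (rate aI each); each of the j
    # inactive ones recovers to open at bI.
    for i in range(n + 1):
        for j in range(i + 1):
            for k in range(p + 1):
                s = ("C", i, j, k)
                if i < n:
                    add(s, ("C", i + 1, j, k), (n - i) * a1)
                if i > j:
                    add(s, ("C", i - 1, j, k), (i - j) * b1)
                    add(s, ("C", i, j + 1, k), (i - j) * aI)
                if j > 0:
                    add(s, ("C", i, j - 1, k), j * bI)
                if k < p:
                    add(s, ("C", i, j, k + 1), (p - k) * a2)
                if k > 0:
                    add(s, ("C", i, j, k - 1), k * b2)
    return R
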