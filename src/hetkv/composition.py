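"""Subunit kinds and tetramer compositions.

A functional Kv channel is a tetramer: four pore-forming alpha subunits.
This package models channels assembled from at most two subunit types —
one non-inactivating type plus (optionally) one inactivating type, where
the inactivating type carries either N-type ("ball and chain") or C-type
(selectivity-filter) inactivation kinetics.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

TETRAMER_SIZE = 4


class SubunitKind(enum.Enum):
    """The three admissible alpha-subunit kinds."""

    NON_INACTIVATING = "non_inactivating"
    N_TYPE = "n_type"
    C_TYPE = "c_type"


class CompositionError(ValueError):
    """Raised for subunit counts that cannot form a valid tetramer."""


@dataclass(frozen=True)
class ChannelComposition:
    """Counts of each subunit kind forming one tetrameric channel.

    Parameters
    ----------
    inactivating_kind
        ``SubunitKind.N_TYPE`` or ``SubunitKind.C_TYPE``, or ``None`` for a
        purely non-inactivating channel.
    n_inactivating
        Number of inactivating subunits (0..4).
    n_plain
        Number of non-inactivating subunits; ``n_inactivating + n_plain``
        must equal 4.
    """

    inactivating_kind: SubunitKind | None
    n_inactivating: int
    n_plain: int

    def __post_init__(self) -> None:
        if not isinstance(self.n_inactivating, int) or not isinstance(self.n_plain, int):
            raise CompositionError("subunit counts must be integers")
        if self.n_inactivating < 0 or self.n_plain < 0:
            raise CompositionError(
                f"subunit counts must be non-negative, got "
                f"{self.n_inactivating}:{self.n_plain}"
            )
        if self.n_inactivating + self.n_plain != TETRAMER_SIZE:
            raise CompositionError(
                f"subunit counts must sum to {TETRAMER_SIZE} (tetramer), got "
                f"{self.n_inactivating} + {self.n_plain} = "
                f"{self.n_inactivating + self.n_plain}"
            )
        if self.inactivating_kind is SubunitKind.NON_INACTIVATING:
            raise CompositionError(
                "inactivating_kind must be N_TYPE, C_TYPE or None"
            )
        if self.n_inactivating == 0 and self.inactivating_kind is not None:
            raise CompositionError(
                "a channel with zero inactivating subunits must not name an "
                "inactivating kind"
            )
        if self.n_inactivating > 0 and self.inactivating_kind is None:
            raise CompositionError(
                "inactivating_kind required when n_inactivating > 0"
            )

    @classmethod
    def plain(cls) -> "ChannelComposition":
        """The homomeric non-inactivating channel (0:4)."""
        return cls(None, 0, TETRAMER_SIZE)

    @classmethod
    def n_type(cls, n_inactivating: int) -> "ChannelComposition":
        """A channel with ``n_inactivating`` N-type subunits (0..4)."""
        if n_inactivating == 0:
            return cls.plain()
        return cls(SubunitKind.N_TYPE, n_inactivating, TETRAMER_SIZE - n_inactivating)

    @classmethod
    def c_type(cls, n_inactivating: int) -> "ChannelComposition":
        """A channel with ``n_inactivating`` C-type subunits (0..4)."""
        if n_inactivating == 0:
            return cls.plain()
        return cls(SubunitKind.C_TYPE, n_inactivating, TETRAMER_SIZE - n_inactivating)

    @property
    def family(self) -> str:
        """``"plain"``, ``"n_type"`` or ``"c_type"``."""
        if self.inactivating_kind is None:
            return "plain"
        return self.inactivating_kind.value

    def __str__(self) -> str:
        return f"{self.family} {self.n_inactivating}:{self.n_plain}"


def composition_from_family(family: str, n_inactivating: int) -> ChannelComposition:
    """Build a composition from a family name and inactivating-subunit count."""
    family = family.lower()
    if family == "plain":
        if n_inactivating != 0:
            raise CompositionError("plain family requires 0 inactivating subunits")
        return ChannelComposition.plain()
    if family == "n_type":
        return ChannelComposition.n_type(n_inactivating)
    if family == "c_type":
        return ChannelComposition.c_type(n_inactivating)
    raise CompositionError(f"unknown channel family {family!r}")
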