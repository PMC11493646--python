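"""Voltage-dependent transition-rate laws and packaged fixture parameter sets.

Subunit gating transitions follow either a constant rate (used for the
voltage-insensitive inactivation steps) or a single-exponential law
``m * exp(n * V)`` — the classic Eyring-style form for voltage-dependent
opening/closing. Units: voltage in mV, rates in 1/ms, slopes in 1/mV.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from importlib import resources

import yaml


class RateLawError(ValueError):
    """Raised for rate laws that evaluate to a non-finite or negative rate."""


class RateForm(enum.Enum):
    CONSTANT = "constant"
    EXPONENTIAL = "exponential"


@dataclass(frozen=True)
class RateLaw:
    """A transition-rate law: a constant or ``m * exp(n * V)``.

    For ``CONSTANT`` only ``value`` is used (ms^-1). For ``EXPONENTIAL``,
    ``m`` is the zero-voltage rate (ms^-1) and ``n`` the voltage
    sensitivity (mV^-1).
    """

    form: RateForm
    value: float = 0.0
    m: float = 0.0
    n: float = 0.0

    @classmethod
    def constant(cls, value: float) -> "RateLaw":
        return cls(RateForm.CONSTANT, value=float(value))

    @classmethod
    def exponential(cls, m: float, n: float) -> "RateLaw":
        return cls(RateForm.EXPONENTIAL, m=float(m), n=float(n))

    def __call__(self, V: float) -> float:
        """Evaluate the rate at membrane potential ``V`` (mV)."""
        if not math.isfinite(V):
            raise RateLawError(f"voltage must be finite, got {V}")
        if self.form is RateForm.CONSTANT:
            rate = self.value
        else:
            try:
                rate = self.m * math.exp(self.n * V)
            except OverflowError:
                raise RateLawError(f"rate law {self} overflows at V={V} mV") from None
        if not math.isfinite(rate):
            raise RateLawError(f"rate law {self} is non-finite at V={V} mV")
        if rate < 0:
            raise RateLawError(f"rate law {self} is negative at V={V} mV")
        return rate

    def to_dict(self) -> dict:
        if self.form is RateForm.CONSTANT:
            return {"form": "constant", "value": self.value}
        return {"form": "exponential", "m": self.m, "n": self.n}

    @classmethod
    def from_dict(cls, spec: dict) -> "RateLaw":
        form = spec.get("form")
        if form == "constant":
            return cls.constant(spec["value"])
        if form == "exponential":
            return cls.exponential(spec["m"], spec["n"])
        raise RateLawError(f"unknown rate-law form {form!r}")


@dataclass(frozen=True)
class PlainRates:
    """Opening/closing laws a2, b2 of a non-inactivating subunit."""

    a2: RateLaw
    b2: RateLaw


@dataclass(frozen=True)
class InactivatingRates:
    """Laws of an inactivating subunit.

    ``a1``/``b1`` are the activation-gate opening/closing laws; ``aI``/``bI``
    the inactivation binding/unbinding laws. For N-type subunits ``aI`` is
    the per-ball pore-binding rate (the channel-level rate from the open
    state scales with the number of balls); for C-type subunits ``aI`` acts
    per open subunit.
    """

    a1: RateLaw
    b1: RateLaw
    aI: RateLaw
    bI: RateLaw


@dataclass(frozen=True)
class SubunitRates:
    """Rate laws for (up to) the two subunit types of one channel."""

    plain: PlainRates | None = None
    inactivating: InactivatingRates | None = None

    def require_plain(self) -> PlainRates:
        if self.plain is None:
            raise RateLawError("composition contains non-inactivating subunits "
                               "but no plain rate laws were provided")
        return self.plain

    def require_inactivating(self) -> InactivatingRates:
        if self.inactivating is None:
            raise RateLawError("composition contains inactivating subunits "
                               "but no inactivating rate laws were provided")
        return self.inactivating


def rate_separation(rates: SubunitRates, V_grid) -> float:
    """Worst-case activation/inactivation timescale separation over a grid.

    Returns ``min over V of min(a1,b1,a2,b2)(V) / max(aI,bI)(V)`` using
    whichever activation laws are present. Values much greater than 1 mean
    closed<->open gating equilibrates fast relative to inactivation, the
    regime where the quasi-steady-state reduction is warranted. Zero
    inactivation rates give ``inf``.
    """
    V_grid = list(V_grid)
    if not V_grid:
        raise ValueError("V_grid must be non-empty")
    activation: list[RateLaw] = []
    if rates.plain is not None:
        activation += [rates.plain.a2, rates.plain.b2]
    inact: list[RateLaw] = []
    if rates.inactivating is not None:
        activation += [rates.inactivating.a1, rates.inactivating.b1]
        inact += [rates.inactivating.aI, rates.inactivating.bI]
    if not activation:
        raise ValueError("no rate laws present")
    worst = math.inf
    for V in V_grid:
        fast = min(law(V) for law in activation)
        slow = max((law(V) for law in inact), default=0.0)
        ratio = math.inf if slow == 0 else fast / slow
        worst = min(worst, ratio)
    return worst


@dataclass(frozen=True)
class FixtureSet:
    """A named, packaged rate-parameter set with a provenance note."""

    name: str
    rates: SubunitRates
    note: str


_FIXTURE_FILES = {
    "KV11_LIKE": "kv11_like.yaml",
    "KV14_NTYPE_LIKE": "kv14_ntype_like.yaml",
    "KV14_DN_CTYPE_LIKE": "kv14_dn_ctype_like.yaml",
}


def fixture_names() -> list[str]:
    return sorted(_FIXTURE_FILES)


def _rates_from_mapping(data: dict) -> SubunitRates:
    plain = None
    inactivating = None
    if "plain" in data and data["plain"] is not None:
        p = data["plain"]
        plain = PlainRates(RateLaw.from_dict(p["a2"]), RateLaw.from_dict(p["b2"]))
    if "inactivating" in data and data["inactivating"] is not None:
        q = data["inactivating"]
        inactivating = InactivatingRates(
            RateLaw.from_dict(q["a1"]),
            RateLaw.from_dict(q["b1"]),
            RateLaw.from_dict(q["aI"]),
            RateLaw.from_dict(q["bI"]),
        )
    return SubunitRates(plain=plain, inactivating=inactivating)


def load_fixture(name: str) -> FixtureSet:
    """Load a packaged fixture parameter set by name."""
    try:
        fname = _FIXTURE_FILES[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        ) from None
    text = resources.files("hetkv.fixtures").joinpath(fname).read_text()
    data = yaml.safe_load(text)
    return FixtureSet(
        name=data["name"],
        rates=_rates_from_mapping(data),
        note=data["note"].strip(),
    )
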