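"""YAML run configuration: validation, defaults, and (de)serialization.

A run is fully described by one config file plus a seed; unknown keys are
rejected so typos fail loudly rather than silently falling back to
defaults.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .composition import ChannelComposition, composition_from_family
from .fitting import DEFAULT_BOUNDS, DEFAULT_WEIGHTS, PARAM_NAMES, FitSpec
from .protocols import ProtocolSpec, default_delta_t_grid, default_voltage_steps
from .rates import SubunitRates, _rates_from_mapping, load_fixture


class ConfigError(ValueError):
    """Raised for invalid or unparseable run configurations."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolConfig(_Strict):
    V_hold: float = -90.0
    V_steps: list[float] | None = None        # default: -90..50 mV by 10
    activation_duration: float = 1000.0
    inactivation_P1_duration: float = 5000.0
    inactivation_P2_duration: float = 1000.0
    inactivation_P2_V: float = 50.0
    recovery_P1_duration: float = 5000.0
    recovery_P2_duration: float = 1000.0
    recovery_V: float = 50.0
    delta_t_grid: list[float] | None = None   # default: 20 log-spaced, 10..1e4 ms
    output_dt: float = Field(default=1.0, gt=0)
    normalization: str = "max_sweep"

    def to_spec(self) -> ProtocolSpec:
        return ProtocolSpec(
            V_hold=self.V_hold,
            V_steps=tuple(self.V_steps if self.V_steps is not None
                          else default_voltage_steps()),
            activation_duration=self.activation_duration,
            inactivation_P1_duration=self.inactivation_P1_duration,
            inactivation_P2_duration=self.inactivation_P2_duration,
            inactivation_P2_V=self.inactivation_P2_V,
            recovery_P1_duration=self.recovery_P1_duration,
            recovery_P2_duration=self.recovery_P2_duration,
            recovery_V=self.recovery_V,
            delta_t_grid=tuple(self.delta_t_grid if self.delta_t_grid is not None
                               else default_delta_t_grid()),
            output_dt=self.output_dt,
        )


class SolverConfig(_Strict):
    backend: str = "expm"
    rtol: float = 1e-8
    atol: float = 1e-10

    @model_validator(mode="after")
    def _check_backend(self):
        if self.backend not in ("expm", "ivp"):
            raise ValueError(f"solver.backend must be 'expm' or 'ivp', got {self.backend!r}")
        return self


class FitConfig(_Strict):
    free: list[str] = Field(default_factory=lambda: list(PARAM_NAMES))
    fixed: dict[str, float] = Field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_BOUNDS.items()})
    weights: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    maxiter: int = 80
    popsize: int = 12
    tol: float = 1e-8
    polish: bool = True
    n_polish: int = 24
    n_islands: int = 2
    max_evaluations: int | None = None

    def to_spec(self, seed: int, protocol: ProtocolSpec) -> FitSpec:
        return FitSpec(
            free=tuple(self.free),
            fixed=dict(self.fixed),
            bounds={k: tuple(v) for k, v in self.bounds.items()},
            weights=dict(self.weights),
            seed=seed,
            maxiter=self.maxiter,
            popsize=self.popsize,
            tol=self.tol,
            polish=self.polish,
            n_polish=self.n_polish,
            n_islands=self.n_islands,
            max_evaluations=self.max_evaluations,
            protocol=protocol,
        )


class RunConfig(_Strict):
    """Everything needed to reproduce one run (plus the seed)."""

    family: str
    inactivating: int = 0
    fixture: str | None = None
    rates: dict | None = None          # inline rate laws, same shape as fixtures
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    reduction: str | None = None       # 'qss' or 'manifold'
    fit: FitConfig | None = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.family not in ("plain", "n_type", "c_type"):
            raise ValueError(f"family must be plain/n_type/c_type, got {self.family!r}")
        if self.fixture is None and self.rates is None:
            raise ValueError("one of 'fixture' or 'rates' is required")
        if self.fixture is not None and self.rates is not None:
            raise ValueError("'fixture' and 'rates' are mutually exclusive")
        if self.reduction not in (None, "qss", "manifold"):
            raise ValueError(f"reduction must be 'qss' or 'manifold', got {self.reduction!r}")
        if self.protocol.normalization not in ("max_sweep", "per_sweep"):
            raise ValueError("protocol.normalization must be 'max_sweep' or 'per_sweep'")
        self.composition()  # tetramer validity
        return self

    def composition(self) -> ChannelComposition:
        try:
            return composition_from_family(self.family, self.inactivating)
        except ValueError as exc:
            raise ConfigError(f"inactivating: {exc}") from exc

    def subunit_rates(self) -> SubunitRates:
        if self.fixture is not None:
            return load_fixture(self.fixture).rates
        return _rates_from_mapping(self.rates)

    def protocol_spec(self) -> ProtocolSpec:
        return self.protocol.to_spec()

    def fit_spec(self) -> FitSpec | None:
        if self.fit is None:
            return None
        return self.fit.to_spec(self.seed, self.protocol_spec())

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(exclude_none=True, mode="json"),
                              sort_keys=False)

    def sha256(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


def _format_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(x) for x in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def parse_config(data: dict) -> RunConfig:
    """Validate a raw mapping into a RunConfig (unknown keys rejected)."""
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return parse_config(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(config.to_yaml())
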