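"""Scenario and experiment configuration.

A :class:`ScenarioConfig` fully parameterizes one simulation replication:
the signal factor (physicians on duty), the noise factor (daily arrival
rate), the four control-factor policies, resource counts, the triage mix,
per-station service-time distributions and the run horizon.  An
:class:`ExperimentConfig` wraps a base scenario together with the settings
of the downstream design, surrogate, optimizer and sensitivity stages.

Configuration files are YAML; unknown keys are rejected with the offending
key path so typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import yaml

from .errors import ConfigError, InvalidParameterError

__all__ = [
    "ServiceDist",
    "ScenarioConfig",
    "TaguchiSettings",
    "SurrogateSettings",
    "GASettings",
    "SensitivitySettings",
    "ExperimentConfig",
    "load_config",
    "PROFILES",
]

STATIONS = ("registration", "exam", "urine", "ct", "xray")
CHECKUP_ROOMS = ("urine", "ct", "xray")

#: Desk-scale vs full-scale run profiles (replications, horizon in days).
PROFILES = {
    "desk": {"replications": 20, "horizon_days": 3},
    "full": {"replications": 1000, "horizon_days": 7},
}


@dataclass(frozen=True)
class ServiceDist:
    """Service-time distribution for one station, in minutes.

    family ``lognormal`` takes ``mean``/``sd`` of the distribution itself,
    ``exponential`` takes ``mean``, ``deterministic`` takes ``value``.
    """

    family: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "exponential", "deterministic"):
            raise InvalidParameterError(f"unknown service distribution family {self.family!r}")
        needed = {
            "lognormal": ("mean", "sd"),
            "exponential": ("mean",),
            "deterministic": ("value",),
        }[self.family]
        for key in needed:
            if key not in self.params:
                raise InvalidParameterError(f"{self.family} distribution requires {key!r}")
            if self.params[key] < 0:
                raise InvalidParameterError(f"{self.family}.{key} must be >= 0")

    def mean(self) -> float:
        if self.family == "lognormal":
            return float(self.params["mean"])
        if self.family == "exponential":
            return float(self.params["mean"])
        return float(self.params["value"])

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "deterministic":
            return float(self.params["value"])
        if self.family == "exponential":
            m = float(self.params["mean"])
            return float(rng.exponential(m)) if m > 0 else 0.0
        m, s = float(self.params["mean"]), float(self.params["sd"])
        if m <= 0:
            return 0.0
        if s == 0:
            return m
        sigma2 = math.log(1.0 + (s / m) ** 2)
        mu = math.log(m) - 0.5 * sigma2
        return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _default_service_dists() -> dict[str, ServiceDist]:
    # Fixture defaults (the study hospital's times are unpublished): minutes,
    # mean +/- sd, balanced so that 1-2 physicians facing 350-425 arrivals/day
    # operate near the crowding boundary where the index thresholds matter.
    return {
        "registration": ServiceDist("lognormal", {"mean": 5.0, "sd": 2.0}),
        "exam": ServiceDist("lognormal", {"mean": 3.5, "sd": 2.0}),
        "urine": ServiceDist("lognormal", {"mean": 10.0, "sd": 5.0}),
        "ct": ServiceDist("lognormal", {"mean": 20.0, "sd": 10.0}),
        "xray": ServiceDist("lognormal", {"mean": 10.0, "sd": 4.0}),
    }


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one ED simulation replication."""

    signal_M: int = 2
    noise_lambda: float = 350.0
    factor_A: float = 1.0
    factor_B: int = 1
    factor_C: int = 1
    factor_D: int = 2
    beds_Bt: int = 30
    exam_rooms: Mapping[str, int] = field(
        default_factory=lambda: {"urine": 1, "ct": 1, "xray": 1}
    )
    registration_servers: int = 2
    triage_mix: tuple[float, ...] = (0.02, 0.08, 0.45, 0.35, 0.10)
    service_dists: Mapping[str, ServiceDist] = field(default_factory=_default_service_dists)
    # probability a patient needs each checkup room, and of admission by triage
    checkup_probs: Mapping[str, float] = field(
        default_factory=lambda: {"urine": 0.25, "ct": 0.12, "xray": 0.20}
    )
    admit_probs: tuple[float, ...] = (0.6, 0.4, 0.2, 0.08, 0.04)
    # competing (non-ED) demand on each exam room, jobs/day
    outpatient_rate_per_day: float = 20.0
    p_divert: float = 1.0
    prev_day_aggregation: str = "mean"  # or "max" / "last"
    # policy signal on day one (the ED never starts empty; the busy/crowded
    # boundary avoids a cold-start backlog artifact)
    initial_prev_day_edwinc: float = 2.0
    horizon_days: int = 7
    warmup_days: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal_M < 1:
            raise InvalidParameterError("signal_M (physicians) must be >= 1")
        if self.noise_lambda <= 0:
            raise InvalidParameterError("noise_lambda must be > 0")
        if not 1.0 <= self.factor_A <= 3.0:
            raise InvalidParameterError(f"factor_A must lie in [1, 3], got {self.factor_A}")
        for name in ("factor_B", "factor_C", "factor_D"):
            if getattr(self, name) not in (1, 2, 3):
                raise InvalidParameterError(f"{name} must be one of 1, 2, 3")
        if self.beds_Bt <= 0:
            raise InvalidParameterError("beds_Bt must be > 0")
        if self.registration_servers < 1:
            raise InvalidParameterError("registration_servers must be >= 1")
        for room in CHECKUP_ROOMS:
            if self.exam_rooms.get(room, 0) < 1:
                raise InvalidParameterError(f"exam_rooms[{room!r}] must be >= 1")
        mix = tuple(float(p) for p in self.triage_mix)
        if len(mix) != 5 or any(p < 0 for p in mix):
            raise InvalidParameterError("triage_mix must be 5 non-negative probabilities")
        if abs(sum(mix) - 1.0) > 1e-9:
            raise InvalidParameterError(f"triage_mix must sum to 1, got {sum(mix)}")
        object.__setattr__(self, "triage_mix", mix)
        for st in STATIONS:
            if st not in self.service_dists:
                raise InvalidParameterError(f"service_dists missing station {st!r}")
        if not 0.0 <= self.p_divert <= 1.0:
            raise InvalidParameterError("p_divert must lie in [0, 1]")
        if len(self.admit_probs) != 5 or any(not 0 <= p <= 1 for p in self.admit_probs):
            raise InvalidParameterError("admit_probs must be 5 probabilities")
        for room, p in self.checkup_probs.items():
            if room not in CHECKUP_ROOMS or not 0 <= p <= 1:
                raise InvalidParameterError(f"checkup_probs[{room!r}] invalid")
        if self.outpatient_rate_per_day < 0:
            raise InvalidParameterError("outpatient_rate_per_day must be >= 0")
        if self.prev_day_aggregation not in ("mean", "max", "last"):
            raise InvalidParameterError("prev_day_aggregation must be mean, max or last")
        if self.initial_prev_day_edwinc < 0:
            raise InvalidParameterError("initial_prev_day_edwinc must be >= 0")
        if self.horizon_days < 1:
            raise InvalidParameterError("horizon_days must be >= 1")
        if self.warmup_days < 0 or self.warmup_days >= self.horizon_days:
            raise InvalidParameterError("warmup_days must be in [0, horizon_days)")

    def replace(self, **kwargs: Any) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class TaguchiSettings:
    signal_levels: tuple[int, int] = (1, 2)
    noise_levels: tuple[float, float] = (350.0, 425.0)
    replications: int = 1000
    sn_variant: str = "beta"  # 10*log10(beta/MSE); or "conventional" (beta^2/MSE)
    mse_ddof: int = 1
    pool_noise: bool = True

    def __post_init__(self) -> None:
        if self.sn_variant not in ("beta", "conventional"):
            raise InvalidParameterError("sn_variant must be 'beta' or 'conventional'")
        if self.mse_ddof not in (0, 1):
            raise InvalidParameterError("mse_ddof must be 0 or 1")
        if self.replications < 1:
            raise InvalidParameterError("replications must be >= 1")


@dataclass(frozen=True)
class SurrogateSettings:
    hidden_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    iterations: int = 10_000
    momentum: float = 0.65
    lr_min: float = 0.01
    lr_max: float = 0.5
    train_fraction: float = 0.8
    edwinc_orientation: str = "ltb"  # larger-the-better ramp; "stb" flips it
    bounds_margin: float = 0.0

    def __post_init__(self) -> None:
        if not self.hidden_range or any(h < 1 for h in self.hidden_range):
            raise InvalidParameterError("hidden_range must be positive integers")
        if not 0.0 < self.train_fraction < 1.0:
            raise InvalidParameterError("train_fraction must lie in (0, 1)")
        if self.edwinc_orientation not in ("ltb", "stb"):
            raise InvalidParameterError("edwinc_orientation must be 'ltb' or 'stb'")
        if not 0 < self.lr_min <= self.lr_max:
            raise InvalidParameterError("need 0 < lr_min <= lr_max")


@dataclass(frozen=True)
class GASettings:
    generations: int = 1000
    population: int = 80
    crossover_rate: float = 0.5
    mutation_rate: float = 0.08
    aggregation: str = "mean"  # over the four (signal, noise) combinations

    def __post_init__(self) -> None:
        if self.generations < 1 or self.population < 2:
            raise InvalidParameterError("generations >= 1 and population >= 2 required")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1]")
        if self.aggregation not in ("mean", "worst", "nominal"):
            raise InvalidParameterError("aggregation must be mean, worst or nominal")


@dataclass(frozen=True)
class SensitivitySettings:
    factor_a_grid: tuple[float, ...] = tuple(round(1.0 + 0.2 * i, 1) for i in range(11))


@dataclass(frozen=True)
class ExperimentConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    taguchi: TaguchiSettings = field(default_factory=TaguchiSettings)
    surrogate: SurrogateSettings = field(default_factory=SurrogateSettings)
    ga: GASettings = field(default_factory=GASettings)
    sensitivity: SensitivitySettings = field(default_factory=SensitivitySettings)
    profile: str = "desk"

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise InvalidParameterError(f"profile must be one of {sorted(PROFILES)}")

    def resolved(self) -> "ExperimentConfig":
        """Apply the run profile's replications/horizon to scenario + design."""
        prof = PROFILES[self.profile]
        scen = self.scenario.replace(horizon_days=prof["horizon_days"])
        tag = dataclasses.replace(self.taguchi, replications=prof["replications"])
        return dataclasses.replace(self, scenario=scen, taguchi=tag)


# ---------------------------------------------------------------------------
# YAML loading


def _build_dataclass(cls, data: Mapping[str, Any], path: str):
    field_names = {f.name for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key not in field_names:
            raise ConfigError(f"unknown key {path}{key!r}")
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except InvalidParameterError as exc:
        raise ConfigError(f"{path[:-1] or 'config'}: {exc}") from exc


def _parse_service_dists(data: Mapping[str, Any]) -> dict[str, ServiceDist]:
    defaults = _default_service_dists()
    for station, spec in data.items():
        if station not in STATIONS:
            raise ConfigError(f"unknown key scenario.service_dists.{station!r}")
        if not isinstance(spec, Mapping) or "family" not in spec:
            raise ConfigError(f"scenario.service_dists.{station}: need a 'family' mapping")
        params = {k: v for k, v in spec.items() if k != "family"}
        try:
            defaults[station] = ServiceDist(spec["family"], params)
        except InvalidParameterError as exc:
            raise ConfigError(f"scenario.service_dists.{station}: {exc}") from exc
    return defaults


def load_config(path: str | None = None, overrides: Mapping[str, Any] | None = None) -> ExperimentConfig:
    """Load and validate an experiment configuration.

    An empty or absent file yields the package defaults, which are the
    published study settings: signal levels {1, 2} physicians, noise rates
    {350, 425} patients/day, GA 1000 generations / population 80 /
    crossover 0.5 / mutation 0.08, NN momentum 0.65 with learning rate in
    [0.01, 0.5] for 10,000 iterations.

    ``overrides`` is a flat mapping of dotted key paths (e.g.
    ``{"scenario.seed": 7}``) applied after the file is read.
    """
    data: dict[str, Any] = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ConfigError("top level of the config file must be a mapping")
        data = dict(loaded)

    for dotted, value in (overrides or {}).items():
        cursor = data
        parts = dotted.split(".")
        for part in parts[:-1]:
            cursor = cursor.setdefault(part, {})
        cursor[parts[-1]] = value

    known_sections = {"scenario", "taguchi", "surrogate", "ga", "sensitivity", "profile"}
    for key in data:
        if key not in known_sections:
            raise ConfigError(f"unknown key {key!r}")

    scen_data = dict(data.get("scenario", {}) or {})
    service_dists = _parse_service_dists(scen_data.pop("service_dists", {}) or {})
    if "triage_mix" in scen_data:
        scen_data["triage_mix"] = tuple(scen_data["triage_mix"])
    if "admit_probs" in scen_data:
        scen_data["admit_probs"] = tuple(scen_data["admit_probs"])
    scen_data["service_dists"] = service_dists
    scenario = _build_dataclass(ScenarioConfig, scen_data, "scenario.")

    tag_data = dict(data.get("taguchi", {}) or {})
    for key in ("signal_levels", "noise_levels"):
        if key in tag_data:
            tag_data[key] = tuple(tag_data[key])
    taguchi = _build_dataclass(TaguchiSettings, tag_data, "taguchi.")

    sur_data = dict(data.get("surrogate", {}) or {})
    if "hidden_range" in sur_data:
        sur_data["hidden_range"] = tuple(sur_data["hidden_range"])
    surrogate = _build_dataclass(SurrogateSettings, sur_data, "surrogate.")
    ga = _build_dataclass(GASettings, dict(data.get("ga", {}) or {}), "ga.")

    sens_data = dict(data.get("sensitivity", {}) or {})
    if "factor_a_grid" in sens_data:
        sens_data["factor_a_grid"] = tuple(sens_data["factor_a_grid"])
    sensitivity = _build_dataclass(SensitivitySettings, sens_data, "sensitivity.")

    try:
        return ExperimentConfig(
            scenario=scenario,
            taguchi=taguchi,
            surrogate=surrogate,
            ga=ga,
            sensitivity=sensitivity,
            profile=data.get("profile", "desk"),
        )
    except InvalidParameterError as exc:
        raise ConfigError(str(exc)) from exc
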