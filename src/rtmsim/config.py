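"""Schema-validated run configuration (YAML or JSON).

A single master seed in the config fully determines every source of
randomness in a run; no operation consults the wall clock or environment.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .agents import AgentProfile
from .trial import TrialDesign


class ConfigError(ValueError):
    """Raised with a field-level message for invalid run configs."""


class EngineBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mode: str = "closed_loop"
    open_interval_min: float = 10.0
    countdown_min: float = 2.0
    vibration_on_s: float = 2.0
    vibration_off_s: float = 2.0
    open_loop_anchor: str = "fixed"


class AgentBlock(BaseModel):
    """Overrides applied to every subject's behavior profile."""

    model_config = ConfigDict(extra="forbid")

    rest_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    affected_ratio: float | None = Field(default=None, gt=0.0, le=1.0)
    p_respond: float = Field(default=0.8, ge=0.0, le=1.0)
    motivation_halflife_days: float = Field(default=7.0, gt=0.0)
    habit_gain: float = Field(default=0.03, ge=0.0)
    bout_mean_s: float = Field(default=60.0, gt=0.0)
    unaffected_intensity: float = Field(default=0.6, ge=0.0, le=1.0)
    exercise_intensity: float = Field(default=0.9, ge=0.0, le=1.0)
    ack_delay_median_s: float = Field(default=2.0, ge=0.0)
    ack_delay_sigma: float = Field(default=0.5, ge=0.0)


class TrialBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_per_group: int = Field(default=8, ge=1)
    days: int = 14
    session_hours: float = Field(default=3.0, gt=0.0)
    open_interval_min: float = Field(default=10.0, gt=0.0)
    countdown_lower_min: float = Field(default=2.0, gt=0.0)
    countdown_higher_min: float = Field(default=5.0, gt=0.0)
    retention_closed: float = Field(default=1.0, ge=0.0)
    retention_open: float = Field(default=0.5, ge=0.0)
    effect_per_1k: float = 0.15
    score_noise_sd: float = Field(default=1.0, ge=0.0)


class StatsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    holm: bool = False


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    trial: TrialBlock = Field(default_factory=TrialBlock)
    agent: AgentBlock = Field(default_factory=AgentBlock)
    stats: StatsBlock = Field(default_factory=StatsBlock)
    write_epoch_logs: bool = False
    write_raw_samples: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        try:
            payload = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
        try:
            return cls.model_validate(payload)
        except ValidationError as exc:
            fields = "; ".join(
                f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
                for err in exc.errors()
            )
            raise ConfigError(f"{path}: invalid config: {fields}") from exc

    def to_design(self) -> TrialDesign:
        t = self.trial
        return TrialDesign(
            n_per_group=t.n_per_group,
            days=t.days,
            session_hours=t.session_hours,
            open_interval_min=t.open_interval_min,
            countdown_by_functioning={
                "lower": t.countdown_lower_min,
                "higher": t.countdown_higher_min,
            },
            retention={
                "closed_loop": t.retention_closed,
                "open_loop": t.retention_open,
            },
            effect_per_1k=t.effect_per_1k,
            score_noise_sd=t.score_noise_sd,
            seed=self.seed,
        )

    def profile_overrides(self) -> dict:
        return self.agent.model_dump()


def default_config_yaml() -> str:
    """The full default configuration, as YAML (for --show-defaults)."""
    cfg = RunConfig()
    return yaml.safe_dump(cfg.model_dump(), sort_keys=False)


def default_profile() -> AgentProfile:
    return AgentProfile()
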