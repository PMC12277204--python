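"""Two-arm, 14-day proof-of-concept trial simulator.

Sixteen synthetic community-dwelling stroke survivors (default), stratified
by upper-limb functioning (FTHUE 3-4 lower / >= 5 higher), are randomized to
an open-loop or closed-loop cueing device, wear it 3 waking hours a day for
14 days in co-simulation with their behavior agent, and contribute abstract
clinical outcome scores at pretest, posttest and 4-week follow-up.

The clinical-score generator is a synthetic linear latent-mediator model:
each subject's score gain is proportional to their achieved
movement-frequency gain plus noise. It makes no claim about real clinical
instruments — it exists so the statistics pipeline receives clinical and
kinematic outcomes that are coherently coupled.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accelerometry import DesignError, DeviceLog, KinematicOutcomes, trial_kinematic_outcomes
from .agents import AgentProfile, generate_day
from .engines import CueEvent, EngineConfig, Mode

ARMS = ("open_loop", "closed_loop")

#: Abstract stand-ins for the trial's clinical instruments, as
#: (name, baseline mean, baseline sd). Scores are unbounded synthetic
#: scales, not item-level simulations of the real instruments.
DEFAULT_MEASURES: tuple[tuple[str, float, float], ...] = (
    ("FMA_UE_total", 30.0, 8.0),
    ("FMA_UE_upper", 20.0, 6.0),
    ("FMA_UE_hand", 10.0, 3.0),
    ("ARAT", 25.0, 8.0),
    ("MAL_AOU", 1.5, 0.5),
    ("MAL_QOM", 1.5, 0.5),
)


@dataclass(frozen=True)
class TrialDesign:
    """Design constants of the dosing trial.

    ``countdown_by_functioning`` fixes the closed-loop preset per stratum
    (2 min lower, 5 min higher); ``retention`` scales how much of the latent
    training gain persists to the 4-week follow-up per arm;
    ``effect_per_1k`` converts a movement-frequency gain of 1000 counts into
    clinical score points (per unit of a measure's baseline sd).
    """

    n_per_group: int = 8
    days: int = 14
    session_hours: float = 3.0
    open_interval_min: float = 10.0
    countdown_by_functioning: dict = field(
        default_factory=lambda: {"lower": 2.0, "higher": 5.0}
    )
    retention: dict = field(
        default_factory=lambda: {"closed_loop": 1.0, "open_loop": 0.5}
    )
    effect_per_1k: float = 0.15
    score_noise_sd: float = 1.0
    measures: tuple = DEFAULT_MEASURES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise DesignError("n_per_group must be >= 1")
        if self.days != 14:
            raise DesignError("the intervention is 14 days by design")

    def engine_for(self, arm: str, functioning: str) -> EngineConfig:
        """The device configuration a subject in this arm/stratum wears."""
        if arm == "open_loop":
            return EngineConfig(mode=Mode.OPEN_LOOP,
                                open_interval_min=self.open_interval_min)
        return EngineConfig(
            mode=Mode.CLOSED_LOOP,
            countdown_min=self.countdown_by_functioning[functioning],
        )


@dataclass
class Subject:
    """One enrolled synthetic participant (pre-allocation)."""

    subject_id: str
    fthue_level: int
    age: float
    onset_months: float
    profile: AgentProfile

    @property
    def functioning(self) -> str:
        return "lower" if self.fthue_level <= 4 else "higher"


@dataclass
class SubjectRecord:
    """A subject's complete trial output."""

    subject: Subject
    group: str
    logs: list[DeviceLog]
    kinematics: KinematicOutcomes
    scores: dict  # measure -> {timepoint -> value}
    cue_events: list[CueEvent] = field(default_factory=list)


@dataclass
class TrialResult:
    subjects: list[SubjectRecord]
    outcome_table: pd.DataFrame
    daily_counts: pd.DataFrame
    manifest: dict


def make_subject_pool(design: TrialDesign, seed: int | None = None,
                      **profile_overrides) -> list[Subject]:
    """Draw a balanced pool of 2 x n_per_group subjects (half per stratum).

    Ages ~ N(60, 10) years, onset-to-treatment lognormal with median 18
    months; FTHUE levels uniform on {3, 4} (lower) or {5, 6, 7} (higher).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n_total = 2 * design.n_per_group
    n_lower = n_total // 2
    subjects = []
    for i in range(n_total):
        lower = i < n_lower
        fthue = int(rng.integers(3, 5)) if lower else int(rng.integers(5, 8))
        subjects.append(
            Subject(
                subject_id=f"S{i + 1:02d}",
                fthue_level=fthue,
                age=float(np.clip(rng.normal(60.0, 10.0), 30.0, 90.0)),
                onset_months=float(np.exp(rng.normal(np.log(18.0), 0.5))),
                profile=AgentProfile(fthue_level=fthue, **profile_overrides),
            )
        )
    return subjects


def allocate(design: TrialDesign, pool: list[Subject],
             seed: int | None = None) -> dict[str, str]:
    """Permuted-block randomization within functioning strata.

    Within each stratum, subjects are shuffled and assigned in blocks of
    two (one per arm in random order), so arms differ by at most one
    subject per stratum; an odd stratum triggers an imbalance warning.
    """
    if len(pool) != 2 * design.n_per_group:
        raise DesignError(
            f"pool size {len(pool)} != 2 x n_per_group = {2 * design.n_per_group}"
        )
    rng = np.random.default_rng(design.seed if seed is None else seed)
    assignment: dict[str, str] = {}
    for stratum in ("lower", "higher"):
        members = [s for s in pool if s.functioning == stratum]
        if len(members) % 2:
            warnings.warn(
                f"odd stratum size {len(members)} for {stratum!r}: arms will "
                "differ by one subject",
                UserWarning,
                stacklevel=2,
            )
        order = rng.permutation(len(members))
        for block_start in range(0, len(members), 2):
            block = order[block_start:block_start + 2]
            arms = list(ARMS)
            rng.shuffle(arms)
            for subj_idx, arm in zip(block, arms):
                assignment[members[subj_idx].subject_id] = arm
    return assignment


def run_trial(
    design: TrialDesign,
    pool: list[Subject] | None = None,
    seed: int | None = None,
    sample_writer=None,
    log_writer=None,
) -> TrialResult:
    """Run the full trial: allocation, 14 co-simulated days per subject,
    kinematic outcomes, and synthetic clinical scores at three timepoints.

    Deterministic in (design, pool, seed): the same inputs reproduce the
    outcome table byte for byte. ``sample_writer(subject_id, day, samples)``
    and ``log_writer(device_log)``, when given, stream raw 5 Hz traces and
    per-day epoch logs to disk as they are produced (they are not kept in
    memory); sample synthesis consumes no randomness, so outputs are
    identical with or without writers.
    """
    master = design.seed if seed is None else seed
    rng = np.random.default_rng(master)
    if pool is None:
        pool = make_subject_pool(design, seed=int(rng.integers(2**31)))
    if len(pool) != 2 * design.n_per_group:
        raise DesignError("one profile per subject required: pool/design mismatch")
    assignment = allocate(design, pool, seed=int(rng.integers(2**31)))

    records: list[SubjectRecord] = []
    rows = []
    daily_rows = []
    for subject in pool:
        arm = assignment[subject.subject_id]
        engine = design.engine_for(arm, subject.functioning)
        subj_rng = np.random.default_rng(
            [master, zlib.crc32(subject.subject_id.encode()) % (2**31)]
        )
        logs: list[DeviceLog] = []
        all_events: list[CueEvent] = []
        for day in range(1, design.days + 1):
            sim = generate_day(
                subject.profile,
                day,
                engine,
                subj_rng,
                session_hours=design.session_hours,
                synthesize_samples=sample_writer is not None,
            )
            if sample_writer is not None:
                sample_writer(subject.subject_id, day, sim.samples)
                sim.samples = None
            logs.append(
                DeviceLog(
                    subject_id=subject.subject_id,
                    day=day,
                    epochs=sim.epochs,
                    cue_events=sim.cue_events,
                    group=arm,
                    fthue_level=subject.fthue_level,
                    threshold=subject.profile.threshold.x,
                    session_hours=design.session_hours,
                )
            )
            if log_writer is not None:
                log_writer(logs[-1])
            all_events.extend(sim.cue_events)
        kin = trial_kinematic_outcomes(logs)
        for day, count in enumerate(kin.daily_counts, start=1):
            daily_rows.append(
                {"subject_id": subject.subject_id, "group": arm,
                 "day": day, "count": count}
            )

        # synthetic clinical scores: latent training gain proportional to the
        # achieved movement-frequency gain, scaled per measure by baseline sd
        latent = design.effect_per_1k * kin.gain_f3l3 / 1000.0
        retention = design.retention[arm]
        scores: dict = {}
        for name, mean, sd in design.measures:
            pre = float(rng.normal(mean, sd))
            post = pre + sd * latent + float(rng.normal(0.0, design.score_noise_sd))
            fu = pre + sd * retention * latent + float(
                rng.normal(0.0, design.score_noise_sd)
            )
            scores[name] = {"pretest": pre, "posttest": post, "follow_up": fu}
            for tp, val in scores[name].items():
                rows.append(
                    {
                        "subject_id": subject.subject_id,
                        "group": arm,
                        "fthue_level": subject.fthue_level,
                        "age": subject.age,
                        "onset_months": subject.onset_months,
                        "timepoint": tp,
                        "measure": name,
                        "value": val,
                    }
                )
        records.append(
            SubjectRecord(subject=subject, group=arm, logs=logs,
                          kinematics=kin, scores=scores, cue_events=all_events)
        )

    outcome_table = pd.DataFrame(rows)
    daily_counts = pd.DataFrame(daily_rows)
    manifest = {
        "seed": master,
        "n_per_group": design.n_per_group,
        "days": design.days,
        "session_hours": design.session_hours,
        "arms": list(ARMS),
        "allocation": assignment,
        "engines": {
            s.subject_id: {
                "mode": assignment[s.subject_id],
                "countdown_min": (
                    design.countdown_by_functioning[s.functioning]
                    if assignment[s.subject_id] == "closed_loop"
                    else None
                ),
                "open_interval_min": (
                    design.open_interval_min
                    if assignment[s.subject_id] == "open_loop"
                    else None
                ),
            }
            for s in pool
        },
    }
    return TrialResult(
        subjects=records,
        outcome_table=outcome_table,
        daily_counts=daily_counts,
        manifest=manifest,
    )
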