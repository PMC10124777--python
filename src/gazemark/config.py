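"""Configuration models for the simulator and the analysis pipeline.

All user-facing quantities are on interpretable scales: percentages 0-100,
milliseconds, pixels, visual degrees.  Internal logit-scale generative
parameters are derived from these targets at run time (see
:mod:`gazemark.calibrate`).
"""

from __future__ import annotations

import hashlib
import json
from enum import Enum
from typing import Dict, List, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field, model_validator


class Task(str, Enum):
    """Battery task codes."""

    AM = "AM"    #: activity monitoring (adults engaged in a shared activity)
    SI = "SI"    #: social interactive (children playing)
    SS = "SS"    #: static social scenes (repeated, mirrored on day 2)
    BM = "BM"    #: biological-motion preference (side-by-side point lights)
    PLR = "PLR"  #: pupillary light reflex (dark screen + white flash)
    VAL = "VAL"  #: validation-target presentations (calibration-error probes)


#: tasks whose %Face values are averaged into the face-gaze composite (OMI)
FACE_TASKS: Tuple[Task, ...] = (Task.AM, Task.SI, Task.SS)
#: tasks a trial plan must cover
REQUIRED_TASKS: Tuple[Task, ...] = (Task.AM, Task.SI, Task.SS, Task.BM, Task.PLR)

ASD = "ASD"
TD = "TD"
GROUPS = (ASD, TD)


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration."""


class Screen(BaseModel):
    model_config = ConfigDict(extra="forbid")

    width_px: int = Field(default=1920, gt=0)
    height_px: int = Field(default=1200, gt=0)
    px_per_degree: float = Field(default=42.0, gt=0)


class TrialBlock(BaseModel):
    """A homogeneous block of trials of one task on one day."""

    model_config = ConfigDict(extra="forbid")

    task: Task
    n_trials: int = Field(gt=0)
    duration_s: float = Field(gt=0)
    day: int = Field(ge=1, le=2)
    tag: str = ""


class PlrShape(BaseModel):
    """Shape and noise parameters of simulated pupil-flash responses."""

    model_config = ConfigDict(extra="forbid")

    tau_ms: float = Field(default=120.0, gt=0)
    flash_ms: float = Field(default=1000.0, gt=0)
    trial_duration_ms: float = Field(default=3500.0, gt=0)
    baseline_au: float = Field(default=1000.0, gt=0)
    baseline_sd_au: float = Field(default=80.0, ge=0)
    noise_frac: float = Field(default=0.001, ge=0)
    trial_jitter_sd_ms: float = Field(default=8.0, ge=0)
    blink_rate: float = Field(default=0.10, ge=0, le=1)
    blink_duration_ms: float = Field(default=150.0, gt=0)

    @model_validator(mode="after")
    def _window(self) -> "PlrShape":
        if self.trial_duration_ms < self.flash_ms + 2000.0:
            raise ConfigError(
                "PLR trial must cover baseline plus at least 2 s post-flash"
            )
        return self


class GroupParams(BaseModel):
    """Per-diagnostic-group generative targets.

    Percent-scale gaze targets are *realized* targets: the simulator solves
    for logit-scale parameters such that the generated per-participant task
    means match these first two moments.
    """

    model_config = ConfigDict(extra="forbid")

    face_pct_targets: Dict[Task, Tuple[float, float]]
    bio_pct_target: Tuple[float, float]
    omi_sd_target: float = Field(gt=0)
    dropout_rate_mean: float = Field(ge=0, le=1)
    dropout_rate_sd: float = Field(ge=0)
    bad_trial_rate: float = Field(ge=0, le=1)
    cal_error_mean_deg: float = Field(ge=0)
    plr_latency_mean_ms: float = Field(gt=0)
    plr_latency_sd_ms: float = Field(ge=0)
    plr_constriction_mean: float = Field(gt=0, lt=1)
    plr_constriction_sd: float = Field(ge=0)
    iq_mean: float
    iq_sd: float = Field(ge=0)
    iq_bounds: Tuple[float, float]

    @model_validator(mode="after")
    def _check_targets(self) -> "GroupParams":
        missing = [t for t in FACE_TASKS if t not in self.face_pct_targets]
        if missing:
            raise ConfigError(f"face_pct_targets missing tasks: {missing}")
        for task, (m, s) in self.face_pct_targets.items():
            if not (0 < m < 100) or s <= 0:
                raise ConfigError(f"invalid face target for {task}: ({m}, {s})")
        m, s = self.bio_pct_target
        if not (0 < m < 100) or s <= 0:
            raise ConfigError(f"invalid bio target: ({m}, {s})")
        return self


class ScoreSpec(BaseModel):
    """A clinical/behavioural score column coupled to the face latent.

    ``rho_target`` is the target population Spearman correlation between the
    score and the realized face-gaze composite within a group.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    rho_target: float
    mean: Dict[str, float]
    sd: Dict[str, float]
    integer: bool = True
    bounds: Optional[Tuple[float, float]] = None

    @model_validator(mode="after")
    def _check(self) -> "ScoreSpec":
        if not -1 < self.rho_target < 1:
            raise ConfigError(f"|rho_target| must be < 1 for score {self.name!r}")
        for g in GROUPS:
            if g not in self.mean or g not in self.sd:
                raise ConfigError(f"score {self.name!r} missing stats for group {g}")
        return self


def default_trial_plan() -> List[TrialBlock]:
    """Two-day battery plan: both days carry every task; day-2 static scenes
    are horizontally mirrored (handled by the ROI layout, not the plan)."""
    plan: List[TrialBlock] = []
    for day in (1, 2):
        plan += [
            TrialBlock(task=Task.AM, n_trials=8, duration_s=10, day=day, tag="static"),
            TrialBlock(task=Task.AM, n_trials=8, duration_s=20, day=day, tag="video"),
            TrialBlock(task=Task.SI, n_trials=11, duration_s=15, day=day),
            TrialBlock(task=Task.SS, n_trials=6, duration_s=20, day=day),
            TrialBlock(task=Task.BM, n_trials=20, duration_s=10, day=day),
            TrialBlock(task=Task.PLR, n_trials=9, duration_s=3.5, day=day),
        ]
    return plan


def _default_groups() -> Dict[str, GroupParams]:
    return {
        ASD: GroupParams(
            face_pct_targets={
                Task.AM: (18.7, 8.7),
                Task.SI: (24.2, 10.7),
                Task.SS: (29.9, 9.8),
            },
            bio_pct_target=(53.4, 6.8),
            omi_sd_target=8.5,
            dropout_rate_mean=0.10,
            dropout_rate_sd=0.12,
            bad_trial_rate=0.06,
            cal_error_mean_deg=0.607,
            plr_latency_mean_ms=285.0,
            plr_latency_sd_ms=15.0,
            plr_constriction_mean=0.505,
            plr_constriction_sd=0.074,
            iq_mean=96.58,
            iq_sd=18.11,
            iq_bounds=(60.0, 150.0),
        ),
        TD: GroupParams(
            face_pct_targets={
                Task.AM: (27.6, 8.5),
                Task.SI: (30.4, 9.6),
                Task.SS: (34.9, 8.0),
            },
            bio_pct_target=(54.8, 6.1),
            omi_sd_target=7.6,
            dropout_rate_mean=0.05,
            dropout_rate_sd=0.08,
            bad_trial_rate=0.04,
            cal_error_mean_deg=0.534,
            plr_latency_mean_ms=279.0,
            plr_latency_sd_ms=15.0,
            plr_constriction_mean=0.505,
            plr_constriction_sd=0.074,
            iq_mean=115.12,
            iq_sd=12.55,
            iq_bounds=(80.0, 150.0),
        ),
    }


def _default_scores() -> List[ScoreSpec]:
    return [
        ScoreSpec(
            name="iq",
            rho_target=0.123,
            mean={ASD: 96.58, TD: 115.12},
            sd={ASD: 18.11, TD: 12.55},
            bounds=(60, 150),
        ),
        ScoreSpec(
            name="verbal_iq",
            rho_target=0.183,
            mean={ASD: 95.95, TD: 116.27},
            sd={ASD: 20.69, TD: 11.22},
            bounds=(20, 160),
        ),
        ScoreSpec(
            name="face_memory_ss",
            rho_target=0.316,
            mean={ASD: 7.86, TD: 10.53},
            sd={ASD: 3.67, TD: 3.49},
            bounds=(1, 19),
        ),
        ScoreSpec(
            name="ados_sa",
            rho_target=-0.165,
            mean={ASD: 7.34, TD: 1.91},
            sd={ASD: 1.79, TD: 1.34},
            bounds=(1, 10),
        ),
        ScoreSpec(
            name="vabs3_com_ss",
            rho_target=0.182,
            mean={ASD: 76.44, TD: 103.44},
            sd={ASD: 15.07, TD: 9.16},
            bounds=(20, 140),
        ),
        ScoreSpec(
            name="pddbi_reprit_t",
            rho_target=-0.238,
            mean={ASD: 49.6, TD: 28.03},
            sd={ASD: 11.52, TD: 2.61},
            bounds=(20, 90),
        ),
    ]


class SimulationConfig(BaseModel):
    """Full specification of a synthetic cohort.

    Identical configuration and seed produce bit-identical outputs.
    """

    model_config = ConfigDict(extra="forbid", validate_default=True)

    n_asd: int = Field(default=280, gt=0)
    n_td: int = Field(default=119, gt=0)
    seed: int = 0

    #: fraction of stable (trait) variance in the face/bio latents; this is
    #: the population intraclass correlation of the realized task means
    trait_variance_fraction: float = Field(default=0.836, ge=0, le=1)
    #: shared-across-task fraction of the face latent; None = solved from
    #: each group's omi_sd_target
    cross_task_corr: Optional[float] = Field(default=None, ge=0, le=1)
    #: relaxation time of the two-state in-face dwell process
    dwell_ms: float = Field(default=300.0, gt=0)
    #: optional extra per-trial jitter of the stationary probability (logit)
    trial_noise_sd: float = Field(default=0.0, ge=0)

    sample_rate_hz: float = Field(default=50.0, gt=0)
    plr_sample_rate_hz: float = Field(default=250.0, gt=0)

    screen: Screen = Field(default_factory=Screen)
    trial_plan: List[TrialBlock] = Field(default_factory=default_trial_plan)
    plr: PlrShape = Field(default_factory=PlrShape)
    groups: Dict[str, GroupParams] = Field(default_factory=_default_groups)
    scores: List[ScoreSpec] = Field(default_factory=_default_scores)

    #: scene area fraction occupied by the face region, per task (these are
    #: the chance levels used by the construct-validity tests)
    roi_area_fractions: Dict[Task, float] = Field(
        default_factory=lambda: {Task.AM: 0.032, Task.SI: 0.083, Task.SS: 0.039}
    )
    #: allocation of non-face gaze among secondary regions (rest = background)
    out_of_face_split: Dict[str, float] = Field(
        default_factory=lambda: {"activity": 0.35, "body": 0.25}
    )
    #: fraction of biological-motion trials carrying affective content
    bm_affective_fraction: float = Field(default=0.20, ge=0, le=1)

    n_sites: int = Field(default=5, gt=0)
    timepoints: Tuple[int, ...] = (1, 2)
    validation_trials_per_day: int = Field(default=3, ge=1)
    validation_duration_s: float = Field(default=1.0, gt=0)
    validation_jitter_deg: float = Field(default=0.15, ge=0)
    age_range_years: Tuple[float, float] = (6.0, 11.5)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        planned = {b.task for b in self.trial_plan}
        missing = [t.value for t in REQUIRED_TASKS if t not in planned]
        if missing:
            raise ConfigError(f"trial_plan missing required tasks: {missing}")
        for g in GROUPS:
            if g not in self.groups:
                raise ConfigError(f"groups must define parameters for {g}")
        split_total = sum(self.out_of_face_split.values())
        if split_total > 1:
            raise ConfigError("out_of_face_split fractions exceed 1")
        for t, frac in self.roi_area_fractions.items():
            if not 0 < frac < 1:
                raise ConfigError(f"roi_area_fractions[{t}] outside (0, 1)")
        if len(self.timepoints) not in (1, 2):
            raise ConfigError("timepoints must be (1,) or (1, 2)")
        return self

    def blocks_for(self, task: Task, day: Optional[int] = None) -> List[TrialBlock]:
        return [
            b
            for b in self.trial_plan
            if b.task == task and (day is None or b.day == day)
        ]

    def n_participants(self) -> int:
        return self.n_asd + self.n_td

    def config_hash(self) -> str:
        payload = self.model_dump_json()
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.model_dump(mode="json"), indent=indent, sort_keys=True)


class Thresholds(BaseModel):
    """Quality-control gates applied by the QC stage."""

    model_config = ConfigDict(extra="forbid")

    valid_data_pct: float = 50.0
    cal_error_deg: float = 2.5
    valid_trials_pct: float = 25.0
    benchmark_pct: float = 70.0
    plr_latency_window_ms: float = 1000.0


class RunConfig(BaseModel):
    """End-to-end pipeline run configuration (echoed into every output dir)."""

    model_config = ConfigDict(extra="forbid")

    outdir: str = "gazemark_out"
    seed: int = 0
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    thresholds: Thresholds = Field(default_factory=Thresholds)
    icc_variant: str = "absolute"
    covariates: List[str] = Field(
        default_factory=lambda: ["age_years", "iq", "site", "pct_valid_data"]
    )

    @model_validator(mode="after")
    def _sync_seed(self) -> "RunConfig":
        # single seed drives the whole run
        object.__setattr__(self.simulation, "seed", self.seed)
        if self.icc_variant not in ("absolute", "consistency"):
            raise ConfigError("icc_variant must be 'absolute' or 'consistency'")
        return self
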