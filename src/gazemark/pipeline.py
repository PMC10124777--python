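"""End-to-end orchestration: simulate -> derive -> qc -> psychometrics -> report.

``run_in_memory`` streams gaze one session at a time through the derivation
stage, so full-scale cohorts never hold the complete sample stream in memory;
``run_pipeline`` additionally writes every intermediate table so each number
in the reports is recomputable from the emitted CSVs alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, SimulationConfig, Thresholds
from .derive import derive_trials
from .io import write_json, write_table
from .psychometrics import PsychometricReport, evaluate
from .qc import (
    AcquisitionReport,
    acquisition_report,
    build_biomarker_table,
    compute_omi,
    gate_trials,
    summarize_task,
)
from .rois import BatterySpec
from .simulate import (
    CohortTables,
    ground_truth_table,
    iter_session_chunks,
    prepare_simulation,
    simulate_clinical_scores,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class PipelineBundle:
    """All participant-level products of one run."""

    config: SimulationConfig
    battery: BatterySpec
    trials: pd.DataFrame
    summaries: pd.DataFrame
    omi: pd.DataFrame
    biomarker_table: pd.DataFrame
    clinical: pd.DataFrame
    ground_truth: pd.DataFrame
    acquisition: AcquisitionReport
    psychometrics: Optional[PsychometricReport] = None
    row_counts: Dict[str, int] = field(default_factory=dict)


def run_in_memory(
    config: SimulationConfig,
    thresholds: Thresholds = Thresholds(),
    session_flags: Optional[pd.DataFrame] = None,
    keep_samples: bool = False,
    run_psychometrics: bool = True,
) -> PipelineBundle:
    """Simulate a cohort and push it through derivation, QC, and evaluation.

    Sample streams are discarded session by session unless ``keep_samples``.
    """
    try:
        calib, latents, battery, children = prepare_simulation(config)
        clinical = simulate_clinical_scores(
            latents, config, calib, np.random.default_rng(children[2])
        )
        ground_truth = ground_truth_table(latents, config)
    except Exception as err:
        raise PipelineError("simulate", err) from err

    trial_frames: List[pd.DataFrame] = []
    gaze_frames: List[pd.DataFrame] = []
    pupil_frames: List[pd.DataFrame] = []
    n_gaze = 0
    n_pupil = 0
    try:
        for tp, day, gaze, pupil in iter_session_chunks(
            config, calib, latents, battery, children[3:]
        ):
            n_gaze += len(gaze)
            n_pupil += len(pupil)
            trial_frames.append(derive_trials(gaze, pupil, battery))
            if keep_samples:
                gaze_frames.append(gaze)
                pupil_frames.append(pupil)
            logger.info("derived session t%s day %s", tp, day)
        trials = pd.concat(trial_frames, ignore_index=True)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError("derive", err) from err

    try:
        gated = gate_trials(trials, thresholds, session_flags)
        summaries = summarize_task(gated, thresholds)
        omi = compute_omi(summaries)
        table = build_biomarker_table(summaries, omi, clinical, gated)
        acquisition = acquisition_report(summaries, omi, clinical, thresholds)
    except Exception as err:
        raise PipelineError("qc", err) from err

    report = None
    if run_psychometrics:
        try:
            report = evaluate(table)
        except Exception as err:
            raise PipelineError("psychometrics", err) from err

    bundle = PipelineBundle(
        config=config,
        battery=battery,
        trials=gated,
        summaries=summaries,
        omi=omi,
        biomarker_table=table,
        clinical=clinical,
        ground_truth=ground_truth,
        acquisition=acquisition,
        psychometrics=report,
        row_counts={
            "gaze_samples": n_gaze,
            "pupil_samples": n_pupil,
            "trials": len(trials),
            "summaries": len(summaries),
            "participant_timepoints": len(table),
        },
    )
    if keep_samples:
        bundle.gaze = pd.concat(gaze_frames, ignore_index=True)  # type: ignore[attr-defined]
        bundle.pupil = pd.concat(pupil_frames, ignore_index=True)  # type: ignore[attr-defined]
    return bundle


def write_cohort(cohort: CohortTables, outdir) -> None:
    """Write a simulated cohort's raw tables (CSV + battery JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(cohort.gaze, out / "gaze.csv")
    write_table(cohort.pupil, out / "pupil.csv")
    write_table(cohort.clinical, out / "clinical.csv")
    write_table(cohort.ground_truth, out / "ground_truth.csv")
    cohort.battery.save(out / "battery_spec.json")
    (out / "sim_config.json").write_text(cohort.config.to_json())


def run_pipeline(run_config: RunConfig) -> Path:
    """Full file-based run; returns the output directory."""
    out = Path(run_config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        run_config.model_dump_json(indent=2)
    )

    bundle = run_in_memory(
        run_config.simulation,
        run_config.thresholds,
        keep_samples=True,
    )
    try:
        write_table(bundle.gaze, out / "gaze.csv")  # type: ignore[attr-defined]
        write_table(bundle.pupil, out / "pupil.csv")  # type: ignore[attr-defined]
        write_table(bundle.clinical, out / "clinical.csv")
        write_table(bundle.ground_truth, out / "ground_truth.csv")
        bundle.battery.save(out / "battery_spec.json")
        write_table(bundle.trials, out / "trials.csv")
        write_table(bundle.summaries, out / "summaries.csv")
        write_table(bundle.omi, out / "omi.csv")
        write_table(bundle.biomarker_table, out / "biomarker_table.csv")
        write_table(bundle.acquisition.table, out / "acquisition_table.csv")
        write_table(bundle.acquisition.group_tests, out / "acquisition_group_tests.csv")
        write_table(bundle.acquisition.site_tests, out / "acquisition_site_tests.csv")
        if bundle.psychometrics is not None:
            for name, df in bundle.psychometrics.tables().items():
                write_table(df, out / f"report_{name}.csv")
        write_json(
            {
                "package_version": __version__,
                "config_hash": run_config.simulation.config_hash(),
                "seed": run_config.seed,
                "row_counts": bundle.row_counts,
            },
            out / "provenance.json",
        )
    except Exception as err:
        raise PipelineError("report", err) from err
    return out
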