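"""Config-driven orchestration: manifest validation and the full pipeline.

``run_pipeline`` ties the stages together: preparation (FIR task
regression, demeaning, concatenation) -> FC estimation -> similarity
decomposition -> permutation inference, with optional per-ROI localization
and split-half reliability.  All randomness derives from a single master
seed; every tabular output is TSV and the run metadata (config echo, seed,
output checksums) is JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .cohort import SimulationConfig
from .connectivity import UnitMetadata, compute_fc, vectorize_upper
from .decomposition import decompose, filter_sample, roi_effect_magnitudes
from .inference import run_comparison_suite
from .prep import (
    DEFAULT_TASK_ORDER,
    build_fir_design,
    concatenate_runs,
    demean_timeseries,
    read_events,
    read_timeseries_file,
    regress_out_task,
)
from .reliability import mean_curve, split_half_curve

logger = logging.getLogger("fcdecomp")

MANIFEST_COLUMNS = (
    "subject_id", "session", "task", "path", "diagnosis", "sex", "responder", "site",
)


class ManifestError(ValueError):
    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("manifest validation failed:\n" + "\n".join(self.problems))


@dataclass
class RunConfig:
    out_dir: str | Path = "results"
    manifest: str | Path | None = None
    events_dir: str | Path | None = None
    sample: str = "all"
    mode: str = "pooled"  # "pooled" or "per-task"
    n_perm: int = 1000
    fdr_q: float = 0.05
    min_voxels: int = 1
    seed: int = 0
    fir_lag: int = 10
    include_within_individual_in_group_masks: bool = False
    simulation: SimulationConfig | None = None
    run_roi: bool = False
    run_reliability: bool = False
    reliability_lengths: tuple = (5, 10, 15, 20, 25, 30)

    def __post_init__(self):
        if self.sample not in ("controls", "patients", "all"):
            raise ValueError(f"unknown sample {self.sample!r}")
        if self.mode not in ("pooled", "per-task"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.manifest is None and self.simulation is None:
            raise ValueError("either a manifest path or a simulation block is required")


@dataclass
class ResultsBundle:
    effects: pd.DataFrame
    participant_effects: pd.DataFrame
    comparisons: pd.DataFrame
    roi_effects: pd.DataFrame | None = None
    reliability: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)


def validate_manifest(
    manifest: pd.DataFrame | str | Path,
    sessions: Sequence[str] = ("baseline", "week2", "week8"),
    tasks: Sequence[str] = DEFAULT_TASK_ORDER,
    base_dir: str | Path | None = None,
    check_files: bool = True,
) -> pd.DataFrame:
    """Check design completeness, label consistency and file existence.

    Every subject must have one row per session x task; labels (diagnosis,
    sex, responder, site) must agree across a subject's rows; paths must
    exist.  All problems are reported together in a ``ManifestError``.
    """
    if not isinstance(manifest, pd.DataFrame):
        base_dir = Path(manifest).parent if base_dir is None else Path(base_dir)
        manifest = pd.read_csv(manifest)
    problems: list[str] = []
    missing_cols = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing_cols:
        raise ManifestError([f"missing columns: {sorted(missing_cols)}"])
    dup = manifest.duplicated(subset=["subject_id", "session", "task"], keep=False)
    for _, row in manifest[dup].iterrows():
        problems.append(
            f"duplicate unit row: {row.subject_id}/{row.session}/{row.task}"
        )
    expected = {(s, t) for s in sessions for t in tasks}
    for subject, grp in manifest.groupby("subject_id"):
        have = set(zip(grp["session"], grp["task"]))
        for s, t in sorted(expected - have):
            problems.append(f"subject {subject} missing {s}/{t} row")
        for label in ("diagnosis", "sex", "responder", "site"):
            if grp[label].nunique() > 1:
                problems.append(f"subject {subject} has contradictory {label} labels")
    if check_files:
        root = Path(base_dir) if base_dir is not None else Path(".")
        for _, row in manifest.iterrows():
            p = root / row["path"]
            if not p.exists():
                problems.append(f"missing file: {p}")
    if problems:
        raise ManifestError(problems)
    return manifest


def _unit_meta(row, task: str) -> UnitMetadata:
    return UnitMetadata(
        subject_id=row["subject_id"],
        session=row["session"],
        task=task,
        diagnosis=row["diagnosis"],
        sex=row["sex"],
        responder=row["responder"],
    )


def _prep_run(ts, events_path, fir_lag):
    if events_path is not None and Path(events_path).exists():
        ev = read_events(events_path)
        if len(ev):
            design = build_fir_design(ev, ts.n_timepoints, ts.tr_seconds, fir_lag)
            ts, design = regress_out_task(ts, design)
            if design.dropped:
                logger.info(
                    "%s/%s/%s: dropped %d collinear FIR columns",
                    ts.subject_id, ts.session, ts.task, len(design.dropped),
                )
    return demean_timeseries(ts)


def _events_path(events_dir, row):
    if events_dir is None:
        return None
    return Path(events_dir) / f"{row['subject_id']}_{row['session']}_{row['task']}_events.tsv"


def _load_and_prep(manifest, base_dir, events_dir, tr_seconds, fir_lag):
    runs = []
    for _, row in manifest.iterrows():
        ts = read_timeseries_file(
            Path(base_dir) / row["path"],
            subject_id=row["subject_id"],
            session=row["session"],
            task=row["task"],
            tr_seconds=tr_seconds,
        )
        runs.append((row, _prep_run(ts, _events_path(events_dir, row), fir_lag)))
    return runs


def _vectors_from_runs(runs, mode):
    """Pooled mode concatenates a subject-session's tasks before FC."""
    vectors = []
    if mode == "pooled":
        groups: dict[tuple, list] = {}
        meta_rows: dict[tuple, object] = {}
        for row, ts in runs:
            key = (row["subject_id"], row["session"])
            groups.setdefault(key, []).append(ts)
            meta_rows[key] = row
        for key in groups:
            pooled = concatenate_runs(groups[key])
            meta = _unit_meta(meta_rows[key], "pooled")
            vectors.append(vectorize_upper(compute_fc(pooled, meta)))
    else:
        for row, ts in runs:
            meta = _unit_meta(row, row["task"])
            vectors.append(vectorize_upper(compute_fc(ts, meta)))
    return vectors


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Execute prep -> FC -> decomposition -> inference (+ optional stages).

    With a ``simulation`` block, the synthetic dataset is generated first
    (written under ``out_dir/simdata`` in time-series mode, in memory in
    vector mode); otherwise the manifest is validated and read.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("run_pipeline: sample=%s mode=%s seed=%d",
                config.sample, config.mode, config.seed)

    fc_runs_by_subject = None
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        cohort = cohort_mod.generate_cohort(sim)
        components = cohort_mod.generate_latent_components(sim, cohort)
        if sim.mode == "vector":
            grain = "session_task" if config.mode == "per-task" else "session"
            sim = dataclasses.replace(sim, unit_grain=grain)
            components = cohort_mod.generate_latent_components(sim, cohort)
            vectors = cohort_mod.generate_fc_vectors(components, cohort, sim)
        else:
            sim_dir = out_dir / "simdata"
            raw_runs, manifest, _ = cohort_mod.generate_timeseries_dataset(
                components, cohort, sim, out_dir=sim_dir
            )
            manifest = validate_manifest(manifest, tasks=[t for t, _ in sim.tasks],
                                         sessions=sim.sessions, base_dir=sim_dir)
            prepped = _load_and_prep(
                manifest, sim_dir, sim_dir / "events", sim.tr_seconds, config.fir_lag
            )
            vectors = _vectors_from_runs(prepped, config.mode)
            fc_runs_by_subject = {}
            for row, ts in prepped:
                fc_runs_by_subject.setdefault(row["subject_id"], []).append(ts)
    else:
        manifest = validate_manifest(config.manifest)
        base_dir = Path(config.manifest).parent
        tr = 2.0 if config.simulation is None else config.simulation.tr_seconds
        prepped = _load_and_prep(manifest, base_dir, config.events_dir, tr, config.fir_lag)
        vectors = _vectors_from_runs(prepped, config.mode)
        fc_runs_by_subject = {}
        for row, ts in prepped:
            fc_runs_by_subject.setdefault(row["subject_id"], []).append(ts)

    simmat, masks, effects, per_subject = decompose(
        vectors,
        sample=config.sample,
        mode=config.mode,
        include_within_individual_in_group_masks=(
            config.include_within_individual_in_group_masks
        ),
    )
    logger.info("decomposition: %d units, %d effects", simmat.n_units, len(masks))
    comparisons = run_comparison_suite(
        per_subject,
        sample=config.sample,
        mode=config.mode,
        n_perm=config.n_perm,
        seed=config.seed,
        q=config.fdr_q,
    )

    roi_effects = None
    if config.run_roi:
        from .connectivity import matrix_from_vector

        mats = [matrix_from_vector(v) for v in vectors]
        roi_effects = roi_effect_magnitudes(mats, sample=config.sample, mode=config.mode)

    reliability = None
    if config.run_reliability and fc_runs_by_subject is not None:
        # reliability is run on control participants only
        reliability = split_half_curve(
            _controls_only(fc_runs_by_subject, vectors),
            lengths_minutes=config.reliability_lengths,
            seed=config.seed,
        )

    per_subject_long = (
        per_subject.reset_index()
        .melt(id_vars="subject_id", var_name="effect", value_name="mean_z")
        .sort_values(["subject_id", "effect"], kind="stable")
    )
    written = {}
    effects.to_csv(out_dir / "effects.tsv", sep="\t", index=False)
    per_subject_long.to_csv(out_dir / "per_participant_effects.tsv", sep="\t", index=False)
    comparisons.to_csv(out_dir / "comparisons.tsv", sep="\t", index=False)
    written["effects.tsv"] = _sha256(out_dir / "effects.tsv")
    written["per_participant_effects.tsv"] = _sha256(out_dir / "per_participant_effects.tsv")
    written["comparisons.tsv"] = _sha256(out_dir / "comparisons.tsv")
    if roi_effects is not None:
        roi_effects.to_csv(out_dir / "roi_effects.tsv", sep="\t", index=False)
        written["roi_effects.tsv"] = _sha256(out_dir / "roi_effects.tsv")
    if reliability is not None:
        reliability.to_csv(out_dir / "reliability.tsv", sep="\t", index=False)
        mean_curve(reliability).to_csv(out_dir / "reliability_mean.tsv", sep="\t", index=False)
        written["reliability.tsv"] = _sha256(out_dir / "reliability.tsv")
        written["reliability_mean.tsv"] = _sha256(out_dir / "reliability_mean.tsv")

    metadata = {
        "seed": config.seed,
        "sample": config.sample,
        "mode": config.mode,
        "n_perm": config.n_perm,
        "fdr_q": config.fdr_q,
        "n_units": simmat.n_units,
        "outputs": written,
    }
    (out_dir / "run.json").write_text(json.dumps(metadata, indent=1, default=str))
    return ResultsBundle(
        effects=effects,
        participant_effects=per_subject,
        comparisons=comparisons,
        roi_effects=roi_effects,
        reliability=reliability,
        metadata=metadata,
    )


def _controls_only(fc_runs_by_subject, vectors):
    control_subjects = {
        v.meta.subject_id for v in vectors if v.meta.diagnosis == "control"
    }
    return {s: r for s, r in fc_runs_by_subject.items() if s in control_subjects}
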