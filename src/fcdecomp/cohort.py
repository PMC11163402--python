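"""Synthetic cohorts with known ground-truth FC variance structure.

The generator emulates a longitudinal antidepressant-trial design: patients
with a major-depression (MD) diagnosis and healthy controls, each scanned
at three sessions (baseline, week 2, week 8) on three tasks (rest, an
affective go/no-go task and a monetary-incentive-delay "anhedonia" task),
with MADRS symptom trajectories in patients defining treatment response
(strictly more than 50% decrease from baseline to week 8).

Each unit's latent FC vector is a weighted sum of i.i.d. standard-normal
component patterns shared according to the unit's labels: one common
pattern, one per diagnosis / sex / response level, one per session and task,
one per individual and per individual-session cell, plus fresh unit noise.
Under this additive model the expected correlation between two units'
vectors is (sum of squared weights of shared components) / (sum of squared
weights of all components including noise), which yields a closed-form
oracle for every effect's expected similarity.

In time-series mode each run's latent vector is mapped to a valid ROI x ROI
correlation matrix and T samples of a Gaussian process with that target
structure are emitted, optionally with an injected task-locked FIR-shaped
response, so the full preparation pipeline (FIR regression, demeaning,
concatenation) can be exercised end to end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import FcVector, UnitMetadata
from .decomposition import make_effect_masks
from .prep import RoiTimeSeries, build_fir_design, write_timeseries_file

COMPONENTS = (
    "common",
    "diagnosis",
    "sex",
    "response",
    "session",
    "individual",
    "task",
    "individual_session",
    "noise",
)

#: study-condition default weights (standard deviations of the latent
#: component patterns); chosen so that common and individual variation
#: dominate, group effects are present but small, and unit noise is modest
DEFAULT_WEIGHTS = {
    "common": 1.0,
    "diagnosis": 0.1,
    "sex": 0.1,
    "response": 0.1,
    "session": 0.05,
    "individual": 0.95,
    "task": 0.30,
    "individual_session": 0.20,
    "noise": 0.35,
}

DEFAULT_SESSIONS = ("baseline", "week2", "week8")
DEFAULT_TASKS = (("rest", 588.0), ("gonogo", 588.0), ("anhedonia", 690.0))

#: event types injected per task in time-series mode
TASK_EVENT_TYPES = {
    "rest": (),
    "gonogo": ("instruction", "angry_go", "angry_nogo", "neutral_go", "neutral_nogo"),
    "anhedonia": (
        "cue_reward",
        "cue_noreward",
        "target",
        "fb_hit_reward",
        "fb_hit_noreward",
        "fb_miss_reward",
        "fb_miss_noreward",
    ),
}

_SITES = ("CAM", "MCU", "QNS", "TGH", "UBC", "UCA")

# sub-stream indices hung off the master seed, one per generation stage
_STREAM_COHORT = 0
_STREAM_COMPONENTS = 1
_STREAM_VECTORS = 2
_STREAM_TIMESERIES = 3


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Design and variance-component weights for one synthetic cohort.

    Counts default to the study composition: 42/26 female/male patients of
    whom 33 respond, and 21/18 female/male controls.  ``n_rois`` defaults to
    60 for speed; 326 mirrors the study's parcellation.
    """

    n_controls_f: int = 21
    n_controls_m: int = 18
    n_patients_f: int = 42
    n_patients_m: int = 26
    n_responders: int = 33
    sessions: tuple = DEFAULT_SESSIONS
    tasks: tuple = DEFAULT_TASKS
    tr_seconds: float = 2.0
    n_rois: int = 60
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    unit_grain: str = "session"  # "session" (pooled tasks) or "session_task"
    mode: str = "vector"  # "vector" or "timeseries"
    task_signal_amplitude: float = 1.0
    fir_lag: int = 10
    seed: int = 0

    def __post_init__(self):
        for name in ("n_controls_f", "n_controls_m", "n_patients_f", "n_patients_m"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.n_responders <= self.n_patients:
            raise ConfigurationError("n_responders must be between 0 and n_patients")
        unknown = set(self.weights) - set(COMPONENTS)
        if unknown:
            raise ConfigurationError(f"unknown weight components: {sorted(unknown)}")
        self.weights = {c: float(self.weights.get(c, 0.0)) for c in COMPONENTS}
        if any(w < 0 for w in self.weights.values()):
            raise ConfigurationError("all weights must be >= 0")
        if all(w == 0 for w in self.weights.values()):
            raise ConfigurationError("at least one weight must be > 0")
        if self.n_rois < 3:
            raise ConfigurationError("n_rois must be >= 3")
        if self.unit_grain not in ("session", "session_task"):
            raise ConfigurationError(f"unknown unit_grain {self.unit_grain!r}")
        if self.mode not in ("vector", "timeseries"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        self.sessions = tuple(self.sessions)
        self.tasks = tuple((str(t), float(d)) for t, d in self.tasks)

    @property
    def n_patients(self) -> int:
        return self.n_patients_f + self.n_patients_m

    @property
    def n_controls(self) -> int:
        return self.n_controls_f + self.n_controls_m

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls

    @property
    def n_pairs(self) -> int:
        """P = R(R-1)/2, the latent FC vector length."""
        return self.n_rois * (self.n_rois - 1) // 2

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def classify_responder(madrs_baseline: float, madrs_week8: float) -> str:
    """Strict rule: responder iff MADRS decreased by more than 50%."""
    if madrs_baseline <= 0:
        raise ValueError("baseline MADRS must be positive")
    decrease = (madrs_baseline - madrs_week8) / madrs_baseline
    return "responder" if decrease > 0.5 else "nonresponder"


def _truncated_normal(rng, mean, sd, lower, size):
    out = rng.normal(mean, sd, size=size)
    while True:
        bad = out < lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Cohort table with diagnosis, sex, site, response label and MADRS scores.

    Exactly ``n_responders`` patients satisfy the responder rule; the label
    column is reproducible from the MADRS columns.  Controls carry NaN MADRS
    scores and ``responder = not_applicable``.
    """
    rng = config.rng(_STREAM_COHORT)
    rows = []
    strata = [
        ("MD", "F", config.n_patients_f),
        ("MD", "M", config.n_patients_m),
        ("control", "F", config.n_controls_f),
        ("control", "M", config.n_controls_m),
    ]
    for diagnosis, sex, count in strata:
        for _ in range(count):
            rows.append({"diagnosis": diagnosis, "sex": sex})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ConfigurationError("empty cohort requested")
    df.insert(0, "subject_id", [f"sub{i + 1:03d}" for i in range(len(df))])
    df["site"] = [_SITES[i % len(_SITES)] for i in range(len(df))]

    is_patient = (df["diagnosis"] == "MD").to_numpy()
    n_pat = int(is_patient.sum())
    responder_flags = np.zeros(n_pat, dtype=bool)
    responder_flags[rng.permutation(n_pat)[: config.n_responders]] = True

    madrs_b = np.full(len(df), np.nan)
    madrs_2 = np.full(len(df), np.nan)
    madrs_8 = np.full(len(df), np.nan)
    # entry criterion: MADRS > 24 at enrollment
    baseline = np.round(_truncated_normal(rng, 29.0, 3.0, 24.0, n_pat))
    week8 = np.empty(n_pat)
    for i, (b, resp) in enumerate(zip(baseline, responder_flags)):
        if resp:
            w8 = round(b * (1.0 - rng.uniform(0.55, 0.90)))
            while not (b - w8) / b > 0.5:  # strict rule, robust to rounding
                w8 -= 1
            w8 = max(w8, 0)
            if not (b - w8) / b > 0.5:
                raise ConfigurationError("cannot satisfy responder rule")
        else:
            w8 = round(b * (1.0 - rng.uniform(-0.10, 0.45)))
            w8 = max(w8, 0)
            while (b - w8) / b > 0.5:
                w8 += 1
        week8[i] = w8
    week2 = np.clip(
        np.round(baseline - 0.5 * (baseline - week8) + rng.normal(0, 2, n_pat)),
        0,
        None,
    )
    madrs_b[is_patient] = baseline
    madrs_2[is_patient] = week2
    madrs_8[is_patient] = week8
    df["responder"] = "not_applicable"
    df.loc[is_patient, "responder"] = [
        "responder" if f else "nonresponder" for f in responder_flags
    ]
    df["madrs_baseline"] = madrs_b
    df["madrs_week2"] = madrs_2
    df["madrs_week8"] = madrs_8
    return df


@dataclass
class LatentComponents:
    """Scaled component patterns, each of length P = R(R-1)/2.

    Keys are tuples: ("common",), ("diagnosis", level), ("sex", level),
    ("response", level), ("session", s), ("task", t), ("individual", subject),
    ("individual_session", subject, session).
    """

    patterns: dict
    n_pairs: int

    def __getitem__(self, key):
        return self.patterns[key]


def generate_latent_components(
    config: SimulationConfig, cohort: pd.DataFrame
) -> LatentComponents:
    """Draw every component pattern in a fixed order (bit-reproducible)."""
    rng = config.rng(_STREAM_COMPONENTS)
    P = config.n_pairs
    w = config.weights
    keys: list[tuple] = [("common",)]
    keys += [("diagnosis", lev) for lev in ("MD", "control")]
    keys += [("sex", lev) for lev in ("F", "M")]
    keys += [("response", lev) for lev in ("responder", "nonresponder", "not_applicable")]
    keys += [("session", s) for s in config.sessions]
    keys += [("task", t) for t, _ in config.tasks]
    keys += [("individual", s) for s in cohort["subject_id"]]
    keys += [
        ("individual_session", s, sess)
        for s in cohort["subject_id"]
        for sess in config.sessions
    ]
    patterns = {k: w[k[0]] * rng.standard_normal(P) for k in keys}
    return LatentComponents(patterns=patterns, n_pairs=P)


def unit_metadata(config: SimulationConfig, cohort: pd.DataFrame, grain=None) -> list:
    """Unit list in generation order: subject-major, then session, then task."""
    grain = grain or config.unit_grain
    units = []
    for row in cohort.itertuples():
        for sess in config.sessions:
            tasks = [t for t, _ in config.tasks] if grain == "session_task" else ["pooled"]
            for t in tasks:
                units.append(
                    UnitMetadata(
                        subject_id=row.subject_id,
                        session=sess,
                        task=t,
                        diagnosis=row.diagnosis,
                        sex=row.sex,
                        responder=row.responder,
                    )
                )
    return units


def _component_keys(meta: UnitMetadata, grain: str) -> list:
    keys = [
        ("common",),
        ("diagnosis", meta.diagnosis),
        ("sex", meta.sex),
        ("response", meta.responder),
        ("session", meta.session),
        ("individual", meta.subject_id),
    ]
    if grain == "session_task":
        keys.append(("task", meta.task))
        keys.append(("individual_session", meta.subject_id, meta.session))
    return keys


def _latent_vector(components, meta, grain):
    v = np.zeros(components.n_pairs)
    for key in _component_keys(meta, grain):
        v = v + components[key]
    return v


def generate_fc_vectors(
    components: LatentComponents, cohort: pd.DataFrame, config: SimulationConfig
) -> list:
    """Latent FC vectors per unit, emitted directly in z-scale.

    The decomposition depends on correlations between vectors, not their
    marginal scale, so no tanh round-trip is applied in vector mode.
    """
    if cohort.empty:
        raise ConfigurationError("empty cohort")
    rng = config.rng(_STREAM_VECTORS)
    grain = config.unit_grain
    noise_w = config.weights["noise"]
    out = []
    for meta in unit_metadata(config, cohort, grain):
        v = _latent_vector(components, meta, grain)
        v = v + noise_w * rng.standard_normal(components.n_pairs)
        out.append(FcVector(values=v, n_rois=config.n_rois, meta=meta))
    return out


# ---------------------------------------------------------------------------
# analytic oracle


def _shared_sq(u: UnitMetadata, v: UnitMetadata, w: Mapping, grain: str) -> float:
    s = w["common"] ** 2
    if u.diagnosis == v.diagnosis:
        s += w["diagnosis"] ** 2
    if u.sex == v.sex:
        s += w["sex"] ** 2
    if u.responder == v.responder:
        s += w["response"] ** 2
    if u.session == v.session:
        s += w["session"] ** 2
    if u.subject_id == v.subject_id:
        s += w["individual"] ** 2
    if grain == "session_task":
        if u.task == v.task:
            s += w["task"] ** 2
        if u.subject_id == v.subject_id and u.session == v.session:
            s += w["individual_session"] ** 2
    return s


def _total_sq(w: Mapping, grain: str) -> float:
    total = (
        w["common"] ** 2
        + w["diagnosis"] ** 2
        + w["sex"] ** 2
        + w["response"] ** 2
        + w["session"] ** 2
        + w["individual"] ** 2
        + w["noise"] ** 2
    )
    if grain == "session_task":
        total += w["task"] ** 2 + w["individual_session"] ** 2
    return total


@dataclass(frozen=True)
class GroundTruthEntry:
    """Expected pairwise correlation and expected mask-average Fisher z."""

    expected_r: float
    expected_z: float


def pairwise_expected_correlations(
    config: SimulationConfig, units: Sequence[UnitMetadata]
) -> np.ndarray:
    """Matrix of expected (pre-Fisher) correlations between latent vectors."""
    w = config.weights
    grain = config.unit_grain
    total = _total_sq(w, grain)
    n = len(units)
    rho = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rho[i, j] = rho[j, i] = _shared_sq(units[i], units[j], w, grain) / total
    return rho


def expected_ground_truth(
    config: SimulationConfig, sample: str = "all", cohort: pd.DataFrame | None = None
) -> dict:
    """Analytic expected similarity per effect for one sample.

    Under the additive component model the correlation between two units'
    latent vectors converges (P -> infinity) to shared variance over total
    variance; each effect's expectation is the cell-count-weighted average
    of Fisher z of that ratio over its mask cells.
    """
    from .decomposition import filter_sample

    if cohort is None:
        cohort = generate_cohort(config)
    mode = "per-task" if config.unit_grain == "session_task" else "pooled"
    units = filter_sample(unit_metadata(config, cohort), sample)
    rho = pairwise_expected_correlations(config, units)
    masks = make_effect_masks(units, sample=sample, mode=mode)
    iu = np.triu_indices(len(units), k=1)
    out = {}
    for eff, m in masks.items():
        sel = m[iu]
        if not sel.any():  # degenerate tiny cohorts can leave a mask empty
            continue
        out[eff] = GroundTruthEntry(
            expected_r=float(rho[iu][sel].mean()),
            expected_z=float(np.arctanh(rho[iu][sel]).mean()),
        )
    return out


def expected_effect_similarity(
    config: SimulationConfig, effect_name: str, sample: str = "all"
) -> GroundTruthEntry:
    """Oracle for one effect; raises on unknown effect names."""
    gt = expected_ground_truth(config, sample=sample)
    if effect_name not in gt:
        raise KeyError(f"unknown effect {effect_name!r} for sample {sample!r}")
    return gt[effect_name]


# ---------------------------------------------------------------------------
# time-series mode


def nearest_correlation(C: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Nearest positive-definite correlation: clip eigenvalues, rescale diagonal."""
    C = (C + C.T) / 2.0
    vals, vecs = np.linalg.eigh(C)
    vals = np.clip(vals, eig_floor, None)
    C = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return C


def target_correlation_from_latent(v: np.ndarray, n_rois: int) -> np.ndarray:
    """Map a latent z-scale vector into a valid ROI x ROI correlation matrix."""
    if not np.all(np.isfinite(v)):
        raise ValueError("latent vector contains non-finite values")
    C = np.eye(n_rois)
    iu = np.triu_indices(n_rois, k=1)
    r = np.tanh(v)
    C[iu] = r
    C = C + C.T - np.eye(n_rois) * C.diagonal()
    np.fill_diagonal(C, 1.0)
    return nearest_correlation(C)


def make_events(task: str, duration_seconds: float) -> pd.DataFrame:
    """Deterministic event tables per task (empty for rest).

    go/no-go: 16 blocks, each a 2 s instruction slide followed by a 30 s
    block of one of the four block types.  anhedonia: 16 s trials of cue
    (reward / no reward), target, and one of four feedback types.
    """
    rows = []
    if task == "gonogo":
        block_types = ("angry_go", "neutral_go", "angry_nogo", "neutral_nogo")
        t = 0.0
        for i in range(16):
            if t + 32.0 > duration_seconds:
                break
            rows.append((t, 2.0, "instruction"))
            rows.append((t + 2.0, 30.0, block_types[i % 4]))
            t += 36.0
    elif task == "anhedonia":
        t = 4.0
        i = 0
        while t + 8.0 <= duration_seconds - 4.0:
            cue = "cue_reward" if i % 2 == 0 else "cue_noreward"
            hit = (i // 2) % 2 == 0
            fb = f"fb_{'hit' if hit else 'miss'}_{'reward' if cue == 'cue_reward' else 'noreward'}"
            rows.append((t, 2.0, cue))
            rows.append((t + 3.0, 1.0, "target"))
            rows.append((t + 5.0, 1.5, fb))
            t += 16.0
            i += 1
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])


def _task_signal(rng, design_matrix, columns, n_rois, lag):
    """FIR-shaped task-locked signal: per-type response shape x ROI loading."""
    types = sorted({c[0] for c in columns})
    window = np.hanning(lag + 2)[1:-1]
    shapes = {k: rng.standard_normal(lag) * window for k in types}
    loadings = {k: rng.standard_normal(n_rois) for k in types}
    W = np.vstack([np.outer(shapes[k], loadings[k])[l] for k, l in columns])
    return design_matrix @ W


def _unit_target(components, meta, config, unit_index) -> np.ndarray:
    """Deterministic per-run target correlation (own noise substream)."""
    rng = np.random.default_rng([int(config.seed), _STREAM_TIMESERIES, unit_index, 0])
    v = _latent_vector(components, meta, "session_task")
    v = v + config.weights["noise"] * rng.standard_normal(components.n_pairs)
    return target_correlation_from_latent(v, config.n_rois)


def unit_target_correlations(
    components: LatentComponents, cohort: pd.DataFrame, config: SimulationConfig
) -> dict:
    """Ground-truth target correlation matrix per run, keyed (subject, session, task)."""
    return {
        (m.subject_id, m.session, m.task): _unit_target(components, m, config, i)
        for i, m in enumerate(unit_metadata(config, cohort, grain="session_task"))
    }


def generate_timeseries_dataset(
    components: LatentComponents,
    cohort: pd.DataFrame,
    config: SimulationConfig,
    out_dir=None,
):
    """Per-run ROI time series realising each unit's target FC structure.

    Each run (subject x session x task) gets T = floor(duration / TR)
    samples of a zero-mean Gaussian process whose correlation matrix is the
    unit's latent vector mapped through tanh and projected to the nearest
    positive-definite correlation matrix, plus (for task runs) an injected
    task-locked FIR-shaped response scaled by ``task_signal_amplitude``.

    Returns (runs, manifest, events) and writes time-series files,
    events.tsv files, manifest.csv and ground_truth.json when ``out_dir``
    is given.
    """
    if cohort.empty:
        raise ConfigurationError("empty cohort")
    durations = dict(config.tasks)
    runs: list[RoiTimeSeries] = []
    events: dict[tuple, pd.DataFrame] = {}
    manifest_rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    for idx, meta in enumerate(unit_metadata(config, cohort, grain="session_task")):
        C = _unit_target(components, meta, config, idx)
        rng = np.random.default_rng([int(config.seed), _STREAM_TIMESERIES, idx, 1])
        L = np.linalg.cholesky(C)
        T = int(durations[meta.task] // config.tr_seconds)
        data = rng.standard_normal((T, config.n_rois)) @ L.T
        ev = make_events(meta.task, durations[meta.task])
        if len(ev) and config.task_signal_amplitude > 0:
            design = build_fir_design(
                ev, T, config.tr_seconds, config.fir_lag,
                trial_types=TASK_EVENT_TYPES[meta.task],
            )
            data = data + config.task_signal_amplitude * _task_signal(
                rng, design.matrix, design.columns, config.n_rois, config.fir_lag
            )
        ts = RoiTimeSeries(
            subject_id=meta.subject_id,
            session=meta.session,
            task=meta.task,
            data=data,
            tr_seconds=config.tr_seconds,
        )
        runs.append(ts)
        events[(meta.subject_id, meta.session, meta.task)] = ev
        row = cohort.loc[cohort["subject_id"] == meta.subject_id].iloc[0]
        rel = f"timeseries/{meta.subject_id}_{meta.session}_{meta.task}_bold.tsv"
        manifest_rows.append(
            {
                "subject_id": meta.subject_id,
                "session": meta.session,
                "task": meta.task,
                "path": rel,
                "diagnosis": row["diagnosis"],
                "sex": row["sex"],
                "responder": row["responder"],
                "site": row["site"],
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        for ts, row in zip(runs, manifest_rows):
            write_timeseries_file(ts, out_dir / row["path"])
        ev_dir = out_dir / "events"
        ev_dir.mkdir(exist_ok=True)
        for (sub, sess, task), ev in events.items():
            ev.to_csv(ev_dir / f"{sub}_{sess}_{task}_events.tsv", sep="\t", index=False)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        gt = {
            sample: {
                eff: {"expected_r": e.expected_r, "expected_z": e.expected_z}
                for eff, e in expected_ground_truth(
                    replace(config, unit_grain="session_task"),
                    sample=sample, cohort=cohort,
                ).items()
            }
            for sample in ("controls", "patients", "all")
            if {"controls": config.n_controls, "patients": config.n_patients,
                "all": config.n_subjects}[sample] > 0
        }
        (out_dir / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    return runs, manifest, events
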