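"""Preparation of parcel time series for connectivity estimation.

Turns raw parcel (or voxel) time series plus event timing into demeaned,
task-regressed, concatenated per-unit ROI time series.  The steps mirror the
post-preprocessing stages of a longitudinal task/rest fMRI study: voxel-to-
parcel averaging, exclusion of tiny parcels, finite-impulse-response (FIR)
regression of task-evoked activity, per-column demeaning, and concatenation
of a session's runs into one long series.

Motion correction, censoring, filtering and spatial normalisation are
assumed to have happened upstream; this module operates on continuous,
already-cleaned series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

#: canonical task order used when concatenating a session's runs
DEFAULT_TASK_ORDER = ("rest", "gonogo", "anhedonia")

#: relative tolerance for dropping rank-deficient FIR design columns
COLLINEARITY_RTOL = 1e-8


@dataclass
class RoiTimeSeries:
    """One subject/session/task run as a time x ROI matrix.

    Parameters
    ----------
    subject_id, session, task
        Unit labels.  ``task`` is ``"pooled"`` after concatenation.
    data
        Array of shape (T, R), signal in arbitrary units.
    tr_seconds
        Sampling interval in seconds.
    roi_ids
        Region labels, one per column, in fixed order.
    """

    subject_id: str
    session: str
    task: str
    data: np.ndarray
    tr_seconds: float
    roi_ids: tuple = ()

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (time x ROI)")
        if self.data.shape[0] < 2:
            raise ValueError("a run needs at least 2 time points")
        if not self.roi_ids:
            self.roi_ids = tuple(f"roi{i:03d}" for i in range(self.data.shape[1]))
        self.roi_ids = tuple(str(r) for r in self.roi_ids)
        if len(self.roi_ids) != self.data.shape[1]:
            raise ValueError("roi_ids length must match the number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_timepoints * self.tr_seconds


@dataclass
class FirDesign:
    """FIR indicator design matrix with per-column (event type, lag) labels.

    ``columns`` holds the retained column labels; ``dropped`` records the
    labels removed by collinearity handling (empty before regression).
    """

    matrix: np.ndarray
    columns: list = field(default_factory=list)
    dropped: list = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if len(self.columns) != self.matrix.shape[1]:
            raise ValueError("column labels must match design width")


def extract_parcel_timeseries(
    voxel_data: np.ndarray,
    labels: Sequence[int],
    *,
    parcel_ids: Sequence[int] | None = None,
    subject_id: str = "unknown",
    session: str = "unknown",
    task: str = "unknown",
    tr_seconds: float = 2.0,
) -> RoiTimeSeries:
    """Average voxel series into parcels (unweighted mean per time point).

    ``voxel_data`` is (T, V); ``labels`` assigns each voxel a parcel id.
    Parcels are returned in ascending id order.  If ``parcel_ids`` is given,
    a parcel with no voxels raises, naming the parcel.
    """
    voxel_data = np.asarray(voxel_data, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != voxel_data.shape[1]:
        raise ValueError("one label per voxel required")
    ids = np.unique(labels) if parcel_ids is None else np.asarray(sorted(parcel_ids))
    cols = []
    for pid in ids:
        sel = labels == pid
        if not sel.any():
            raise ValueError(f"parcel {pid} has no voxels")
        cols.append(voxel_data[:, sel].mean(axis=1))
    return RoiTimeSeries(
        subject_id=subject_id,
        session=session,
        task=task,
        data=np.column_stack(cols),
        tr_seconds=tr_seconds,
        roi_ids=tuple(str(i) for i in ids),
    )


def extract_parcel_timeseries_nifti(
    bold_path, label_path, *, background: int = 0, **meta
) -> RoiTimeSeries:
    """Parcel extraction from a 4-D NIfTI plus an integer label volume."""
    import nibabel as nib

    bold = np.asanyarray(nib.load(str(bold_path)).dataobj, dtype=float)
    labels = np.asanyarray(nib.load(str(label_path)).dataobj).astype(int)
    if bold.ndim != 4:
        raise ValueError("BOLD image must be 4-D")
    voxel_data = bold.reshape(-1, bold.shape[-1]).T  # (T, V)
    flat = labels.reshape(-1)
    keep = flat != background
    return extract_parcel_timeseries(voxel_data[:, keep], flat[keep], **meta)


def filter_small_parcels(parcel_sizes: Mapping, min_voxels: int) -> list:
    """Keep parcels with at least ``min_voxels`` voxels (strict ``<`` excluded)."""
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    return sorted(pid for pid, size in parcel_sizes.items() if size >= min_voxels)


def read_events(path) -> pd.DataFrame:
    """Read a BIDS-style events.tsv (onset, duration, trial_type; seconds)."""
    ev = pd.read_csv(path, sep="\t")
    return validate_events(ev)


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    required = {"onset", "duration", "trial_type"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    if len(events) and (events["onset"] < 0).any():
        raise ValueError("event onsets must be >= 0")
    if len(events) and (events["duration"] < 0).any():
        raise ValueError("event durations must be >= 0")
    if len(events) and (np.diff(events["onset"].to_numpy()) < 0).any():
        raise ValueError("event onsets must be non-decreasing")
    return events


def build_fir_design(
    events: pd.DataFrame,
    n_timepoints: int,
    tr_seconds: float,
    lag_samples: int,
    trial_types: Sequence[str] | None = None,
) -> FirDesign:
    """Lagged indicator (FIR) design: one column block per event type.

    For an event of type ``k`` with onset sample ``o = floor(onset / TR)``,
    column ``(k, lag)`` gets a 1 at row ``o + lag`` for lag 0..L-1, truncated
    at the run end.  The unconstrained lag structure lets each event type
    take an arbitrary response shape, which is what makes FIR regression
    robust to group differences in hemodynamics.
    """
    events = validate_events(events)
    if lag_samples < 1:
        raise ValueError("lag_samples must be >= 1")
    if trial_types is None:
        types = sorted(events["trial_type"].astype(str).unique())
    else:
        types = [str(t) for t in trial_types]
        unknown = set(events["trial_type"].astype(str)) - set(types)
        if unknown:
            raise ValueError(f"unknown trial types in events: {sorted(unknown)}")
    columns = [(k, lag) for k in types for lag in range(lag_samples)]
    X = np.zeros((n_timepoints, len(columns)))
    col_of = {lab: j for j, lab in enumerate(columns)}
    for onset, ttype in zip(events["onset"], events["trial_type"].astype(str)):
        o = math.floor(onset / tr_seconds)
        if o >= n_timepoints:
            raise ValueError(
                f"event at {onset} s (sample {o}) lies beyond the run end"
            )
        for lag in range(lag_samples):
            row = o + lag
            if row < n_timepoints:
                X[row, col_of[(ttype, lag)]] = 1.0
    return FirDesign(matrix=X, columns=columns)


def drop_collinear_columns(design: FirDesign, rtol: float = COLLINEARITY_RTOL) -> FirDesign:
    """Drop rank-deficient design columns via pivoted QR (recorded in ``dropped``)."""
    X = design.matrix
    if X.shape[1] == 0:
        return design
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    ref = diag[0] if diag.size else 0.0
    if ref == 0.0:
        keep_idx: list[int] = []
    else:
        k = int(np.sum(diag > rtol * ref))
        keep_idx = sorted(piv[:k])
    dropped = [design.columns[j] for j in range(X.shape[1]) if j not in set(keep_idx)]
    return FirDesign(
        matrix=X[:, keep_idx],
        columns=[design.columns[j] for j in keep_idx],
        dropped=list(design.dropped) + dropped,
    )


def regress_out_task(
    ts: RoiTimeSeries, design: FirDesign, rtol: float = COLLINEARITY_RTOL
) -> tuple[RoiTimeSeries, FirDesign]:
    """OLS residuals per ROI after removing retained FIR columns.

    No intercept is added (demeaning is an explicit separate step).  Returns
    the residual series and the reduced design whose ``dropped`` field
    records the collinear columns removed.
    """
    if design.matrix.shape[0] != ts.n_timepoints:
        raise ValueError("design rows must equal the number of time points")
    reduced = drop_collinear_columns(design, rtol=rtol)
    X = reduced.matrix
    if X.shape[1] > X.shape[0]:
        raise ValueError("more retained design columns than time points")
    if X.shape[1] == 0:
        return replace(ts, data=ts.data.copy()), reduced
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    resid = ts.data - X @ beta
    return replace(ts, data=resid), reduced


def demean_timeseries(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Subtract each ROI column's temporal mean."""
    return replace(ts, data=ts.data - ts.data.mean(axis=0, keepdims=True))


def concatenate_runs(
    runs: Sequence[RoiTimeSeries], task_order: Sequence[str] = DEFAULT_TASK_ORDER
) -> RoiTimeSeries:
    """Row-wise concatenation of one subject-session's runs in task order."""
    if not runs:
        raise ValueError("no runs to concatenate")
    first = runs[0]
    for r in runs[1:]:
        if r.subject_id != first.subject_id or r.session != first.session:
            raise ValueError("all runs must share subject and session")
        if r.roi_ids != first.roi_ids:
            raise ValueError("all runs must share ROI count and order")
        if r.tr_seconds != first.tr_seconds:
            raise ValueError("all runs must share the sampling interval")
    order = {t: i for i, t in enumerate(task_order)}
    ranked = sorted(
        enumerate(runs), key=lambda ir: (order.get(ir[1].task, len(order)), ir[0])
    )
    data = np.vstack([r.data for _, r in ranked])
    return RoiTimeSeries(
        subject_id=first.subject_id,
        session=first.session,
        task="pooled",
        data=data,
        tr_seconds=first.tr_seconds,
        roi_ids=first.roi_ids,
    )


def read_timeseries_file(
    path, *, subject_id: str, session: str, task: str, tr_seconds: float
) -> RoiTimeSeries:
    """Read a delimited text run (T rows x R columns, header row of ROI ids)."""
    df = pd.read_csv(path, sep="\t")
    return RoiTimeSeries(
        subject_id=subject_id,
        session=session,
        task=task,
        data=df.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
        roi_ids=tuple(df.columns),
    )


def write_timeseries_file(ts: RoiTimeSeries, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(ts.data, columns=list(ts.roi_ids)).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )
    return path
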