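"""Split-half reliability of FC as a function of data amount.

Each subject's runs are cut into whole 2.5-minute segments (75 samples at
TR = 2 s; remainders discarded) and the segments are split into two
disjoint pools, each constrained to contain every task and both temporal
run-halves.  A reference FC is estimated from the full first pool; FC from
increasing numbers of second-pool segments is correlated with it, giving a
reliability curve over data amount.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import compute_fc, vectorize_upper
from .prep import RoiTimeSeries

SEGMENT_SECONDS = 150.0
DEFAULT_LENGTH_GRID_MINUTES = (5, 10, 15, 20, 25, 30, 35, 40, 45)


@dataclass(frozen=True)
class Segment:
    """A contiguous whole segment of one run."""

    subject_id: str
    session: str
    task: str
    half: str  # temporal half of the run: "first" or "second"
    start: int
    length: int
    run_index: int  # position in the subject's run list


def segment_run(ts: RoiTimeSeries, run_index: int, segment_seconds: float = SEGMENT_SECONDS):
    """Cut one run into whole segments; trailing remainder samples are discarded."""
    seg_len = int(segment_seconds // ts.tr_seconds)
    n_seg = ts.n_timepoints // seg_len
    segments = []
    for i in range(n_seg):
        start = i * seg_len
        center = start + seg_len / 2.0
        half = "first" if center < ts.n_timepoints / 2.0 else "second"
        segments.append(
            Segment(
                subject_id=ts.subject_id,
                session=ts.session,
                task=ts.task,
                half=half,
                start=start,
                length=seg_len,
                run_index=run_index,
            )
        )
    return segments


def _covers(segments: Sequence[Segment], tasks, halves) -> bool:
    return (
        {s.task for s in segments} >= tasks and {s.half for s in segments} >= halves
    )


def make_segments(
    runs: Sequence[RoiTimeSeries],
    seed: int = 0,
    segment_seconds: float = SEGMENT_SECONDS,
    max_tries: int = 200,
):
    """Split one subject's runs into two disjoint, balanced segment pools.

    Every run contributes segments to both pools (alternating assignment
    with a pseudorandom phase per run), and the assignment is re-drawn until
    each pool contains at least one segment of every task and of both
    temporal run-halves.
    """
    if not runs:
        raise ValueError("no runs given")
    per_run = [segment_run(ts, i, segment_seconds) for i, ts in enumerate(runs)]
    for i, segs in enumerate(per_run):
        if len(segs) < 2:
            raise ValueError(
                f"run {runs[i].task}/{runs[i].session} yields fewer than 2 segments"
            )
    tasks = {ts.task for ts in runs}
    halves = {"first", "second"}
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        ref, test = [], []
        for segs in per_run:
            offset = int(rng.integers(0, 2))
            for j, seg in enumerate(segs):
                (ref if (j + offset) % 2 == 0 else test).append(seg)
        if _covers(ref, tasks, halves) and _covers(test, tasks, halves):
            return ref, test
    raise ValueError("could not balance segment pools over tasks and halves")


def _segment_data(segments: Sequence[Segment], runs: Sequence[RoiTimeSeries]) -> np.ndarray:
    """Concatenate segment data, demeaning each segment before stacking."""
    chunks = []
    for seg in segments:
        block = runs[seg.run_index].data[seg.start : seg.start + seg.length]
        chunks.append(block - block.mean(axis=0, keepdims=True))
    return np.vstack(chunks)


def _fc_vector(data: np.ndarray, template: RoiTimeSeries) -> np.ndarray:
    ts = RoiTimeSeries(
        subject_id=template.subject_id,
        session="split",
        task="mixed",
        data=data,
        tr_seconds=template.tr_seconds,
        roi_ids=template.roi_ids,
    )
    return vectorize_upper(compute_fc(ts)).values


def _select_covering(segments, n_needed, tasks, rng):
    """Pseudorandom selection of n segments covering all tasks and halves."""
    order = list(rng.permutation(len(segments)))
    chosen: list[int] = []
    missing_tasks = set(tasks)
    missing_halves = {"first", "second"}
    for idx in list(order):
        seg = segments[idx]
        if seg.task in missing_tasks or seg.half in missing_halves:
            chosen.append(idx)
            missing_tasks.discard(seg.task)
            missing_halves.discard(seg.half)
            order.remove(idx)
        if len(chosen) == n_needed:
            break
    for idx in order:
        if len(chosen) == n_needed:
            break
        chosen.append(idx)
    return [segments[i] for i in chosen[:n_needed]]


def split_half_curve(
    runs_by_subject: Mapping[str, Sequence[RoiTimeSeries]],
    lengths_minutes: Sequence[float] = DEFAULT_LENGTH_GRID_MINUTES,
    seed: int = 0,
    segment_seconds: float = SEGMENT_SECONDS,
) -> pd.DataFrame:
    """Reliability curve r(length) per subject plus the across-subject mean.

    The curve value is the Pearson correlation between the reference-half
    FC vector and the FC vector from ``length`` minutes of test-half
    segments.  Raises if a grid length exceeds the test pool.
    """
    lengths = list(lengths_minutes)
    if any(b <= a for a, b in zip(lengths, lengths[1:])):
        raise ValueError("length grid must be strictly increasing")
    rows = []
    master = np.random.SeedSequence(seed)
    for (subject, runs), ss in zip(
        sorted(runs_by_subject.items()), master.spawn(len(runs_by_subject))
    ):
        runs = list(runs)
        sub_rng = np.random.default_rng(ss)
        ref, test = make_segments(
            runs, seed=int(sub_rng.integers(2**31)), segment_seconds=segment_seconds
        )
        tasks = {ts.task for ts in runs}
        ref_vec = _fc_vector(_segment_data(ref, runs), runs[0])
        for minutes in lengths:
            n_needed = int(round(minutes * 60.0 / segment_seconds))
            if n_needed > len(test):
                raise ValueError(
                    f"{minutes} min exceeds the test pool "
                    f"({len(test)} segments) for subject {subject}"
                )
            sel = _select_covering(test, n_needed, tasks, sub_rng)
            vec = _fc_vector(_segment_data(sel, runs), runs[0])
            r = float(np.corrcoef(ref_vec, vec)[0, 1])
            rows.append({"subject_id": subject, "minutes": minutes, "r": r})
    return pd.DataFrame(rows)


def mean_curve(curve: pd.DataFrame) -> pd.DataFrame:
    """Across-subject mean reliability per data amount."""
    return (
        curve.groupby("minutes", as_index=False)["r"]
        .mean()
        .rename(columns={"r": "mean_r"})
    )
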