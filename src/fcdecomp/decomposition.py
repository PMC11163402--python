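"""Similarity-matrix variance decomposition of whole-brain FC.

The central object is the unit x unit similarity matrix: the Fisher-z
correlation between every pair of units' whole-brain FC vectors, where a
unit is one subject-session (pooled mode) or one subject-session-task run
(per-task mode).  Each source of variance (common, session, sex, diagnosis,
treatment response, their two-way interactions, individual, and the
individual x session / individual x task interactions) is quantified as the
mean similarity over a mask of matrix cells, corrected against a baseline
and normalised so that the corrected magnitudes sum to 100%.

Masks select off-diagonal cells only; the diagonal (unity by definition) is
never averaged.  Group-level masks are restricted to different-subject pairs
by default, so that e.g. the session effect measures similarity across
participants within a session rather than inheriting within-individual
similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import (
    ConnectivityMatrix,
    FcVector,
    UnitMetadata,
    fisher_z,
    roi_profile,
)

#: effects whose baseline is the common effect
_MAIN_EFFECTS = ("session", "sex", "diagnosis", "response")
#: name separator for two-way interactions
_IX = "_x_"


@dataclass
class SimilarityMatrix:
    """N x N Fisher-z correlations between units' FC vectors."""

    values: np.ndarray
    units: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.units)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape must match the unit list")

    @property
    def n_units(self) -> int:
        return len(self.units)

    def subject_rows(self, subject_id: str) -> np.ndarray:
        return np.array([u.subject_id == subject_id for u in self.units])


def build_similarity_matrix(vectors: Sequence[FcVector]) -> SimilarityMatrix:
    """Correlate every pair of FC vectors; Fisher-z transform the result."""
    if len(vectors) < 2:
        raise ValueError("need at least 2 units to build a similarity matrix")
    lengths = {v.values.shape[0] for v in vectors}
    if len(lengths) != 1:
        raise ValueError("all FC vectors must have the same length")
    stack = np.vstack([v.values for v in vectors])
    sd = stack.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"unit {vectors[bad[0]].meta.label} has a zero-variance FC vector"
        )
    z = fisher_z(np.corrcoef(stack))
    return SimilarityMatrix(values=z, units=[v.meta for v in vectors])


def filter_sample(items: Sequence, sample: str) -> list:
    """Subset units (FcVectors or metadata) to a sample: controls|patients|all."""
    def meta(x):
        return x if isinstance(x, UnitMetadata) else x.meta

    if sample == "all":
        return list(items)
    if sample == "controls":
        return [x for x in items if meta(x).diagnosis == "control"]
    if sample == "patients":
        return [x for x in items if meta(x).diagnosis == "MD"]
    raise ValueError(f"unknown sample {sample!r}")


def make_effect_masks(
    units: Sequence[UnitMetadata],
    sample: str = "all",
    mode: str = "pooled",
    include_within_individual_in_group_masks: bool = False,
) -> dict:
    """Boolean cell masks over the similarity matrix, one per effect.

    In pooled mode the individual effect is the within-subject,
    cross-session block.  In per-task mode the within-subject block is
    partitioned into three disjoint effects: individual (different session
    AND different task), individual x session (same session, different
    task), and individual x task (same task, different session).

    A factor with a single level in the sample drops its effects with a
    warning.  Masks never include the diagonal.
    """
    if mode not in ("pooled", "per-task"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(units)
    subj = np.array([u.subject_id for u in units])
    sess = np.array([u.session for u in units])
    task = np.array([u.task for u in units])
    sexes = np.array([u.sex for u in units])
    diag = np.array([u.diagnosis for u in units])
    resp = np.array([u.responder for u in units])

    offdiag = ~np.eye(n, dtype=bool)
    same_subj = subj[:, None] == subj[None, :]
    same_sess = sess[:, None] == sess[None, :]
    same_task = task[:, None] == task[None, :]
    diff_subj = ~same_subj

    def level_mask(labels):
        same = labels[:, None] == labels[None, :]
        if include_within_individual_in_group_masks:
            return same & offdiag
        return same & diff_subj

    masks: dict[str, np.ndarray] = {"common": offdiag}

    factors = {"session": sess, "sex": sexes}
    if sample == "all":
        factors["diagnosis"] = diag
    elif sample == "patients":
        factors["response"] = resp
    present = {}
    for name, labels in factors.items():
        if len(np.unique(labels)) < 2:
            warnings.warn(
                f"factor {name!r} has a single level in this sample; "
                "its effects are omitted"
            )
            continue
        present[name] = labels
        # session similarity is always across participants
        masks[name] = (labels[:, None] == labels[None, :]) & diff_subj \
            if name == "session" else level_mask(labels)

    group = "diagnosis" if sample == "all" else "response" if sample == "patients" else None
    if group in present:
        glab = present[group]
        same_g = glab[:, None] == glab[None, :]
        if "session" in present:
            masks[f"{group}{_IX}session"] = same_g & same_sess & diff_subj
        if "sex" in present:
            same_x = sexes[:, None] == sexes[None, :]
            base = same_g & same_x
            masks[f"{group}{_IX}sex"] = (
                base & offdiag if include_within_individual_in_group_masks
                else base & diff_subj
            )

    if mode == "pooled":
        masks["individual"] = same_subj & ~same_sess
    else:
        masks["individual"] = same_subj & ~same_sess & ~same_task
        masks["individual_x_session"] = same_subj & same_sess & ~same_task
        masks["individual_x_task"] = same_subj & same_task & ~same_sess

    for name, m in masks.items():
        np.fill_diagonal(m, False)
    empty = [name for name, m in masks.items() if not m.any()]
    for name in empty:  # e.g. singleton factor levels in very small samples
        warnings.warn(f"effect {name!r} selects no cells in this sample; omitted")
        del masks[name]
    return masks


def effect_average(simmat: SimilarityMatrix, mask: np.ndarray) -> float:
    """Mean similarity over the masked cells, each unordered pair counted once."""
    iu = np.triu_indices(simmat.n_units, k=1)
    sel = mask[iu]
    if not sel.any():
        raise ValueError("empty effect mask")
    return float(simmat.values[iu][sel].mean())


def participant_effect_averages(
    simmat: SimilarityMatrix, mask: np.ndarray, subject_id: str
) -> float:
    """Mean of mask cells within one participant's rows.

    Symmetric within-subject cells appear in two of the subject's rows; both
    orderings carry the same value, so the mean is unaffected.  Returns NaN
    (with a warning) if the subject's rows do not intersect the mask.
    """
    rows = simmat.subject_rows(subject_id)
    if not rows.any():
        raise ValueError(f"unknown subject {subject_id!r}")
    sub = mask[rows]
    if not sub.any():
        warnings.warn(f"no mask cells in rows of subject {subject_id!r}")
        return float("nan")
    return float(simmat.values[rows][sub].mean())


def participant_table(simmat: SimilarityMatrix, masks: Mapping) -> pd.DataFrame:
    """Per-subject effect averages: one row per subject, one column per effect."""
    subjects = list(dict.fromkeys(u.subject_id for u in simmat.units))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data = {
            eff: [participant_effect_averages(simmat, m, s) for s in subjects]
            for eff, m in masks.items()
        }
    return pd.DataFrame(data, index=pd.Index(subjects, name="subject_id"))


def baseline_for(effect: str, raw: Mapping) -> float:
    """Baseline ladder for one effect given all raw mask averages.

    common -> 0; session and group mains -> common; group two-way
    interactions -> max of their constituent mains; individual -> max over
    all session/group mains and interactions present; individual x session
    and individual x task -> individual.
    """
    if effect == "common":
        return 0.0
    if effect in _MAIN_EFFECTS:
        return float(raw["common"])
    if effect in ("individual_x_session", "individual_x_task"):
        return float(raw["individual"])
    if effect == "individual":
        pool = [
            v for k, v in raw.items()
            if k in _MAIN_EFFECTS or (_IX in k and not k.startswith("individual"))
        ]
        if not pool:
            return float(raw["common"])
        return float(max(pool))
    if _IX in effect:
        a, b = effect.split(_IX)
        pool = [raw[k] for k in (a, b) if k in raw]
        if not pool:
            raise KeyError(f"no constituent mains present for {effect!r}")
        return float(max(pool))
    raise KeyError(f"unknown effect {effect!r}")


def normalized_magnitudes(raw: Mapping) -> pd.DataFrame:
    """Raw, baseline-corrected (floored at 0) and normalised (%) magnitudes.

    The normalised relative magnitude of an effect is its corrected mask
    average as a percentage of the sum of all corrected averages; columns
    are NaN-normalised when every corrected magnitude is zero.
    """
    effects = list(raw)
    base = {e: baseline_for(e, raw) for e in effects}
    corrected = {e: max(float(raw[e]) - base[e], 0.0) for e in effects}
    total = sum(corrected.values())
    if total > 0:
        normalized = {e: 100.0 * corrected[e] / total for e in effects}
    else:
        warnings.warn("all corrected magnitudes are zero; normalisation undefined")
        normalized = {e: float("nan") for e in effects}
    return pd.DataFrame(
        {
            "effect": effects,
            "raw_mean_z": [float(raw[e]) for e in effects],
            "baseline_z": [base[e] for e in effects],
            "corrected": [corrected[e] for e in effects],
            "normalized_pct": [normalized[e] for e in effects],
        }
    )


def decompose(
    vectors: Sequence[FcVector],
    sample: str = "all",
    mode: str = "pooled",
    include_within_individual_in_group_masks: bool = False,
):
    """Full whole-brain decomposition for one sample and mode.

    Returns (similarity matrix, masks, magnitude table, per-participant table).
    """
    vecs = filter_sample(vectors, sample)
    simmat = build_similarity_matrix(vecs)
    masks = make_effect_masks(
        simmat.units,
        sample=sample,
        mode=mode,
        include_within_individual_in_group_masks=include_within_individual_in_group_masks,
    )
    raw = {eff: effect_average(simmat, m) for eff, m in masks.items()}
    table = normalized_magnitudes(raw)
    per_subject = participant_table(simmat, masks)
    return simmat, masks, table, per_subject


def roi_effect_magnitudes(
    fc_matrices: Sequence[ConnectivityMatrix],
    sample: str = "all",
    mode: str = "pooled",
    roi_indices: Sequence[int] | None = None,
    include_within_individual_in_group_masks: bool = False,
) -> pd.DataFrame:
    """Per-ROI decomposition on region connectivity profiles.

    For each region, units' profiles (that region's connectivity with every
    other region) replace the whole-brain vectors; the identical
    mask/baseline pipeline then yields one magnitude table per region.  No
    inference is performed on these regional estimates.
    """
    mats = filter_sample(fc_matrices, sample)
    if len(mats) < 2:
        raise ValueError("need at least 2 units")
    R = mats[0].n_rois
    if R < 3:
        raise ValueError("need at least 3 ROIs for regional profiles")
    units = [m.meta for m in mats]
    masks = make_effect_masks(
        units,
        sample=sample,
        mode=mode,
        include_within_individual_in_group_masks=include_within_individual_in_group_masks,
    )
    indices = range(R) if roi_indices is None else roi_indices
    frames = []
    for r in indices:
        # profiles have length R-1 (not a triangular number), so correlate
        # the raw profiles directly instead of wrapping them in FcVectors
        stack = np.vstack([roi_profile(m, r) for m in mats])
        sd = stack.std(axis=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(
                f"unit {mats[bad[0]].meta.label} has a constant profile for ROI {r}"
            )
        simmat = SimilarityMatrix(values=fisher_z(np.corrcoef(stack)), units=units)
        raw = {eff: effect_average(simmat, m) for eff, m in masks.items()}
        tab = normalized_magnitudes(raw)
        tab.insert(0, "roi_index", r)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
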