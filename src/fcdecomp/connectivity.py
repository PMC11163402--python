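"""Fisher-z functional connectivity per unit and its vectorizations.

Functional connectivity (FC) is the Pearson correlation between two regions'
time courses, variance-stabilised with Fisher's z = atanh(r).  Correlations
are clipped to +/-(1 - 1e-7) before the transform so that numerically
perfect correlations cannot inject infinities into downstream similarity
averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .prep import RoiTimeSeries

#: clipping bound on r before atanh
R_CLIP = 1.0 - 1e-7
#: largest representable z value after clipping
Z_CLIP = float(np.arctanh(R_CLIP))


def fisher_z(r):
    """atanh with the module-wide clipping guard."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


@dataclass(frozen=True)
class UnitMetadata:
    """Labels identifying one analysis unit (a subject-session or run)."""

    subject_id: str
    session: str
    task: str = "pooled"
    diagnosis: str = "control"
    sex: str = "F"
    responder: str = "not_applicable"

    @property
    def label(self) -> str:
        return f"{self.subject_id}/{self.session}/{self.task}"


@dataclass
class ConnectivityMatrix:
    """R x R symmetric Fisher-z FC matrix; the diagonal is excluded downstream."""

    values: np.ndarray
    meta: UnitMetadata

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class FcVector:
    """Upper-triangle FC in row-major (i < j) order, length R(R-1)/2."""

    values: np.ndarray
    n_rois: int
    meta: UnitMetadata

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = self.n_rois * (self.n_rois - 1) // 2
        if self.values.shape != (expected,):
            raise ValueError(
                f"FC vector for {self.n_rois} ROIs must have length {expected}"
            )


def compute_fc(ts: RoiTimeSeries, meta: UnitMetadata | None = None) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of ROI time courses, Fisher-z transformed.

    Raises if a ROI series has zero variance (its correlations are undefined),
    naming the offending ROI.
    """
    data = ts.data
    if data.shape[0] < 3:
        raise ValueError("need at least 3 time points to estimate FC")
    sd = data.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"ROI {ts.roi_ids[bad[0]]} has zero variance")
    z = fisher_z(np.corrcoef(data, rowvar=False))
    if meta is None:
        meta = UnitMetadata(subject_id=ts.subject_id, session=ts.session, task=ts.task)
    return ConnectivityMatrix(values=z, meta=meta)


def vectorize_upper(fc: ConnectivityMatrix) -> FcVector:
    """Row-major upper triangle (0,1),(0,2),...,(R-2,R-1)."""
    iu = np.triu_indices(fc.n_rois, k=1)
    return FcVector(values=fc.values[iu], n_rois=fc.n_rois, meta=fc.meta)


def matrix_from_vector(vec: FcVector) -> ConnectivityMatrix:
    """Rebuild the symmetric matrix (diagonal set to 0, which is excluded anyway)."""
    R = vec.n_rois
    m = np.zeros((R, R))
    iu = np.triu_indices(R, k=1)
    m[iu] = vec.values
    m = m + m.T
    return ConnectivityMatrix(values=m, meta=vec.meta)


def roi_profile(fc: ConnectivityMatrix, roi_index: int) -> np.ndarray:
    """One region's connectivity to all other regions (self-entry removed)."""
    if not 0 <= roi_index < fc.n_rois:
        raise IndexError(f"roi_index {roi_index} out of range for R={fc.n_rois}")
    return np.delete(fc.values[roi_index], roi_index)
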