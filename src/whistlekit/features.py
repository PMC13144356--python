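"""Acoustic parameters of whistle contours and their PCA characterization.

Seven parameters summarize each contour: duration (W_dur, s), minimum and
maximum frequency (F_min, F_max), start and end frequency (F_start, F_end),
frequency range (F_range = F_max - F_min) and mean frequency (F_mean, the
average of all trace points), all frequencies in kHz.

The PCA operates on the correlation matrix by default (the parameters mix
seconds and kilohertz, so covariance PCA would be unit-dominated), orders
components by decreasing eigenvalue, fixes the sign of each component so its
largest-magnitude loading is positive, and retains components under the
Kaiser criterion (eigenvalue strictly greater than 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .contours import ContourSet, WhistleContour
from .errors import DegenerateInputError, InvalidInputError

FEATURE_COLUMNS = [
    "w_dur_s",
    "f_min_khz",
    "f_max_khz",
    "f_start_khz",
    "f_end_khz",
    "f_range_khz",
    "f_mean_khz",
]


@dataclass
class FeatureVector:
    w_dur_s: float
    f_min_khz: float
    f_max_khz: float
    f_start_khz: float
    f_end_khz: float
    f_range_khz: float
    f_mean_khz: float

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.w_dur_s,
            self.f_min_khz,
            self.f_max_khz,
            self.f_start_khz,
            self.f_end_khz,
            self.f_range_khz,
            self.f_mean_khz,
        )


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    loadings: pd.DataFrame          # parameter x component
    scores: pd.DataFrame            # contour x component
    variance_explained_pct: np.ndarray
    retained: int


def extract_features(c: WhistleContour) -> FeatureVector:
    f = c.freqs_khz
    return FeatureVector(
        w_dur_s=c.duration_s,
        f_min_khz=float(f.min()),
        f_max_khz=float(f.max()),
        f_start_khz=float(f[0]),
        f_end_khz=float(f[-1]),
        f_range_khz=float(f.max() - f.min()),
        f_mean_khz=float(f.mean()),
    )


def feature_table(cs: ContourSet) -> pd.DataFrame:
    """One row per contour, indexed by id in ascending order."""
    rows = {cid: extract_features(cs[cid]).as_tuple() for cid in cs.ids()}
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=FEATURE_COLUMNS
    ).rename_axis("id")


def run_pca(table: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """Eigendecomposition of the correlation (or covariance) matrix.

    Requires >= 3 complete rows and >= 2 columns.  A constant column makes
    the correlation matrix undefined and raises
    :class:`DegenerateInputError` naming the column.
    """
    if table.shape[0] < 3 or table.shape[1] < 2:
        raise InvalidInputError("PCA needs >= 3 rows and >= 2 columns")
    if table.isna().any().any():
        raise InvalidInputError("PCA input contains missing values")
    X = table.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = [c for c, s in zip(table.columns, sd) if s == 0]
    if standardize and constant:
        raise DegenerateInputError(f"constant column(s): {constant}")
    Z = (X - mean) / sd if standardize else X - mean
    C = np.cov(Z, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.maximum(eigvals[order], 0.0)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-magnitude loading of each component positive
    for k in range(eigvecs.shape[1]):
        j = int(np.argmax(np.abs(eigvecs[:, k])))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    comps = [f"PC{k + 1}" for k in range(eigvecs.shape[1])]
    loadings = pd.DataFrame(eigvecs, index=table.columns, columns=comps)
    scores = pd.DataFrame(Z @ eigvecs, index=table.index, columns=comps)
    var_pct = 100.0 * eigvals / eigvals.sum()
    return PcaResult(
        eigenvalues=eigvals,
        loadings=loadings,
        scores=scores,
        variance_explained_pct=var_pct,
        retained=int(np.sum(eigvals > 1.0)),
    )


def category_clusters(
    scores: pd.DataFrame,
    labels: Mapping[str, object],
    min_n: int = 20,
) -> dict:
    """Centroid and 2-SD ellipse in the first two component axes for every
    label with more than ``min_n`` members.

    Ellipse half-axes are ``2 * sqrt(eigenvalue)`` of the 2x2 score
    covariance; the angle is that of the leading eigenvector, degrees.
    """
    if scores.shape[1] < 2:
        raise InvalidInputError("need >= 2 retained components")
    out = {}
    ids = list(scores.index)
    by_label: dict = {}
    for cid in ids:
        by_label.setdefault(labels[cid], []).append(cid)
    for label, members in sorted(by_label.items(), key=lambda kv: str(kv[0])):
        if len(members) <= min_n:
            continue
        pts = scores.loc[members].iloc[:, :2].to_numpy()
        centroid = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
        angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
        out[label] = {
            "centroid": centroid,
            "half_axes": 2.0 * np.sqrt(evals),
            "angle_deg": angle,
            "n": len(members),
        }
    return out
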