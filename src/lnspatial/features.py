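"""PCA reduction of per-patient histograms into spatial factors.

Per (organ, histogram type) the OVH or POV curves of a cohort are stacked
into a patient x bin matrix, reduced by mean-centered PCA (no per-bin
scaling: bins share units, and scaling would inflate noisy tail bins), and
the smallest number of leading components explaining at least 75% of the
cumulative variance is retained.  Per-patient component coefficients — the
spatial factors — are the prognostic covariates downstream.

Component signs are made reproducible by requiring each loading vector's
largest-magnitude entry to be positive.  Validation cohorts are always
*projected* with discovery-fitted models, never refit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "HistogramMatrix",
    "PCModel",
    "fit_pca",
    "select_components",
    "project",
    "factor_id",
]

DEFAULT_VARIANCE_THRESHOLD = 0.75


def factor_id(htype: str, organ: str, k: int) -> str:
    """Canonical factor label, e.g. ``OVH_SpinalCord_PC1`` (k is 1-based)."""
    return f"{htype}_{organ}_PC{k}"


@dataclass(frozen=True)
class HistogramMatrix:
    """Stacked curves of one cohort for one (organ, histogram type).

    Rows are patients (ordered by ``patients``), columns the shared bin or
    angle grid.  A patient lacking the organ contour must be excluded
    upstream; no missing entries are allowed here.
    """

    patients: list[str]
    grid: np.ndarray
    values: np.ndarray  # (n_patients, n_bins)
    organ: str
    htype: str  # "OVH" | "POV"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != len(self.patients):
            raise ValueError("values must be (n_patients, n_bins)")
        if v.shape[1] != np.asarray(self.grid).size:
            raise ValueError("values and grid disagree on the number of bins")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite histogram values for {self.organ}/{self.htype}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))


@dataclass(frozen=True)
class PCModel:
    """Fitted PCA for one (organ, histogram type).

    ``loadings`` has one orthonormal component per row, ordered by
    decreasing explained variance; ``evr`` are the explained-variance
    ratios; ``n_selected`` components satisfy the cumulative-variance rule.
    """

    mean: np.ndarray
    loadings: np.ndarray  # (n_components, n_bins)
    evr: np.ndarray
    n_selected: int
    organ: str
    htype: str
    grid: np.ndarray
    scaled: bool = False  # centering only; recorded for provenance

    def factor_ids(self) -> list[str]:
        return [factor_id(self.htype, self.organ, k + 1) for k in range(self.n_selected)]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "organ": self.organ,
            "htype": self.htype,
            "n_selected": int(self.n_selected),
            "scaled": self.scaled,
            "mean": self.mean.tolist(),
            "loadings": self.loadings.tolist(),
            "evr": self.evr.tolist(),
            "grid": self.grid.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCModel":
        d = json.loads(Path(path).read_text())
        return cls(
            mean=np.asarray(d["mean"]),
            loadings=np.asarray(d["loadings"]),
            evr=np.asarray(d["evr"]),
            n_selected=int(d["n_selected"]),
            organ=d["organ"],
            htype=d["htype"],
            grid=np.asarray(d["grid"]),
            scaled=bool(d.get("scaled", False)),
        )


def _apply_sign_convention(loadings: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-|loading| entry is positive."""
    out = loadings.copy()
    for i, comp in enumerate(out):
        j = int(np.argmax(np.abs(comp)))
        if comp[j] < 0:
            out[i] = -comp
    return out


def fit_pca(matrix: HistogramMatrix, variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD) -> PCModel:
    """Mean-centered PCA of a histogram matrix.

    Components are ordered by decreasing variance and sign-normalized.
    ``n_selected`` is the smallest count of leading components whose
    cumulative explained-variance ratio reaches ``variance_threshold``
    (at least one; a zero-variance matrix yields ``n_selected = 0`` with
    all ``evr`` zero).
    """
    X = matrix.values
    if X.shape[0] < 2:
        raise ValueError(
            f"PCA for {matrix.organ}/{matrix.htype} needs at least 2 patients, got {X.shape[0]}"
        )
    mean = X.mean(axis=0)
    centered = X - mean
    if np.allclose(centered, 0.0):
        return PCModel(
            mean=mean,
            loadings=np.zeros((0, X.shape[1])),
            evr=np.zeros(0),
            n_selected=0,
            organ=matrix.organ,
            htype=matrix.htype,
            grid=matrix.grid,
        )
    pca = PCA(svd_solver="full")
    pca.fit(X)
    loadings = _apply_sign_convention(pca.components_)
    evr = pca.explained_variance_ratio_
    n_sel = select_components(evr, variance_threshold)
    return PCModel(
        mean=mean,
        loadings=loadings,
        evr=evr,
        n_selected=n_sel,
        organ=matrix.organ,
        htype=matrix.htype,
        grid=matrix.grid,
    )


def select_components(evr: np.ndarray, threshold: float = DEFAULT_VARIANCE_THRESHOLD) -> int:
    """Smallest k whose cumulative explained-variance ratio is >= threshold."""
    evr = np.asarray(evr, dtype=float)
    if evr.size == 0 or np.all(evr == 0):
        raise ValueError("degenerate histograms: all explained-variance ratios are zero")
    cum = np.cumsum(evr)
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    return min(k, evr.size)


def project(model: PCModel, matrix: HistogramMatrix) -> pd.DataFrame:
    """Per-patient coefficients of the selected components.

    Coefficients are ``(curve - model.mean) . loading_k`` for the first
    ``n_selected`` components; the matrix must be on the grid the model was
    fitted on.  Returns a DataFrame indexed by patient with one column per
    factor id.
    """
    if model.grid.size != matrix.grid.size or not np.allclose(model.grid, matrix.grid):
        raise ValueError(
            f"grid mismatch for {matrix.organ}/{matrix.htype}: model fitted on a "
            f"different bin grid"
        )
    if model.n_selected == 0:
        return pd.DataFrame(index=pd.Index(matrix.patients, name="patient_id"))
    L = model.loadings[: model.n_selected]
    coeffs = (matrix.values - model.mean) @ L.T
    return pd.DataFrame(
        coeffs, index=pd.Index(matrix.patients, name="patient_id"), columns=model.factor_ids()
    )
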