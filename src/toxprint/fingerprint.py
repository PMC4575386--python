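"""Toxin fingerprints: PCA of relative-change profiles and profile matching.

The change matrix has one row per marker peak and one column per treatment
(toxin x concentration) plus a pooled control column, so a PCA "variables
factor map" draws each treatment as an arrow in the (PC1, PC2) loading
plane. Ratios are log-transformed by default before decomposition since
fold-change data are multiplicative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import ConditionSummary

__all__ = [
    "build_change_matrix",
    "pca",
    "fingerprint_pca",
    "fingerprint_distance",
    "PCAResult",
    "half_plane_separable",
]


def build_change_matrix(
    summary: ConditionSummary, control_condition: str = "control"
) -> pd.DataFrame:
    """Peaks x treatments matrix of mean-abundance ratios versus control.

    The control column (ratio 1 by construction) is appended so the pooled
    control appears as its own variable in the factor map. Peaks absent
    from the control (ratio undefined) are dropped.
    """
    from .differential import relative_change

    changes = relative_change(summary, control_condition, scale="ratio")
    matrix = changes.ratios.copy()
    if matrix.shape[0] < 2 or matrix.shape[1] < 1:
        raise ValueError("need at least 2 peaks and 1 treatment to build a change matrix")
    matrix[control_condition] = 1.0
    return matrix


@dataclass
class PCAResult:
    """Scores (rows x components), loadings (variables x components), variance."""

    scores: np.ndarray
    loadings: pd.DataFrame             # index: variable names
    explained_variance_fraction: np.ndarray
    row_names: list

    def __post_init__(self) -> None:
        evf = self.explained_variance_fraction
        if np.any(evf < -1e-12) or evf.sum() > 1 + 1e-9:
            raise ValueError("variance fractions must be nonnegative and sum to <= 1")


def pca(matrix: pd.DataFrame | np.ndarray, center: bool = True, scale: bool = False) -> PCAResult:
    """Deterministic PCA of a peaks-x-variables matrix via SVD.

    Columns are the variables (treatments): they are mean-centred and
    optionally unit-scaled. The sign of each component is fixed so its
    largest-magnitude loading is positive, making results reproducible
    bit-for-bit.
    """
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns)
        rows = list(matrix.index)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        names = [f"v{j}" for j in range(x.shape[1])]
        rows = list(range(x.shape[0]))
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("matrix must be 2-D with at least 2 rows and 2 columns")
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix contains non-finite values")

    if center:
        x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("cannot unit-scale zero-variance variables")
        x = x / sd
    if np.allclose(x, 0):
        raise ValueError("matrix has zero variance; PCA undefined")

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    variance = s**2
    evf = variance / variance.sum()
    scores = u * s
    loadings = pd.DataFrame(
        vt.T, index=names, columns=[f"PC{j + 1}" for j in range(vt.shape[0])]
    )
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=evf,
        row_names=rows,
    )


def fingerprint_pca(
    change_matrix: pd.DataFrame,
    log_ratio: bool = True,
    center: bool = True,
    scale: bool = False,
) -> PCAResult:
    """PCA of a relative-change matrix, log-transforming ratios by default."""
    matrix = change_matrix.copy()
    if log_ratio:
        if (matrix.to_numpy() <= 0).any():
            raise ValueError("log-ratio transform requires strictly positive ratios")
        matrix = np.log(matrix)
    return pca(matrix, center=center, scale=scale)


def fingerprint_distance(profile_a, profile_b) -> float:
    """Cosine dissimilarity between two log-ratio fingerprints.

    0 for proportional profiles, 2 for profiles with opposite log-ratios.
    Inputs are relative-change (ratio) vectors over the same peak panel.
    """
    a = np.log(np.asarray(profile_a, dtype=float))
    b = np.log(np.asarray(profile_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("profiles must cover the same peak panel")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero log-ratio profile has no direction")
    return float(1.0 - np.dot(a, b) / (na * nb))


def half_plane_separable(points_a: np.ndarray, points_b: np.ndarray, n_angles: int = 720) -> bool:
    """Whether a line through the origin separates two 2-D point sets.

    Used to test that different toxins' treatment arrows occupy distinct
    half-planes of the (PC1, PC2) loading plot.
    """
    a = np.atleast_2d(points_a)
    b = np.atleast_2d(points_b)
    angles = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    directions = np.column_stack([np.cos(angles), np.sin(angles)])
    proj_a = a @ directions.T
    proj_b = b @ directions.T
    return bool(np.any((proj_a.min(axis=0) > 0) & (proj_b.max(axis=0) < 0)))
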