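"""Full-principal-component transformation of flattened RP images.

The model diagonalizes C = X^T X (uncentered by default — no mean
subtraction) and projects F = X W onto all nonzero components, an
orthogonal, information-preserving transform. The pixel-by-pixel matrix
C (resolution^4 entries) is never materialized: the thin SVD of X solves
the equivalent i x i dual problem.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class PCAModel:
    """Eigenvectors of C = X^T X with descending eigenvalues.

    ``W`` is m x r with orthonormal columns; ``eigenvalues`` are the r
    retained eigenvalues of C, sorted descending. ``mean`` is nonzero
    only when fit with ``center=True``.
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    center: bool = False
    mean: np.ndarray | None = None

    @property
    def r(self) -> int:
        return self.W.shape[1]

    @property
    def m(self) -> int:
        return self.W.shape[0]


def fit_pca(
    X: np.ndarray,
    center: bool = False,
    n_components: int | None = None,
) -> PCAModel:
    """Fit the transform on an images-by-pixels matrix.

    Computed via thin SVD of X (the i x i dual route): right singular
    vectors are eigenvectors of X^T X with eigenvalues = squared singular
    values. Retains the full nonzero spectrum (r = rank) unless
    ``n_components`` truncates explicitly.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("X must be a nonempty 2-D matrix")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to fit")
    mean = None
    if center:
        mean = X.mean(axis=0)
        X = X - mean
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    r = rank if n_components is None else min(n_components, rank)
    if r == 0:
        raise ValueError("X has rank 0 (all-zero matrix)")
    return PCAModel(
        W=Vt[:r].T.copy(),
        eigenvalues=(s[:r] ** 2).copy(),
        center=center,
        mean=mean,
    )


def apply_pca(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project rows of X: F = X W (after centering if the model was fit
    centered). With the full nonzero spectrum this is an isometry on the
    row space and X is recoverable as F W^T."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.m:
        raise ValueError(
            f"X must have {model.m} columns to match the model, "
            f"got shape {X.shape}"
        )
    if model.center and model.mean is not None:
        X = X - model.mean
    return X @ model.W


def inverse_pca(model: PCAModel, F: np.ndarray) -> np.ndarray:
    """Reconstruct X ≈ F W^T (exact for full-rank models)."""
    X = np.asarray(F, dtype=float) @ model.W.T
    if model.center and model.mean is not None:
        X = X + model.mean
    return X


def reshape_to_images(
    F: np.ndarray,
    resolution: int,
    rescale: bool = True,
):
    """Fold each feature row into a resolution x resolution image.

    Rows shorter than resolution^2 (rank < m) are zero-padded. With
    ``rescale`` each image is min-max scaled to [0, 1]; a constant row
    maps to the all-zero image by convention.
    """
    from gaitrp.recurrence import RPImage

    F = np.atleast_2d(np.asarray(F, dtype=float))
    m = resolution * resolution
    if F.shape[1] > m:
        raise ValueError(
            f"feature length {F.shape[1]} exceeds resolution^2 = {m}"
        )
    if F.shape[1] < m:
        F = np.pad(F, ((0, 0), (0, m - F.shape[1])))
    images = []
    for row in F:
        img = row.reshape(resolution, resolution)
        if rescale:
            lo, hi = img.min(), img.max()
            img = np.zeros_like(img) if hi - lo == 0 else (img - lo) / (hi - lo)
        images.append(RPImage(pixels=img, meta={"stage": "pca"}))
    return images


def save_model(model: PCAModel, path: str | Path) -> Path:
    path = Path(path)
    np.savez(
        path,
        W=model.W,
        eigenvalues=model.eigenvalues,
        center=np.array(model.center),
        mean=model.mean if model.mean is not None else np.zeros(0),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_model(path: str | Path) -> PCAModel:
    with np.load(path) as z:
        mean = z["mean"]
        return PCAModel(
            W=z["W"],
            eigenvalues=z["eigenvalues"],
            center=bool(z["center"]),
            mean=mean if mean.size else None,
        )
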