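"""Principal component analysis via the explicit covariance route.

The steps are spelled out rather than delegated so the fitted model is
auditable: mean-center the sample-by-channel matrix X, form the
covariance V = XᵀX / (N−1), eigendecompose the symmetric V, and keep the
eigenvectors of the d largest eigenvalues as the projection basis. An
independent SVD-based computation serves as a cross-check in the test
suite, never as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError, SizeError

_EIG_CLAMP = 1e-10


@dataclass
class PCAModel:
    """Fitted PCA basis.

    ``components`` columns are unit eigenvectors ordered by descending
    eigenvalue; each column's largest-magnitude entry is positive (a
    deterministic sign convention — eigenvectors are only defined up to
    sign).
    """

    mean: np.ndarray
    components: np.ndarray  # (n_features, n_components), columns orthonormal
    eigenvalues: np.ndarray  # descending, >= 0
    n_fit: int

    @property
    def n_features(self) -> int:
        return self.components.shape[0]


def fit_pca(features: np.ndarray) -> PCAModel:
    """Fit PCA on a sample-by-channel matrix.

    Uses the unbiased 1/(N−1) covariance normalization. Eigenvalues that
    come out slightly negative from floating-point round-off are clamped
    to zero.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise SizeError(f"need a 2-D sample-by-channel matrix, got shape {X.shape}")
    n = X.shape[0]
    if n < 2:
        raise SizeError(f"need >= 2 samples to fit PCA, got {n}")
    mean = X.mean(axis=0)
    Xc = X - mean
    V = Xc.T @ Xc / (n - 1)
    evals, evecs = np.linalg.eigh(V)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals.size and evals[-1] < -_EIG_CLAMP:
        raise SizeError(
            f"covariance eigenvalue {evals[-1]:.3e} below clamp tolerance"
        )
    evals = np.clip(evals, 0.0, None)
    # deterministic sign: largest-magnitude entry of each component positive
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])])
    flip[flip == 0] = 1.0
    evecs = evecs * flip
    return PCAModel(mean=mean, components=evecs, eigenvalues=evals, n_fit=n)


def pca_transform(model: PCAModel, features: np.ndarray, d: int) -> np.ndarray:
    """Project onto the top ``d`` components: Y = (X − mean) · W[:, :d].

    Held-out data must be projected with the training-fit mean and basis;
    this function never refits.
    """
    X = np.asarray(features, dtype=float)
    if not 1 <= d <= model.components.shape[1]:
        raise ParameterError(
            f"d={d} outside 1..{model.components.shape[1]} fitted components"
        )
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ParameterError(
            f"feature column count {X.shape[1] if X.ndim == 2 else X.shape} "
            f"does not match model ({model.n_features})"
        )
    return (X - model.mean) @ model.components[:, :d]


def pca_inverse(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Map d-dimensional scores back to the original feature space."""
    Y = np.asarray(scores, dtype=float)
    d = Y.shape[1]
    return Y @ model.components[:, :d].T + model.mean


def save_pca(model: PCAModel, path: str | Path) -> None:
    """Serialize the model as delimited text (mean / eigenvalues / basis)."""
    with open(path, "w") as fh:
        fh.write(f"# gammase pca v1 n_fit {model.n_fit}\n")
        fh.write("mean " + " ".join("%.17g" % v for v in model.mean) + "\n")
        fh.write(
            "eigenvalues " + " ".join("%.17g" % v for v in model.eigenvalues) + "\n"
        )
        for row in model.components:
            fh.write(" ".join("%.17g" % v for v in row) + "\n")


def load_pca(path: str | Path) -> PCAModel:
    with open(path) as fh:
        header = fh.readline().split()
        n_fit = int(header[-1])
        mean = np.asarray(fh.readline().split()[1:], dtype=float)
        eigenvalues = np.asarray(fh.readline().split()[1:], dtype=float)
        components = np.loadtxt(fh, ndmin=2)
    return PCAModel(mean=mean, components=components,
                    eigenvalues=eigenvalues, n_fit=n_fit)
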