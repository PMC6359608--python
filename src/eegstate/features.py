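"""Sub-band statistical features and principal-component reduction.

Each segment is summarised by ten numbers: the mean and the population
standard deviation of the wavelet coefficients in each of the five bands,
in fixed order (gamma, beta, alpha, theta, delta).  By default the mean is
taken over absolute coefficient values — sub-band means of raw zero-mean
coefficients carry little signal, while |c| tracks band energy — and the
standard deviation over raw values; both conventions are switchable.

PCA is implemented directly as an eigendecomposition of the feature
covariance so the whole pipeline is self-contained; fitted models keep the
centering vector and orthonormal loadings needed to project held-out data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sym_wavelet import BAND_ORDER, DecompositionResult

#: Feature names in vector order.
FEATURE_NAMES = tuple(
    f"{stat}_{band}" for band in ("gamma", "beta", "alpha", "theta", "delta")
    for stat in ("mean", "std")
)


@dataclass
class FeatureVector:
    """The 10-dimensional (mean, std) x 5-band descriptor of one segment."""

    values: np.ndarray
    abs_mode: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (10,):
            raise ValueError(f"expected 10 features, got shape {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite feature values")
        if (self.values[1::2] < 0).any():
            raise ValueError("standard-deviation features must be nonnegative")


def subband_stats(dec: DecompositionResult, abs_mode: bool = True) -> FeatureVector:
    """Mean and population std per band, ordered gamma..delta.

    With ``abs_mode`` the mean is of |coefficients| (avoiding cancellation
    of positive and negative excursions); the std is always of the raw
    coefficients.
    """
    sets = dec.coefficient_sets()
    values = []
    for tag, coeffs in zip(BAND_ORDER, sets):
        c = np.asarray(coeffs, dtype=float)
        if c.size == 0:
            raise ValueError(f"band {tag}: empty coefficient set")
        mean = np.abs(c).mean() if abs_mode else c.mean()
        values.extend([mean, c.std()])
    return FeatureVector(values=np.array(values), abs_mode=abs_mode)


def feature_matrix(decs, abs_mode: bool = True) -> np.ndarray:
    """Stack :func:`subband_stats` over decompositions into an (n, 10) matrix."""
    return np.vstack([subband_stats(d, abs_mode=abs_mode).values for d in decs])


@dataclass
class PCAModel:
    """Principal components of a feature matrix.

    ``component_matrix`` holds orthonormal loadings as rows (leading
    eigenvectors of the covariance); ``explained_variance_ratio`` the
    corresponding eigenvalue fractions, nonincreasing.
    """

    component_matrix: np.ndarray
    center: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.component_matrix.shape[0]


def pca_fit(X: np.ndarray, variance_keep: float = 0.95) -> PCAModel:
    """Fit PCA keeping the fewest components reaching ``variance_keep``.

    Eigendecomposition of the (population) covariance of the centered
    rows; components ordered by decreasing eigenvalue.  Eigenvector signs
    are fixed so each row's largest-magnitude entry is positive, making
    fits reproducible.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not 0 < variance_keep <= 1:
        raise ValueError(f"variance_keep must lie in (0, 1], got {variance_keep}")
    center = X.mean(axis=0)
    Xc = X - center
    cov = (Xc.T @ Xc) / X.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    total = eigvals.sum()
    if total <= 0:
        raise ValueError("rank-0 input: features have no variance")
    ratio = eigvals / total
    k = int(np.searchsorted(np.cumsum(ratio), variance_keep - 1e-12) + 1)
    k = min(k, len(eigvals))
    comps = eigvecs[:, :k].T.copy()
    # deterministic sign: largest-|.| entry of each loading made positive
    for row in comps:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1
    return PCAModel(component_matrix=comps, center=center,
                    explained_variance=eigvals[:k],
                    explained_variance_ratio=ratio[:k])


def pca_transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project rows of ``X`` onto the model's components."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.center.shape[0]:
        raise ValueError(
            f"feature count {X.shape[1]} does not match model "
            f"({model.center.shape[0]})"
        )
    return (X - model.center) @ model.component_matrix.T


def pca_inverse_transform(model: PCAModel, Z: np.ndarray) -> np.ndarray:
    """Map component scores back to (approximate) feature space."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != model.n_components:
        raise ValueError(
            f"component count {Z.shape[1]} does not match model "
            f"({model.n_components})"
        )
    return Z @ model.component_matrix + model.center
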