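"""Principal-component retention by cABC analysis of eigenvalues.

How many principal components to keep is usually decided heuristically
(Kaiser-Guttman eigenvalue > 1, 95% explained variance, scree-plot
elbows).  cABC analysis instead treats the eigenvalue spectrum as an
importance vector and computes the retained set: the first cABC level
keeps the "important few" components, and the recursion shrinks the set
further until the remaining eigenvalues are uniformly distributed.

By default the spectrum comes from the covariance matrix of the raw
feature matrix (equivalently, PCA without standardization); correlation
PCA (standardize-then-decompose) is available with ``standardize=True``,
with zero-variance columns excluded from standardization and given zero
loadings.  Retained components reconstruct the data by zeroing the scores
of all other components and back-transforming into the original space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import ItemSet
from .recursion import RecursionConfig, RecursionTrace, recursive_cabc

__all__ = [
    "EigenSpectrum",
    "ComponentSelection",
    "eigen_spectrum",
    "kaiser_guttman_count",
    "cabc_component_selection",
    "reconstruct",
]


@dataclass(frozen=True)
class EigenSpectrum:
    """Eigendecomposition of a feature matrix, ready for back-transformation.

    ``components`` has one column per retained eigenvector (d x k);
    ``mean`` and ``scale`` are the per-feature centering/scaling applied
    before projection (scale is all ones for covariance PCA).
    """

    eigenvalues: np.ndarray          # nonincreasing, >= 0
    components: np.ndarray           # (d, k) eigenvectors as columns
    mean: np.ndarray                 # (d,)
    scale: np.ndarray                # (d,)
    standardized: bool

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def item_set(self) -> ItemSet:
        labels = tuple(f"PC{i + 1}" for i in range(self.n_components))
        return ItemSet(labels, self.eigenvalues)


def eigen_spectrum(data, *, standardize: bool = False) -> EigenSpectrum:
    """Eigendecomposition of the feature covariance (or correlation) matrix.

    Parameters
    ----------
    data
        Numeric matrix, cases x features, with at least three columns of
        nonzero variance.
    standardize
        If True, z-score each non-constant column first (correlation PCA);
        constant columns are excluded from the decomposition and assigned
        zero loadings.  If False (default), decompose the covariance
        matrix of the raw data.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a 2-D cases x features matrix")
    if np.any(np.isnan(X)):
        raise ValueError("data must not contain NaN")
    d = X.shape[1]
    sd = X.std(axis=0, ddof=1)
    if int((sd > 0).sum()) < 3:
        raise ValueError("need at least 3 features with nonzero variance")

    mean = X.mean(axis=0)
    if standardize:
        live = sd > 0
        scale = np.where(live, sd, 1.0)
        Z = (X[:, live] - mean[live]) / sd[live]
        C = np.corrcoef(Z, rowvar=False)
        w, v = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        eig = np.clip(w[order], 0.0, None)
        comps = np.zeros((d, eig.size))
        comps[live, :] = v[:, order]
    else:
        scale = np.ones(d)
        C = np.cov(X, rowvar=False, ddof=1)
        w, v = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        eig = np.clip(w[order], 0.0, None)
        comps = v[:, order]
    return EigenSpectrum(eigenvalues=eig, components=comps, mean=mean,
                         scale=scale, standardized=standardize)


def kaiser_guttman_count(spectrum: EigenSpectrum) -> int:
    """Number of eigenvalues strictly greater than 1."""
    return int(np.sum(spectrum.eigenvalues > 1.0))


@dataclass(frozen=True)
class ComponentSelection:
    """Retained component indices per method, with the recursion trace."""

    kaiser_guttman: np.ndarray       # indices of eigenvalues > 1
    cabc_levels: tuple               # per-level index arrays, outermost first
    trace: RecursionTrace

    def level(self, depth: int) -> np.ndarray:
        """Retained indices after `depth` cABC levels (0 = Kaiser-Guttman)."""
        if depth == 0:
            return self.kaiser_guttman
        return self.cabc_levels[depth - 1]


def cabc_component_selection(spectrum: EigenSpectrum,
                             config: Optional[RecursionConfig] = None
                             ) -> ComponentSelection:
    """Select components to retain by recursive cABC on the eigenvalues."""
    trace = recursive_cabc(spectrum.item_set(), config)
    # eigenvalues are sorted descending, so each "A" set is a leading block
    levels = tuple(
        np.array(sorted(int(lab[2:]) - 1 for lab in lvl.set_a))
        for lvl in trace.levels
    )
    kg = np.flatnonzero(spectrum.eigenvalues > 1.0)
    return ComponentSelection(kaiser_guttman=kg, cabc_levels=levels, trace=trace)


def reconstruct(data, spectrum: EigenSpectrum,
                retained: Sequence[int]) -> np.ndarray:
    """Back-transform data keeping only the retained components' scores.

    The data are centered/scaled as during the decomposition, projected
    onto all components, the scores of the non-retained components are
    overwritten with zeros, and the result is back-transformed into the
    original data space.  Output shape equals input shape.
    """
    retained = np.asarray(retained, dtype=int)
    if retained.size == 0:
        raise ValueError("retained component set must not be empty")
    if retained.min() < 0 or retained.max() >= spectrum.n_components:
        raise IndexError("retained indices outside the component range")
    X = np.asarray(data, dtype=float)
    Z = (X - spectrum.mean) / spectrum.scale
    V = spectrum.components[:, retained]
    scores = Z @ V
    return (scores @ V.T) * spectrum.scale + spectrum.mean
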