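"""Standardisation, EM-PCA imputation, distances and non-metric MDS.

The ordination stage takes a samples x variables feature matrix (biomarker
activities plus viability), z-scores each column, fills missing cells with an
iterative low-rank (EM-PCA) scheme, and embeds the Euclidean distance matrix
in k = 2 dimensions by non-metric MDS, minimising Kruskal stress-1

    stress1 = sqrt( sum (dhat_ij - d_ij)^2 / sum d_ij^2 )

where dhat is the monotone (isotonic) regression of the configuration
distances d on the ranks of the input dissimilarities (primary treatment of
ties: tied dissimilarities are free to take different dhat). Optimisation
alternates isotonic regression with a Guttman-transform majorization update,
from one deterministic classical-scaling (PCoA) start plus seeded random
starts; the lowest-stress configuration is returned, centred and rotated to
its principal axes. Stress below 0.2 is conventionally an acceptable fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import isotonic_regression


class StructuralError(ValueError):
    """Matrix shape/missingness precludes the requested operation."""


def _as_matrix(matrix) -> tuple[np.ndarray, pd.DataFrame | None]:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), matrix
    return np.asarray(matrix, dtype=float), None


def _wrap_like(values: np.ndarray, template: pd.DataFrame | None):
    if template is None:
        return values
    return pd.DataFrame(values, index=template.index, columns=template.columns)


def zscore(matrix):
    """Column-wise z-scoring (mean 0, sample SD 1) over non-missing entries.

    Constant columns map to all zeros with a warning; columns with fewer
    than 2 observed values are an error.
    """
    import warnings

    x, template = _as_matrix(matrix)
    x = x.copy()
    for j in range(x.shape[1]):
        col = x[:, j]
        obs = col[~np.isnan(col)]
        if obs.size < 2:
            name = template.columns[j] if template is not None else j
            raise ValueError(f"column {name!r} has fewer than 2 observed values")
        sd = obs.std(ddof=1)
        if sd == 0:
            warnings.warn(
                f"constant column {template.columns[j] if template is not None else j}; "
                "z-scores set to 0",
                stacklevel=2,
            )
            x[:, j] = np.where(np.isnan(col), np.nan, 0.0)
        else:
            x[:, j] = (col - obs.mean()) / sd
    return _wrap_like(x, template)


def impute_missing(matrix, n_components: int = 2, tol: float = 1e-6, max_iter: int = 500):
    """Iterative low-rank (EM-PCA) imputation of missing cells.

    Missing cells start at their column means; the algorithm then alternates
    a rank-``n_components`` SVD reconstruction (of the column-centred
    matrix) with reimposition of the observed cells, until the largest
    absolute change over imputed cells drops below ``tol``. Observed cells
    are returned unchanged.
    """
    x, template = _as_matrix(matrix)
    x = x.copy()
    mask = np.isnan(x)
    if not mask.any():
        return _wrap_like(x, template)
    if mask.all(axis=1).any():
        raise StructuralError("a row has no observed values")
    if mask.all(axis=0).any():
        raise StructuralError("a column has no observed values")
    if n_components >= min(x.shape):
        raise ValueError("n_components must be < min(n_rows, n_cols)")
    col_means = np.nanmean(x, axis=0)
    x[mask] = np.take(col_means, np.where(mask)[1])
    for _ in range(max_iter):
        mu = x.mean(axis=0)
        u, s, vt = np.linalg.svd(x - mu, full_matrices=False)
        recon = mu + (u[:, :n_components] * s[:n_components]) @ vt[:n_components]
        delta = np.max(np.abs(recon[mask] - x[mask]))
        x[mask] = recon[mask]
        if delta < tol:
            break
    return _wrap_like(x, template)


def euclidean_distances(matrix) -> np.ndarray:
    """Symmetric Euclidean distance matrix; rejects missing cells."""
    x, _ = _as_matrix(matrix)
    if np.isnan(x).any():
        raise ValueError("matrix contains missing cells; run impute_missing first")
    return squareform(pdist(x, metric="euclidean"))


def classify_stress(stress: float) -> str:
    """'acceptable' below the conventional 0.2 cutoff, else 'poor'."""
    if stress < 0:
        raise ValueError("stress must be nonnegative")
    return "acceptable" if stress < 0.2 else "poor"


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def _stress_and_disparities(
    d_flat: np.ndarray, order: np.ndarray
) -> tuple[float, np.ndarray]:
    """Kruskal stress-1 and isotonic disparities for configuration distances."""
    dhat_sorted = isotonic_regression(d_flat[order])
    dhat = np.empty_like(d_flat)
    dhat[order] = dhat_sorted
    denom = float(np.sum(d_flat**2))
    if denom == 0:
        return np.inf, dhat
    return float(np.sqrt(np.sum((dhat - d_flat) ** 2) / denom)), dhat


@dataclass
class NMDSResults:
    """Best embedding found: coordinates, stress-1 and search metadata."""

    coordinates: np.ndarray
    stress: float
    best_start: int
    n_starts: int
    converged: bool
    n_components: int

    @property
    def classification(self) -> str:
        return classify_stress(self.stress)

    def summary(self) -> str:
        return (
            f"NMDS (k={self.n_components}, {self.n_starts} starts)\n"
            f"  stress-1 = {self.stress:.4f} ({self.classification})\n"
            f"  best start = {self.best_start} "
            f"({'classical-MDS' if self.best_start == 0 else 'random'}), "
            f"converged = {self.converged}"
        )

    def plot(self, groups=None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        xy = self.coordinates
        if groups is None:
            ax.scatter(xy[:, 0], xy[:, 1], s=20)
        else:
            groups = np.asarray(groups)
            for g in pd.unique(groups):
                sel = groups == g
                ax.scatter(xy[sel, 0], xy[sel, 1], s=20, label=str(g))
            ax.legend(fontsize=8)
        ax.set_xlabel("NMDS1")
        ax.set_ylabel("NMDS2")
        ax.set_title(f"stress = {self.stress:.4f}")
        return ax


class NMDS:
    """Non-metric MDS of a dissimilarity matrix (Kruskal stress-1).

    Parameters
    ----------
    dissimilarities : (n, n) array
        Symmetric nonnegative dissimilarity matrix with zero diagonal.
    n_components : int
        Embedding dimension (2 by default).
    n_starts : int
        Total starts: one classical-scaling start plus ``n_starts - 1``
        seeded random starts. Start j draws from substream (seed, j), so
        enlarging ``n_starts`` only adds starts and can never raise the
        returned stress.
    seed : int
        Seed for the random starts.
    tol, max_iter :
        Inner convergence: stop when stress decreases by less than ``tol``
        (default 1e-7) or after ``max_iter`` (default 300) iterations.
    """

    def __init__(
        self,
        dissimilarities,
        *,
        n_components: int = 2,
        n_starts: int = 100,
        seed: int = 0,
        tol: float = 1e-7,
        max_iter: int = 300,
    ):
        d = np.asarray(dissimilarities, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("dissimilarities must be a square matrix")
        if not np.allclose(d, d.T):
            raise ValueError("dissimilarities must be symmetric")
        if d.shape[0] < n_components + 2:
            raise ValueError("too few points for a meaningful embedding")
        if not d[np.triu_indices_from(d, k=1)].any():
            raise ValueError("all dissimilarities are zero; nothing to embed")
        self.dissimilarities = d
        self.n_components = int(n_components)
        self.n_starts = int(n_starts)
        self.seed = int(seed)
        self.tol = float(tol)
        self.max_iter = int(max_iter)

    def _run_single(self, x0: np.ndarray, delta_flat: np.ndarray):
        n = self.dissimilarities.shape[0]
        iu = np.triu_indices(n, k=1)
        x = x0 - x0.mean(axis=0)
        prev = np.inf
        best_stress, best_x = np.inf, x
        converged = False
        for _ in range(self.max_iter):
            d_flat = pdist(x)
            # primary tie treatment: tied dissimilarities are ordered by the
            # current configuration distances, so PAVA leaves them
            # unconstrained relative to one another
            order = np.lexsort((d_flat, delta_flat))
            stress, dhat = _stress_and_disparities(d_flat, order)
            if stress < best_stress:
                best_stress, best_x = stress, x
            if prev - stress < self.tol:
                converged = True
                break
            prev = stress
            # Guttman transform with unit weights
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d_flat > 0, dhat / d_flat, 0.0)
            b = np.zeros((n, n))
            b[iu] = -ratio
            b = b + b.T
            np.fill_diagonal(b, -b.sum(axis=1))
            x = (b @ x) / n
            x -= x.mean(axis=0)
        return best_stress, best_x, converged

    def fit(self) -> NMDSResults:
        d = self.dissimilarities
        n = d.shape[0]
        delta_flat = d[np.triu_indices(n, k=1)]

        best = None
        converged_any = False
        for start in range(self.n_starts):
            if start == 0:
                x0 = _classical_mds(d, self.n_components)
                # the classical start itself is a candidate: evaluate before
                # optimising so the contract "returned stress <= classical
                # start stress" holds even in pathological cases
                d0 = pdist(x0)
                s0, _ = _stress_and_disparities(d0, np.lexsort((d0, delta_flat)))
                if best is None or s0 < best[0]:
                    best = (s0, x0, 0)
            else:
                rng = np.random.default_rng((self.seed, start))
                scale = delta_flat.mean()
                x0 = rng.standard_normal((n, self.n_components)) * scale
            stress, x, conv = self._run_single(x0, delta_flat)
            converged_any = converged_any or conv
            if best is None or stress < best[0]:
                best = (stress, x, start)
        stress, x, start = best
        x = x - x.mean(axis=0)
        # principal-axis rotation with a deterministic sign convention
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        x = x @ vt.T
        for j in range(x.shape[1]):
            if x[np.argmax(np.abs(x[:, j])), j] < 0:
                x[:, j] = -x[:, j]
        return NMDSResults(x, float(stress), start, self.n_starts, converged_any, self.n_components)


def nmds(dissimilarities, **kwargs) -> NMDSResults:
    """One-call convenience: ``NMDS(dissimilarities, **kwargs).fit()``."""
    return NMDS(dissimilarities, **kwargs).fit()
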