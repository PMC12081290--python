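"""Population geometry: embeddings + Procrustes, LDA silhouettes, and TCA.

Representational similarity between mazes is measured by reducing the
neuronal dimension of epoch-averaged responses to three components (PCA or
Isomap with 19 neighbors, fit on both mazes jointly), then computing the
Procrustes distance — the residual sum of squared distances between
corresponded points after optimal translation, uniform scaling and
rotation.  Trial-type clustering quality is quantified by projecting
trials through PCA (30 components) and canonical discriminant (LDA) axes
and taking silhouette values on the first two canonical dimensions.
Across-trial structure is decomposed with non-negative canonical polyadic
("tensor component") analysis of the units x epochs x trials tensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _scipy_procrustes
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.manifold import Isomap
from sklearn.metrics import silhouette_samples


@dataclass
class PopulationTensor:
    """N units x T epochs x K trials of firing rates, with trial labels."""

    values: np.ndarray  # (N, T, K)
    trial_labels: pd.DataFrame  # K rows; columns include maze_id, type_key

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("tensor must be 3-dimensional (units, epochs, trials)")
        if np.any(self.values < 0):
            raise ValueError("firing-rate tensor must be nonnegative")
        if len(self.trial_labels) != self.values.shape[2]:
            raise ValueError("trial_labels must have one row per trial")

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            g = f.create_group("trial_labels")
            for col in self.trial_labels.columns:
                data = self.trial_labels[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                g.create_dataset(col, data=data)

    @classmethod
    def load_h5(cls, path) -> "PopulationTensor":
        import h5py

        with h5py.File(path, "r") as f:
            values = f["values"][()]
            cols = {}
            for col, ds in f["trial_labels"].items():
                arr = ds[()]
                if arr.dtype.kind == "S":
                    arr = arr.astype(str)
                cols[col] = arr
        return cls(values, pd.DataFrame(cols))


def embed_population(responses: np.ndarray, maze_labels: np.ndarray,
                     method: str = "linear", n_components: int = 3,
                     n_neighbors: int = 19) -> dict[str, np.ndarray]:
    """Shared low-dimensional embedding of per-maze population responses.

    ``responses`` is units x points (each point one trial-epoch or
    condition-epoch response vector); ``maze_labels`` assigns each point
    to a maze.  The neuronal dimension is reduced to ``n_components``
    (PCA for ``method="linear"``, Isomap with ``n_neighbors`` for
    ``method="nonlinear"``) on all points jointly, so both mazes live in
    the same subspace; returns {maze_id: (n_points, n_components)}.
    """
    responses = np.asarray(responses, dtype=float)
    maze_labels = np.asarray(maze_labels)
    if responses.shape[1] != maze_labels.size:
        raise ValueError("one maze label per response column required")
    points = responses.T  # samples in neuron space
    if method == "linear":
        embedded = PCA(n_components=n_components).fit_transform(points)
    elif method == "nonlinear":
        embedded = Isomap(n_neighbors=n_neighbors,
                          n_components=n_components).fit_transform(points)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {str(m): embedded[maze_labels == m] for m in pd.unique(maze_labels)}


def procrustes_dissimilarity(points1: np.ndarray, points2: np.ndarray) -> float:
    """Residual sum of squared distances after Procrustes alignment.

    Both point sets are centered and scaled to unit Frobenius norm, then
    optimally rotated onto each other; the returned disparity is zero
    exactly when the sets differ only by translation, uniform scaling and
    rotation/reflection.
    """
    p1 = np.asarray(points1, dtype=float)
    p2 = np.asarray(points2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("point sets must have identical shape with correspondence")
    if np.allclose(p1, p1.mean(axis=0)) or np.allclose(p2, p2.mean(axis=0)):
        raise ValueError("degenerate (all-coincident) point set")
    _, _, disparity = _scipy_procrustes(p1, p2)
    return float(disparity)


def lda_cluster_silhouette(trial_matrix: np.ndarray, labels: np.ndarray,
                           n_pcs: int = 30, n_canonical: int = 2
                           ) -> tuple[dict[str, float], np.ndarray]:
    """Canonical-variable clustering of trials and per-type silhouettes.

    ``trial_matrix`` is K trials x (N units * T epochs).  PCA reduces to
    ``n_pcs`` scores, canonical discriminant variables are extracted with
    the trial labels as groups (the MANOVA canonical axes), and
    silhouette values are computed on the first ``n_canonical``
    dimensions.  Returns (per-label mean silhouettes, K x n_canonical
    canonical scores).  A singular within-group scatter is regularized by
    LDA's SVD solver.
    """
    X = np.asarray(trial_matrix, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] != labels.size:
        raise ValueError("one label per trial row required")
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two trial groups")
    n_pcs = min(n_pcs, X.shape[0] - 1, X.shape[1])
    scores = PCA(n_components=n_pcs).fit_transform(X)
    lda = LinearDiscriminantAnalysis(solver="svd")
    canonical = lda.fit_transform(scores, labels)[:, :n_canonical]
    sil = silhouette_samples(canonical, labels)
    means = {str(u): float(sil[labels == u].mean()) for u in uniq}
    return means, canonical


# ---------------------------------------------------------------------------
# Non-negative canonical polyadic (tensor component) decomposition
# ---------------------------------------------------------------------------

def _khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a[:, None, :] * b[None, :, :]).reshape(-1, a.shape[1])


def _unfold(t: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(t, mode, 0).reshape(t.shape[mode], -1)


def _ncp_fit(tensor: np.ndarray, rank: int, rng: np.random.Generator,
             n_iter: int = 300, tol: float = 1e-7,
             init: list[np.ndarray] | None = None
             ) -> tuple[list[np.ndarray], float]:
    """One multiplicative-updates run of non-negative CP."""
    eps = 1e-12
    scale = tensor.mean() or 1.0
    if init is None:
        factors = [rng.uniform(0.1, 1.0, size=(dim, rank)) * scale ** (1 / 3)
                   for dim in tensor.shape]
    else:
        factors = [np.maximum(f.copy(), eps) for f in init]
    norm_x = np.linalg.norm(tensor)
    last = np.inf
    for it in range(n_iter):
        for mode in range(3):
            others = [factors[m] for m in range(3) if m != mode]
            kr = _khatri_rao(others[0], others[1])  # matches unfold column order
            Xn = _unfold(tensor, mode)
            numer = Xn @ kr
            gram = np.ones((rank, rank))
            for f in others:
                gram = gram * (f.T @ f)
            denom = factors[mode] @ gram + eps
            factors[mode] = factors[mode] * numer / denom
        if it % 10 == 9 or it == n_iter - 1:
            err = _reconstruction_error(tensor, factors, norm_x)
            if last - err < tol:
                break
            last = err
    return factors, _reconstruction_error(tensor, factors, norm_x)


def _reconstruct(factors: list[np.ndarray]) -> np.ndarray:
    a, b, c = factors
    return np.einsum("ir,jr,kr->ijk", a, b, c)


def _reconstruction_error(tensor, factors, norm_x) -> float:
    return float(np.linalg.norm(tensor - _reconstruct(factors)) / (norm_x or 1.0))


def tca_decompose(tensor: PopulationTensor | np.ndarray, rank: int,
                  n_restarts: int = 10, seed: int | np.random.Generator = 0,
                  n_iter: int = 300) -> tuple[list[np.ndarray], float]:
    """Best-of-restarts non-negative CP decomposition of the trial tensor.

    Returns ``(factors, relative_error)`` where factors are the
    (units x rank), (epochs x rank) and (trials x rank) non-negative
    loading matrices and the error is the relative Frobenius residual of
    the reconstruction.  The objective is nonconvex; ``n_restarts``
    independent multiplicative-update runs are fit and the best kept,
    which empirically preserves the error-nonincreasing-in-rank nesting
    property.  Deterministic given ``seed``.
    """
    values = tensor.values if isinstance(tensor, PopulationTensor) else np.asarray(tensor, float)
    if values.ndim != 3:
        raise ValueError("tensor must be 3-dimensional")
    if np.any(values < 0):
        raise ValueError("tensor must be nonnegative")
    if rank < 1:
        raise ValueError("rank must be positive")
    if rank >= min(values.shape):
        import warnings

        warnings.warn(f"rank {rank} >= smallest tensor dimension {min(values.shape)}",
                      stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # Grow the rank one component at a time: at each rank take the best of
    # ``n_restarts`` random initializations and one fit warm-started from
    # the previous rank's best solution padded with a small random column.
    # The multiplicative updates never increase the objective, so the
    # returned error is nonincreasing in rank, and because the random
    # draws per rank stage do not depend on the target rank, calls at
    # different ranks with the same seed share the chain prefix.
    pad = 1e-3 * (values.mean() or 1.0) ** (1 / 3)
    best_factors, best_err = None, np.inf
    for r in range(1, rank + 1):
        candidates = []
        for _ in range(n_restarts):
            candidates.append(_ncp_fit(values, r, rng, n_iter=n_iter))
        if best_factors is not None:
            init = [np.hstack([f, pad * rng.uniform(0.1, 1.0, size=(f.shape[0], 1))])
                    for f in best_factors]
            candidates.append(_ncp_fit(values, r, rng, n_iter=n_iter, init=init))
        best_factors, best_err = min(candidates, key=lambda c: c[1])
    return best_factors, best_err


def factor_congruence(factors_a: list[np.ndarray],
                      factors_b: list[np.ndarray]) -> float:
    """Mean best-matching congruence between two CP factorizations.

    Components are matched by maximizing the product over modes of the
    cosine similarity (Tucker congruence) via the assignment problem;
    returns the mean matched congruence in [0, 1] — near 1 when the
    factorizations agree up to permutation and scaling.
    """
    from scipy.optimize import linear_sum_assignment

    def unit(f):
        return f / (np.linalg.norm(f, axis=0, keepdims=True) + 1e-12)

    rank = factors_a[0].shape[1]
    sim = np.ones((rank, rank))
    for fa, fb in zip(factors_a, factors_b):
        sim = sim * np.abs(unit(fa).T @ unit(fb))
    row, col = linear_sum_assignment(-sim)
    return float(sim[row, col].mean())
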