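"""Behavioral cartography: low-dimensional maps of the excursion landscape.

Embeds the scaled excursion feature matrix in 2 or 3 dimensions so modules
and non-modular excursions can be visualized as a behavioral landscape.
The preferred backend is PHATE when the ``phate`` package is importable;
otherwise a built-in diffusion-map embedding is used (adaptive Gaussian
kernel on k-nearest-neighbor distances, symmetrized, with diffusion-scaled
eigenvector coordinates). Both are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .features import FeatureMatrix
from .module_detection import ModuleCatalog

__all__ = ["EmbeddingResult", "embed_excursions", "diffusion_map",
           "plot_embedding"]


@dataclass
class EmbeddingResult:
    coords: pd.DataFrame        # CIMAR-indexed, columns dim1..dimN
    params: dict = field(default_factory=dict)
    seed: int = 0
    backend: str = "diffusion-map"

    def with_labels(self, catalog: ModuleCatalog) -> pd.DataFrame:
        df = self.coords.copy()
        df["label"] = [catalog.labels.get(c, "0") for c in df.index]
        return df

    def to_csv(self, path: str | Path) -> None:
        self.coords.to_csv(path, index_label="cimar")


def diffusion_map(X: np.ndarray, dims: int = 2, knn: int = 15,
                  t: int = 1) -> np.ndarray:
    """Diffusion-map coordinates (n x dims).

    Adaptive bandwidth: each point's kernel scale is its distance to the
    ``knn``-th neighbor. The symmetrized transition operator's leading
    non-trivial eigenvectors, scaled by eigenvalue^t, give the map.
    Deterministic: eigenvector signs are fixed to make each column's
    largest-magnitude entry positive.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    knn = min(knn, n - 1)
    nn = NearestNeighbors(n_neighbors=knn + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    sigma = dist[:, -1]
    sigma[sigma < 1e-12] = 1e-12
    # sparse-in-spirit dense kernel; n is at most a few thousand here
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    K = np.exp(-d2 / (sigma[:, None] * sigma[None, :]))
    np.fill_diagonal(K, 0.0)
    K = 0.5 * (K + K.T)
    d = K.sum(axis=1)
    d[d < 1e-12] = 1e-12
    # normalized symmetric operator shares eigenvalues with the Markov one
    Dm = 1.0 / np.sqrt(d)
    A = K * Dm[:, None] * Dm[None, :]
    vals, vecs = np.linalg.eigh(A)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    phi = vecs * Dm[:, None]       # right eigenvectors of the Markov operator
    coords = phi[:, 1:dims + 1] * (vals[1:dims + 1] ** t)[None, :]
    for j in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def embed_excursions(matrix: FeatureMatrix, dims: int = 2, seed: int = 0,
                     knn: int = 15) -> EmbeddingResult:
    """Embed all excursions; one point per excursion, CIMAR-keyed."""
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    X = matrix.values
    if X.shape[0] < 10:
        raise ValueError("need at least 10 excursions to embed")
    try:
        import phate  # pragma: no cover - optional backend

        op = phate.PHATE(n_components=dims, random_state=seed, verbose=0)
        coords = op.fit_transform(X)
        backend = "phate"
        params = {"knn": op.knn, "t": op.t}
    except ImportError:
        coords = diffusion_map(X, dims=dims, knn=knn)
        backend = "diffusion-map"
        params = {"knn": knn, "t": 1}
    df = pd.DataFrame(coords, index=matrix.cimars,
                      columns=[f"dim{i + 1}" for i in range(dims)])
    return EmbeddingResult(coords=df, params=params, seed=seed, backend=backend)


def plot_embedding(result: EmbeddingResult, catalog: ModuleCatalog,
                   path: str | Path, title: str = "Excursion landscape") -> None:
    """Module-colored scatter; non-modular excursions in gray."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.with_labels(catalog)
    fig, ax = plt.subplots(figsize=(7, 6))
    non_mod = df[~df["label"].str.startswith("M")]
    ax.scatter(non_mod["dim1"], non_mod["dim2"], s=6, c="0.75", label="non-modular")
    mods = sorted({l for l in df["label"] if l.startswith("M")},
                  key=lambda s: int(s[1:]))
    cmap = plt.get_cmap("tab20")
    for i, m in enumerate(mods):
        sub = df[df["label"] == m]
        ax.scatter(sub["dim1"], sub["dim2"], s=8, color=cmap(i % 20), label=m)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.set_title(title)
    ax.legend(fontsize=7, markerscale=1.5, ncol=2, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
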