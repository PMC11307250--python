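"""PCA over condition-level weight vectors: clustering of retention mechanisms.

Each row of the weight matrix is the descriptor-weight vector of one trained
network (one stationary phase / modifier / time point / compound set); nearby
rows in principal-component space indicate similar retention mechanisms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist


@dataclass
class PcaResult:
    scores: pd.DataFrame  # rows: condition tags, cols: PC1..PCk
    loadings: pd.DataFrame  # rows: descriptor names, cols: PC1..PCk
    explained_variance_fraction: np.ndarray


def pca_weights(M: pd.DataFrame, n_components: int = 2, center: bool = True) -> PcaResult:
    """Column-centered PCA of a (conditions x descriptors) weight matrix via SVD.

    No scaling is applied by default: weights are already on a common scale.
    Sign convention: the largest-|loading| element of each component is made
    positive, so scores and loadings are reproducible.
    """
    if M.isna().any().any():
        raise ValueError("weight matrix has missing cells")
    if M.index.duplicated().any():
        raise ValueError("duplicate row tags in weight matrix")
    n, p = M.shape
    if n < 2:
        raise ValueError("need at least two condition rows")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(rows-1, columns)={min(n - 1, p)}"
        )
    X = M.to_numpy(dtype=float)
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    total_var = float(np.sum(X**2))
    if total_var == 0.0:
        raise ValueError("weight matrix is constant across conditions (no variance)")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = n_components
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    for j in range(k):
        imax = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[imax, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]
    evf = (S[:k] ** 2) / total_var
    pcs = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=M.index, columns=pcs),
        loadings=pd.DataFrame(loadings, index=M.columns, columns=pcs),
        explained_variance_fraction=evf,
    )


def condition_distances(scores: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Euclidean distances between conditions in retained-PC space.

    Returns the symmetric distance table and each condition's nearest
    neighbor.
    """
    d = squareform(pdist(scores.to_numpy(dtype=float)))
    table = pd.DataFrame(d, index=scores.index, columns=scores.index)
    nn = {}
    for i, tag in enumerate(scores.index):
        row = d[i].copy()
        row[i] = np.inf
        nn[tag] = scores.index[int(np.argmin(row))]
    return table, pd.Series(nn, name="nearest_neighbor")


def plot_scores(result: PcaResult, path: str, marker_by: int = 0, color_by: int = 1) -> None:
    """Two-component scatter; row tags are expected to be 'column|modifier|...' strings."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tags = [str(t).split("|") for t in result.scores.index]
    markers = "so^vDPX*"
    cols = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    m_levels = sorted({t[marker_by] for t in tags if len(t) > marker_by})
    c_levels = sorted({t[color_by] for t in tags if len(t) > color_by})
    fig, ax = plt.subplots(figsize=(6, 5))
    for (x, y), tag in zip(result.scores.iloc[:, :2].to_numpy(), tags):
        m = markers[m_levels.index(tag[marker_by]) % len(markers)] if len(tag) > marker_by else "o"
        c = cols[c_levels.index(tag[color_by]) % len(cols)] if len(tag) > color_by else cols[0]
        ax.scatter(x, y, marker=m, color=c)
    evf = result.explained_variance_fraction
    ax.set_xlabel(f"PC1 ({100 * evf[0]:.1f}% var)")
    ax.set_ylabel(f"PC2 ({100 * evf[1]:.1f}% var)" if len(evf) > 1 else "PC2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
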