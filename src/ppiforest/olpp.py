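"""Orthogonal Locality Preserving Projections (OLPP).

A linear manifold-learning embedding.  Given n samples x_1..x_n, locality
preserving projections (LPP) seek directions w minimizing

    sum_ij ||w^T x_i - w^T x_j||^2 W_ij

over a k-nearest-neighbour affinity graph with heat-kernel weights
W_ij = exp(-||x_i - x_j||^2 / t), which reduces to the generalized
eigenproblem  X L X^T w = lambda X D X^T w  with graph Laplacian
L = D - W, solved at the smallest eigenvalue.  The orthogonal variant
extracts the basis one direction at a time, deflating so that each new
direction is Euclidean-orthogonal to all previous ones:

    o_1   = smallest-eigenvalue eigenvector of (X D X^T)^-1 X L X^T
    o_k   = smallest-eigenvalue eigenvector of
            M(k) = {I - (XDX^T)^-1 A B^-1 A^T} (XDX^T)^-1 X L X^T,
            A = [o_1 .. o_{k-1}],  B = A^T (XDX^T)^-1 A.

Everything runs in a PCA pre-projection space from which near-null
covariance directions have been discarded, and the combined transform is
W = W_PCA W_OLPP applied to centered inputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "OLPPConfig",
    "OLPPModel",
    "pca_projection",
    "build_knn_graph",
    "heat_weights",
    "degree_laplacian",
    "orthogonal_basis",
    "fit_olpp",
    "transform",
    "save_olpp_model",
    "load_olpp_model",
]


@dataclass(frozen=True)
class OLPPConfig:
    """Parameters of the OLPP fit.

    n_neighbors
        Neighbour count of the affinity graph (OR-symmetrized KNN).
    heat_t
        Heat-kernel constant t; ``"auto"`` uses the mean squared distance
        over graph edges.
    embed_dim
        Number of orthogonal basis vectors d.
    pca_tol
        Relative eigenvalue cutoff of the PCA pre-projection: components
        with eigenvalue <= pca_tol * lambda_max are discarded.
    ridge
        Relative Tikhonov term added to X D X^T before inversion
        (scaled by trace(XDX^T)/r); guards rank deficiency.
    """

    n_neighbors: int = 5
    heat_t: float | str = "auto"
    embed_dim: int = 50
    pca_tol: float = 1e-9
    ridge: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if not self.pca_tol > 0:
            raise ValueError("pca_tol must be > 0")
        if self.heat_t != "auto" and not float(self.heat_t) > 0:
            raise ValueError("heat_t must be positive or 'auto'")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")


@dataclass
class OLPPModel:
    """Fitted OLPP projection: y = W_combined^T (x - mean)."""

    mean: np.ndarray
    w_pca: np.ndarray  # (input_dim, r)
    basis: np.ndarray  # (r, d), columns o_1..o_d, mutually orthogonal
    w_combined: np.ndarray = field(init=False)  # (input_dim, d)
    config: OLPPConfig | None = None

    def __post_init__(self) -> None:
        self.w_combined = self.w_pca @ self.basis

    @property
    def embed_dim(self) -> int:
        return self.basis.shape[1]


def pca_projection(x: np.ndarray, pca_tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """PCA pre-projection retaining components with non-negligible variance.

    Returns ``(mean, w_pca)`` where the columns of ``w_pca`` are unit
    eigenvectors of the covariance of centered ``x`` whose eigenvalues
    exceed ``pca_tol`` times the largest one.  Constant data (no component
    survives) raises ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    n, m = x.shape
    if n < 2:
        raise ValueError("pca_projection needs at least 2 samples")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = (xc.T @ xc) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0:
        raise ValueError("degenerate data: zero covariance")
    keep = evals > pca_tol * evals[0]
    r = int(np.sum(keep))
    if r == 0:
        raise ValueError("degenerate data: all eigenvalues below cutoff")
    r = min(r, n - 1, m)
    w = evecs[:, :r]
    # Deterministic sign: largest-magnitude entry of each component positive.
    for j in range(r):
        k = np.argmax(np.abs(w[:, j]))
        if w[k, j] < 0:
            w[:, j] = -w[:, j]
    return mean, w


def build_knn_graph(x: np.ndarray, n_neighbors: int) -> np.ndarray:
    """Boolean adjacency of the OR-symmetrized K-nearest-neighbour graph.

    An edge (i, j) is present iff i is among the ``n_neighbors`` Euclidean
    nearest of j or vice versa.  No self-edges.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if not 1 <= n_neighbors <= n - 1:
        raise ValueError(f"n_neighbors must be in [1, {n - 1}], got {n_neighbors}")
    d = squareform(pdist(x))
    np.fill_diagonal(d, np.inf)
    adj = np.zeros((n, n), dtype=bool)
    # argsort is stable: ties resolve toward the lower index, deterministically.
    nn = np.argsort(d, axis=1, kind="stable")[:, :n_neighbors]
    rows = np.repeat(np.arange(n), n_neighbors)
    adj[rows, nn.ravel()] = True
    adj |= adj.T
    np.fill_diagonal(adj, False)
    return adj


def heat_weights(
    x: np.ndarray, adjacency: np.ndarray, heat_t: float | str = "auto"
) -> np.ndarray:
    """Heat-kernel edge weights W_ij = exp(-||x_i - x_j||^2 / t) on graph
    edges, zero elsewhere.  ``heat_t="auto"`` sets t to the mean squared
    distance over edges."""
    x = np.asarray(x, dtype=float)
    adjacency = np.asarray(adjacency, dtype=bool)
    if not np.array_equal(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    d2 = squareform(pdist(x, metric="sqeuclidean"))
    if heat_t == "auto":
        if not adjacency.any():
            raise ValueError("heat_t='auto' requires at least one edge")
        t = float(d2[adjacency].mean())
        if t <= 0:  # all linked points coincide
            t = 1.0
    else:
        t = float(heat_t)
        if t <= 0:
            raise ValueError("heat_t must be positive")
    w = np.where(adjacency, np.exp(-d2 / t), 0.0)
    np.fill_diagonal(w, 0.0)
    return w


def degree_laplacian(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Degree matrix D (column sums of W on the diagonal) and Laplacian
    L = D - W.  Rows of L sum to zero."""
    w = np.asarray(w, dtype=float)
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError("weight matrix must be symmetric")
    if (w < 0).any():
        raise ValueError("weight matrix must be non-negative")
    d = np.diag(w.sum(axis=0))
    return d, d - w


def _fix_sign(v: np.ndarray) -> np.ndarray:
    k = np.argmax(np.abs(v))
    return -v if v[k] < 0 else v


def _smallest_real_eigvec(m: np.ndarray, imag_tol: float = 1e-8) -> list[np.ndarray]:
    """Eigenvectors of (possibly non-symmetric) m sorted by ascending real
    eigenvalue, discarding pairs with non-negligible imaginary parts."""
    evals, evecs = scipy.linalg.eig(m, check_finite=False)
    scale = max(1.0, float(np.abs(evals).max()))
    ok = np.abs(evals.imag) <= imag_tol * scale
    idx = np.argsort(evals.real[ok], kind="stable")
    vecs = evecs[:, ok][:, idx]
    out = []
    for j in range(vecs.shape[1]):
        v = vecs[:, j]
        if np.abs(v.imag).max() > imag_tol:
            continue
        out.append(v.real)
    return out


def orthogonal_basis(
    xp: np.ndarray,
    d_mat: np.ndarray,
    l_mat: np.ndarray,
    embed_dim: int,
    ridge: float = 1e-8,
) -> np.ndarray:
    """Extract the orthogonal OLPP basis o_1..o_d by iterative deflation.

    Parameters
    ----------
    xp : (r, n) array
        PCA-space data, one sample per column.
    d_mat, l_mat : (n, n) arrays
        Graph degree and Laplacian matrices.
    embed_dim : int
        Number of basis vectors; must not exceed r.
    ridge : float
        Relative regularizer: ridge * trace(XDX^T)/r is added to the
        diagonal of XDX^T before inversion.

    Returns
    -------
    (r, embed_dim) array whose columns are unit-norm, mutually orthogonal.
    """
    xp = np.asarray(xp, dtype=float)
    r, n = xp.shape
    if embed_dim > r:
        raise ValueError(f"embed_dim ({embed_dim}) exceeds PCA rank ({r})")
    xdx = xp @ d_mat @ xp.T
    xlx = xp @ l_mat @ xp.T
    if ridge > 0:
        xdx = xdx + (ridge * np.trace(xdx) / r) * np.eye(r)
    xdx_inv = scipy.linalg.inv(xdx)
    q = xdx_inv @ xlx  # (XDX^T)^-1 XLX^T

    basis: list[np.ndarray] = []
    for k in range(embed_dim):
        if k == 0:
            m = q
        else:
            a = np.column_stack(basis)  # r x k
            ta = xdx_inv @ a
            b = a.T @ ta  # B^(k-1) = A^T (XDX^T)^-1 A
            try:
                b_inv = scipy.linalg.inv(b)
            except scipy.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    f"B matrix singular at deflation step {k + 1}"
                ) from exc
            m = q - ta @ b_inv @ (a.T @ q)
        candidates = _smallest_real_eigvec(m)
        if not candidates:
            raise np.linalg.LinAlgError(
                f"no real eigenvector at deflation step {k + 1}"
            )
        chosen = None
        for v in candidates:
            v = v / np.linalg.norm(v)
            # Deflation theory makes non-null eigenvectors orthogonal to
            # previous directions; skip spurious null-space vectors that
            # violate the constraint.
            if basis:
                a = np.column_stack(basis)
                if np.abs(a.T @ v).max() > 1e-6:
                    continue
            chosen = v
            break
        if chosen is None:
            chosen = candidates[0] / np.linalg.norm(candidates[0])
        if basis:
            a = np.column_stack(basis)
            chosen = chosen - a @ (a.T @ chosen)  # polish to 1e-8 orthogonality
            nrm = np.linalg.norm(chosen)
            if nrm < 1e-12:
                raise np.linalg.LinAlgError(
                    f"degenerate direction at deflation step {k + 1}"
                )
            chosen = chosen / nrm
        basis.append(_fix_sign(chosen))
    return np.column_stack(basis)


def fit_olpp(x: np.ndarray, config: OLPPConfig | None = None) -> OLPPModel:
    """Fit the full OLPP pipeline on an (n, m) data matrix.

    Steps: PCA pre-projection -> KNN graph -> heat-kernel weights ->
    graph Laplacian -> orthogonal basis extraction -> combined transform.
    Deterministic: no randomness anywhere.

    If ``embed_dim`` exceeds the PCA rank it is clamped to the rank (with
    a warning), so the model is always well-defined.
    """
    config = config or OLPPConfig()
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < config.n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={config.n_neighbors + 1} samples, got {n}"
        )
    mean, w_pca = pca_projection(x, config.pca_tol)
    scores = (x - mean) @ w_pca  # (n, r)
    r = scores.shape[1]
    d = config.embed_dim
    if d > r:
        warnings.warn(
            f"embed_dim {d} exceeds PCA rank {r}; clamping to {r}", stacklevel=2
        )
        d = r
    adj = build_knn_graph(scores, config.n_neighbors)
    w = heat_weights(scores, adj, config.heat_t)
    d_mat, l_mat = degree_laplacian(w)
    basis = orthogonal_basis(scores.T, d_mat, l_mat, d, config.ridge)
    return OLPPModel(mean=mean, w_pca=w_pca, basis=basis, config=config)


def transform(model: OLPPModel, x: np.ndarray) -> np.ndarray:
    """Embed rows of ``x``: y = W_combined^T (x - mean)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"expected {model.mean.shape[0]} input features, got {x.shape[1]}"
        )
    return (x - model.mean) @ model.w_combined


def save_olpp_model(model: OLPPModel, path: str | Path) -> None:
    """Serialize the model to a single portable JSON file."""
    cfg = model.config
    payload = {
        "mean": model.mean.tolist(),
        "w_pca": model.w_pca.tolist(),
        "basis": model.basis.tolist(),
        "config": None
        if cfg is None
        else {
            "n_neighbors": cfg.n_neighbors,
            "heat_t": cfg.heat_t,
            "embed_dim": cfg.embed_dim,
            "pca_tol": cfg.pca_tol,
            "ridge": cfg.ridge,
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_olpp_model(path: str | Path) -> OLPPModel:
    payload = json.loads(Path(path).read_text())
    cfg = payload.get("config")
    return OLPPModel(
        mean=np.array(payload["mean"], dtype=float),
        w_pca=np.array(payload["w_pca"], dtype=float),
        basis=np.array(payload["basis"], dtype=float),
        config=None if cfg is None else OLPPConfig(**cfg),
    )
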