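"""Multivariate curve resolution by alternating least squares (MCR-ALS).

Factors a non-negative spectra matrix ``A`` (cells x bins) into
component spectra ``W`` (components x bins) and intensity profiles
``H`` (cells x components), ``A ~= H W + E``, under non-negativity on
both factors with an L1 (LASSO) penalty on ``H`` to discourage
overfitted, dense profiles:

    minimize  1/2 ||A - H W||_F^2 + alpha * ||H||_1    s.t. H, W >= 0

``A`` is internally scaled to unit maximum intensity so that the
penalty weight (default ``alpha_l1_h = 5e-05``) has a reproducible
meaning regardless of the detector's count scale.  Each alternating
step solves its non-negative subproblem exactly (active-set NNLS on the
Cholesky-reduced normal equations), so the penalized objective is
non-increasing across iterations.  After every iteration the rows of
``W`` are scaled to unit L2 norm with the scale absorbed into ``H``,
which leaves the product ``H W`` unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans

from .datatypes import ComponentSet

logger = logging.getLogger(__name__)

INIT_METHODS = ("purest_variable", "kmeans", "random", "user")


def _nnls_gram(G: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Solve min_{x>=0} 1/2 x'Gx - c'x for every column c of C.

    G must be symmetric positive definite (a small ridge is added for
    safety); the problem is reduced to standard NNLS through the
    Cholesky factor of G.
    """
    k = G.shape[0]
    ridge = 1e-12 * max(np.trace(G) / k, 1e-30)
    L = np.linalg.cholesky(G + ridge * np.eye(k))
    # 1/2 x'Gx - c'x = 1/2 ||L'x - inv(L) c||^2 + const
    Y = np.linalg.solve(L, C)
    X = np.empty_like(C)
    Lt = L.T
    for j in range(C.shape[1]):
        X[:, j], _ = nnls(Lt, Y[:, j])
    return X


def _solve_h(A: np.ndarray, W: np.ndarray, alpha: float) -> np.ndarray:
    """Exact penalized non-negative update of H given W (rows of A independent)."""
    G = W @ W.T
    C = W @ A.T - alpha  # linear L1 term: alpha * 1'h for h >= 0
    return _nnls_gram(G, C).T


def _solve_w(A: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Exact non-negative update of W given H (columns of A independent)."""
    G = H.T @ H
    C = H.T @ A
    return _nnls_gram(G, C)


def _row_normalize(W: np.ndarray, H: np.ndarray | None = None):
    """Scale W rows to unit L2 norm, absorbing the scale into H columns."""
    norms = np.linalg.norm(W, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    W = W / safe[:, None]
    if H is not None:
        H = H * safe[None, :]
        return W, H
    return W


def _simplisma_rows(A: np.ndarray, n_components: int, offset_frac: float = 0.05) -> np.ndarray:
    """SIMPLISMA-style purest-row selection.

    Candidate "pure variables" are the rows of ``A`` (single-cell
    spectra).  Purity of row i is std_i / (mean_i + offset), where the
    offset (a fraction of the largest row mean) protects against
    low-intensity noise rows.  After each selection, candidate weights
    are multiplied by the determinant of the correlation-around-origin
    matrix of the candidate together with the already selected rows,
    which suppresses rows nearly collinear with previous picks.  Ties
    break to the lowest row index.
    """
    mu = A.mean(axis=1)
    sigma = A.std(axis=1)
    offset = offset_frac * max(mu.max(), 1e-30)
    purity = sigma / (mu + offset)
    # length-scaled rows for the determinant-based independence weight
    denom = np.sqrt(mu**2 + (sigma + offset) ** 2)
    Z = A / np.where(denom > 0, denom, 1.0)[:, None]
    n_bins = A.shape[1]
    selected: list[int] = []
    for _ in range(n_components):
        weights = np.empty(A.shape[0])
        for i in range(A.shape[0]):
            idx = selected + [i]
            coo = (Z[idx] @ Z[idx].T) / n_bins
            weights[i] = np.linalg.det(coo)
        weights[selected] = -np.inf
        score = purity * weights
        selected.append(int(np.argmax(score)))
    return A[selected].copy()


def initialize_components(
    A: np.ndarray,
    n_components: int,
    method: str = "purest_variable",
    seed: int | None = None,
    W0: np.ndarray | None = None,
) -> np.ndarray:
    """Non-negative, row-normalized initial component spectra.

    ``purest_variable`` selects the purest single-cell spectra
    (SIMPLISMA-style, see :func:`_simplisma_rows`); ``kmeans`` clusters
    L2-normalized spectra and uses cluster centers; ``random`` draws
    uniform spectra; ``user`` row-normalizes the provided ``W0``.
    """
    A = np.asarray(A, dtype=float)
    if method not in INIT_METHODS:
        raise ValueError(f"unknown init method {method!r}; choose from {INIT_METHODS}")
    if method != "user" and n_components > min(A.shape):
        raise ValueError(
            f"n_components={n_components} exceeds the rank bound min{A.shape}"
        )
    if method == "user":
        if W0 is None:
            raise ValueError("method='user' requires W0")
        W = np.clip(np.asarray(W0, dtype=float), 0.0, None)
        if W.shape[0] != n_components:
            raise ValueError("W0 row count does not match n_components")
    elif method == "random":
        rng = np.random.default_rng(seed)
        W = rng.uniform(0.0, 1.0, size=(n_components, A.shape[1]))
    elif method == "kmeans":
        norms = np.linalg.norm(A, axis=1, keepdims=True)
        X = A / np.where(norms > 0, norms, 1.0)
        km = KMeans(n_clusters=n_components, n_init=10, random_state=seed)
        km.fit(X)
        W = np.clip(km.cluster_centers_, 0.0, None)
    else:  # purest_variable
        W = np.clip(_simplisma_rows(A, n_components), 0.0, None)
    return _row_normalize(W)


@dataclass
class MCRResult:
    """Fitted MCR factorization with its audit trail."""

    W: np.ndarray
    H: np.ndarray
    residual_norm: float
    alpha_l1_h: float
    n_iter: int
    converged: bool
    init_method: str
    seed: int | None
    objective_history: np.ndarray


class MCRALS(BaseEstimator, TransformerMixin):
    """MCR-ALS estimator with L1-regularized non-negative profiles.

    Parameters
    ----------
    n_components : int, default=6
        Number of component spectra to resolve.
    alpha_l1_h : float, default=5e-05
        L1 penalty on the intensity profile H, under the unit-max
        scaling of A.
    init : {'purest_variable', 'kmeans', 'random', 'user'}
        Initialization of the component spectra.
    max_iter, tol
        ALS stops when the relative change of the residual Frobenius
        norm falls below ``tol`` or after ``max_iter`` iterations.

    Attributes
    ----------
    components_ : ndarray (n_components, n_bins)
        Resolved spectra, rows scaled to unit L2 norm.
    reconstruction_err_ : float
        Frobenius norm of ``A - H W`` on the input scale.
    objective_history_ : ndarray
        Penalized objective after every iteration (unit-max scale).
    """

    def __init__(
        self,
        n_components: int = 6,
        alpha_l1_h: float = 5e-05,
        init: str = "purest_variable",
        max_iter: int = 500,
        tol: float = 1e-06,
        random_state: int | None = None,
        W0: np.ndarray | None = None,
    ):
        self.n_components = n_components
        self.alpha_l1_h = alpha_l1_h
        self.init = init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.W0 = W0

    def _validate(self, A) -> np.ndarray:
        A = np.asarray(A, dtype=float)
        if A.ndim != 2:
            raise ValueError("A must be a 2-D matrix (cells x bins)")
        if not np.all(np.isfinite(A)):
            raise ValueError("A must be finite")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        A = np.clip(A, 0.0, None)  # documented clip-at-zero policy at MCR input
        if A.max() <= 0:
            raise ValueError("A is degenerate: all intensities are <= 0")
        return A

    def fit(self, A, y=None):
        self.fit_transform(A)
        return self

    def fit_transform(self, A, y=None):
        A = self._validate(A)
        scale = A.max()
        As = A / scale
        alpha = self.alpha_l1_h
        W = initialize_components(
            As, self.n_components, method=self.init, seed=self.random_state, W0=self.W0
        )
        H = _solve_h(As, W, alpha)
        objective = []
        prev_res = np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            W_new = _solve_w(As, H)
            W, H = _row_normalize(W_new, H)
            H = _solve_h(As, W, alpha)
            resid = As - H @ W
            res_norm = float(np.linalg.norm(resid))
            objective.append(0.5 * res_norm**2 + alpha * np.abs(H).sum())
            if prev_res < np.inf:
                rel = abs(prev_res - res_norm) / max(prev_res, 1e-30)
                if rel < self.tol:
                    converged = True
                    prev_res = res_norm
                    break
            prev_res = res_norm
        if not converged:
            warnings.warn(
                f"MCR-ALS did not converge in {n_iter} iterations "
                f"(relative residual change above tol={self.tol})",
                RuntimeWarning,
            )
            logger.warning("MCR-ALS non-convergence after %d iterations", n_iter)
        self.components_ = W
        self.scale_ = float(scale)
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.objective_history_ = np.asarray(objective)
        H_out = H * scale
        self.reconstruction_err_ = float(np.linalg.norm(A - H_out @ W))
        self.profile_ = H_out
        return H_out

    def transform(self, A):
        """Penalized non-negative profiles for new spectra under the fitted W."""
        if not hasattr(self, "components_"):
            raise RuntimeError("MCRALS is not fitted")
        A = np.clip(np.asarray(A, dtype=float), 0.0, None)
        H = _solve_h(A / self.scale_, self.components_, self.alpha_l1_h)
        return H * self.scale_

    def result(self) -> MCRResult:
        return MCRResult(
            W=self.components_,
            H=self.profile_,
            residual_norm=self.reconstruction_err_,
            alpha_l1_h=self.alpha_l1_h,
            n_iter=self.n_iter_,
            converged=self.converged_,
            init_method=self.init,
            seed=self.random_state,
            objective_history=self.objective_history_,
        )


def mcr_als(
    A: np.ndarray,
    n_components: int = 6,
    alpha_l1_h: float = 5e-05,
    max_iter: int = 500,
    tol: float = 1e-06,
    init: str = "purest_variable",
    seed: int | None = None,
    W0: np.ndarray | None = None,
) -> MCRResult:
    """Functional wrapper around :class:`MCRALS`."""
    est = MCRALS(
        n_components=n_components,
        alpha_l1_h=alpha_l1_h,
        init=init,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
        W0=W0,
    )
    est.fit_transform(A)
    return est.result()


def cosine_similarity_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity between rows of X and rows of Y."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    xn = np.linalg.norm(X, axis=1, keepdims=True)
    yn = np.linalg.norm(Y, axis=1, keepdims=True)
    X = X / np.where(xn > 0, xn, 1.0)
    Y = Y / np.where(yn > 0, yn, 1.0)
    return X @ Y.T


def match_components(resolved: ComponentSet, reference: ComponentSet):
    """Optimal one-to-one pairing of resolved and reference components.

    Uses Hungarian assignment to maximize the summed cosine similarity.
    Returns ``(mapping, similarity_matrix, unmatched)`` where
    ``mapping`` is a dict resolved-name -> (reference-name, cosine) and
    ``unmatched`` lists names left unpaired on the larger side.
    """
    if resolved.n_components == 0 or reference.n_components == 0:
        raise ValueError("both component sets must be non-empty")
    if resolved.axis.size != reference.axis.size or not np.allclose(
        resolved.axis, reference.axis
    ):
        raise ValueError("component sets are on different wavenumber axes")
    sim = cosine_similarity_matrix(resolved.spectra, reference.spectra)
    rows, cols = linear_sum_assignment(-sim)
    mapping = {
        resolved.names[i]: (reference.names[j], float(sim[i, j]))
        for i, j in zip(rows, cols)
    }
    matched_res = set(rows.tolist())
    matched_ref = set(cols.tolist())
    unmatched = [n for i, n in enumerate(resolved.names) if i not in matched_res]
    unmatched += [n for j, n in enumerate(reference.names) if j not in matched_ref]
    return mapping, sim, unmatched
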