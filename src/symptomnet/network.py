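"""Sparse partial-correlation network estimation.

The symptom network is a Gaussian graphical model: edges are partial
correlations, obtained from the standardized negative inverse of the
(tetrachoric) correlation matrix.  False-positive edges are controlled by
the graphical LASSO, whose L1 penalty sets small edges exactly to zero; the
penalty is chosen by minimizing the extended Bayesian information
criterion

    EBIC(lambda) = -2 loglik + E log(n) + 4 E gamma log(p),

where E is the number of nonzero edges and gamma (default 0.5) penalizes
model-space size.  The single-penalty solver is the block coordinate
descent in `symptomnet._glasso`; the warm-started path, model selection,
edge bookkeeping and the force-directed layout live here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._glasso import glasso
from .cohort import SymptomMatrix, round_half_up
from .tetrachoric import CorrelationEstimate, TetrachoricCorrelation

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkModel",
    "Layout",
    "GlassoConvergenceError",
    "glasso_fit",
    "precision_to_partial",
    "EBICGraphLasso",
    "select_ebic",
    "estimate_network",
    "count_edges",
    "top_associations",
    "fruchterman_reingold",
]

EDGE_TOL = 1e-10  # |weight| above this counts as an edge (guards float noise)


class GlassoConvergenceError(RuntimeError):
    """Graphical-LASSO failure, carrying the penalty and iteration budget."""

    def __init__(self, lam: float, max_iter: int, cause: str):
        self.lam = lam
        self.max_iter = max_iter
        super().__init__(
            f"graphical lasso did not converge at lambda={lam:.6g} "
            f"within {max_iter} iterations: {cause}"
        )


@dataclass
class NetworkModel:
    """Estimated partial-correlation network and its selection path."""

    weights: np.ndarray
    item_codes: tuple[str, ...]
    lambda_selected: float
    ebic: float
    ebic_gamma: float
    n_effective: int
    nonzero_edges: int
    precision: np.ndarray | None = None
    path: pd.DataFrame | None = None
    dense_warning: bool = False

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def to_graph(self) -> nx.Graph:
        """networkx graph of the nonzero edges (|weight| as 'abs_weight')."""
        G = nx.Graph()
        G.add_nodes_from(self.item_codes)
        for i in range(self.p):
            for j in range(i + 1, self.p):
                w = float(self.weights[i, j])
                if abs(w) > EDGE_TOL:
                    G.add_edge(
                        self.item_codes[i],
                        self.item_codes[j],
                        weight=w,
                        abs_weight=abs(w),
                        distance=1.0 / abs(w),
                    )
        return G

    def edge_list(self) -> pd.DataFrame:
        """Long-format nonzero edges sorted by |weight| descending."""
        rows = [
            (self.item_codes[i], self.item_codes[j], float(self.weights[i, j]))
            for i in range(self.p)
            for j in range(i + 1, self.p)
            if abs(self.weights[i, j]) > EDGE_TOL
        ]
        rows.sort(key=lambda r: (-abs(r[2]), r[0], r[1]))
        return pd.DataFrame(rows, columns=["item_i", "item_j", "weight"])

    def to_matrix_csv(self, path) -> None:
        pd.DataFrame(
            self.weights, index=list(self.item_codes), columns=list(self.item_codes)
        ).to_csv(path)

    def to_edge_tsv(self, path) -> None:
        self.edge_list().to_csv(path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_graph(), path)


@dataclass
class Layout:
    """2-D node coordinates from the force-directed layout."""

    coordinates: np.ndarray
    item_codes: tuple[str, ...]
    seed: int
    iterations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coordinates, index=list(self.item_codes), columns=["x", "y"]
        )


def glasso_fit(
    S: np.ndarray,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 200,
    W_init: np.ndarray | None = None,
) -> np.ndarray:
    """L1-penalized precision matrix at one penalty value.

    Maximizes ``logdet K - tr(S K) - lam * sum|K_offdiag|`` by block
    coordinate descent (see `symptomnet._glasso`); convergence when the
    largest parameter change in a sweep drops below `tol`.  Raises
    `GlassoConvergenceError` when the sweep budget is exhausted.
    """
    S = np.asarray(S, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    K, _, n_iter, converged = glasso(S, float(lam), tol=tol, max_iter=max_iter, W_init=W_init)
    if not converged:
        raise GlassoConvergenceError(lam, max_iter, f"max change still above {tol} after {n_iter} sweeps")
    return K


def precision_to_partial(precision: np.ndarray) -> np.ndarray:
    """Partial correlations w_ij = -k_ij / sqrt(k_ii k_jj), zero diagonal."""
    K = np.asarray(precision, dtype=float)
    d = np.diag(K)
    if np.any(d <= 0):
        raise ValueError("precision diagonal must be positive")
    W = -K / np.sqrt(np.outer(d, d))
    np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2.0


def _gaussian_loglik(K: np.ndarray, S: np.ndarray, n: int) -> float:
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise ValueError("precision matrix is not positive definite")
    return 0.5 * n * (logdet - np.trace(S @ K))


def ebic_value(K: np.ndarray, S: np.ndarray, n: int, gamma: float, edge_tol: float = EDGE_TOL) -> float:
    """Extended BIC of a fitted precision matrix."""
    p = K.shape[0]
    W = precision_to_partial(K)
    E = int(np.sum(np.abs(W[np.triu_indices(p, 1)]) > edge_tol))
    return -2.0 * _gaussian_loglik(K, S, n) + E * np.log(n) + 4.0 * E * gamma * np.log(p)


def lambda_path(S: np.ndarray, n_lambdas: int = 100, min_ratio: float = 0.01) -> np.ndarray:
    """Decreasing log-spaced penalty path from lambda_max = max|S_offdiag|."""
    S = np.asarray(S, dtype=float)
    off = np.abs(S[np.triu_indices(S.shape[0], 1)])
    lam_max = float(off.max())
    if lam_max <= 0:  # fully independent input; any positive path works
        lam_max = 1.0
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambdas)


class EBICGraphLasso(BaseEstimator):
    """Graphical LASSO over a penalty path with EBIC model selection.

    Parameters
    ----------
    gamma : float, default 0.5
        EBIC model-space hyperparameter (0 recovers plain BIC).
    n_lambdas, lambda_min_ratio :
        Log-spaced path of `n_lambdas` penalties from lambda_max (the
        largest absolute off-diagonal input correlation) down to
        ``lambda_min_ratio * lambda_max``.
    lambdas : array-like, optional
        Explicit decreasing penalty path, overriding the two above.
    covariance : {"tetrachoric", "precomputed"}
        With "tetrachoric" (default), `fit` expects binary data (array or
        SymptomMatrix) and estimates the input correlation itself; with
        "precomputed", `fit` expects a correlation matrix and requires
        `n_samples`.
    n_samples : int, optional
        Effective sample size for the EBIC when the input is precomputed.
    edge_tol : float
        |partial correlation| above this counts as an edge.

    Attributes
    ----------
    weights_ : ndarray (p, p)
        Selected partial-correlation matrix (zero diagonal).
    precision_ : ndarray (p, p)
    lambda_ : float
        Selected penalty (EBIC minimizer; ties go to the sparser model).
    ebic_ : float
    n_edges_ : int
    path_ : DataFrame with columns (lambda, n_edges, ebic)
    correlation_ : CorrelationEstimate or None
        The tetrachoric input estimate when computed internally.
    """

    def __init__(
        self,
        gamma: float = 0.5,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 0.01,
        lambdas=None,
        covariance: str = "tetrachoric",
        n_samples: int | None = None,
        edge_tol: float = EDGE_TOL,
        tol: float = 1e-6,
        max_iter: int = 200,
        eig_floor: float = 1e-6,
    ):
        self.gamma = gamma
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.lambdas = lambdas
        self.covariance = covariance
        self.n_samples = n_samples
        self.edge_tol = edge_tol
        self.tol = tol
        self.max_iter = max_iter
        self.eig_floor = eig_floor

    def fit(self, X, y=None):
        if self.covariance == "precomputed":
            S = np.asarray(X, dtype=float)
            if self.n_samples is None:
                raise ValueError("n_samples is required with covariance='precomputed'")
            n = int(self.n_samples)
            codes = tuple(f"V{j + 1}" for j in range(S.shape[1]))
            self.correlation_ = None
        elif self.covariance == "tetrachoric":
            tet = TetrachoricCorrelation(eig_floor=self.eig_floor).fit(X)
            S = tet.rho_
            n = tet.n_samples_
            codes = tet.item_codes_
            self.correlation_ = tet.estimate_()
        else:
            raise ValueError("covariance must be 'tetrachoric' or 'precomputed'")

        p = S.shape[0]
        if self.lambdas is not None:
            lams = np.asarray(self.lambdas, dtype=float)
            if lams.size > 1 and np.any(np.diff(lams) >= 0):
                raise ValueError("lambda path must be strictly decreasing")
        else:
            lams = lambda_path(S, self.n_lambdas, self.lambda_min_ratio)

        possible = p * (p - 1) // 2
        records = []
        best = None
        W_prev = None  # warm start along the descending path
        for lam in lams:  # descending: ties keep the sparser (larger-lambda) model
            K, W_prev, n_iter, converged = glasso(
                S, float(lam), tol=self.tol, max_iter=self.max_iter, W_init=W_prev
            )
            if not converged:
                raise GlassoConvergenceError(
                    float(lam), self.max_iter, f"path fit stalled after {n_iter} sweeps"
                )
            W = precision_to_partial(K)
            E = int(np.sum(np.abs(W[np.triu_indices(p, 1)]) > self.edge_tol))
            ebic = (
                -2.0 * _gaussian_loglik(K, S, n)
                + E * np.log(n)
                + 4.0 * E * self.gamma * np.log(p)
            )
            records.append((float(lam), E, float(ebic)))
            if best is None or ebic < best[0]:
                best = (ebic, float(lam), K, W, E)

        dense = all(r[1] == possible for r in records) and n < p
        if dense:
            warnings.warn(
                "every path model is dense and n < p; EBIC selection is unreliable",
                stacklevel=2,
            )

        self.ebic_, self.lambda_, self.precision_, self.weights_, self.n_edges_ = best
        self.path_ = pd.DataFrame(records, columns=["lambda", "n_edges", "ebic"])
        self.item_codes_ = codes
        self.n_samples_ = n
        self.dense_warning_ = dense
        return self

    def model_(self) -> NetworkModel:
        """Fitted result as a `NetworkModel` record."""
        return NetworkModel(
            weights=self.weights_,
            item_codes=self.item_codes_,
            lambda_selected=self.lambda_,
            ebic=self.ebic_,
            ebic_gamma=self.gamma,
            n_effective=self.n_samples_,
            nonzero_edges=self.n_edges_,
            precision=self.precision_,
            path=self.path_,
            dense_warning=self.dense_warning_,
        )


def select_ebic(S: np.ndarray, n: int, gamma: float = 0.5, lambdas=None, **kwargs) -> NetworkModel:
    """EBIC-minimizing network from a precomputed correlation matrix."""
    est = EBICGraphLasso(
        gamma=gamma, lambdas=lambdas, covariance="precomputed", n_samples=n, **kwargs
    ).fit(S)
    return est.model_()


def estimate_network(matrix: SymptomMatrix, gamma: float = 0.5, **kwargs) -> NetworkModel:
    """Full tetrachoric + EBIC-GLASSO estimate from a binary cohort."""
    est = EBICGraphLasso(gamma=gamma, covariance="tetrachoric", **kwargs).fit(matrix)
    model = est.model_()
    model.item_codes = matrix.item_codes
    return model


def count_edges(model: NetworkModel) -> tuple[int, int, float]:
    """(nonzero, possible, one-decimal percentage) edge counts."""
    possible = model.p * (model.p - 1) // 2
    pct = round_half_up(100.0 * model.nonzero_edges / possible, 1)
    return model.nonzero_edges, possible, pct


def top_associations(model: NetworkModel, k: int) -> list[tuple[str, str, float]]:
    """The k strongest edges as (item_i, item_j, weight), |weight| descending.

    Ties break lexicographically by item codes.  Requests beyond the number
    of nonzero edges return the truncated list with a warning.
    """
    edges = list(model.edge_list().itertuples(index=False, name=None))
    if k > len(edges):
        warnings.warn(
            f"requested {k} edges but only {len(edges)} are nonzero", stacklevel=2
        )
    return edges[:k]


def fruchterman_reingold(
    model: NetworkModel, seed: int = 0, iterations: int = 200
) -> Layout:
    """Force-directed node layout with |weight| as attraction strength.

    Classic Fruchterman-Reingold annealing: repulsion k^2/d between every
    pair, attraction |w| d^2 / k along edges, displacement capped by a
    linearly cooling temperature.  Coordinates are not rescaled afterwards,
    so strongly tied pairs genuinely end closer together; a fixed seed
    gives bit-identical coordinates.
    """
    p = model.p
    if p < 2:
        raise ValueError("need at least two nodes")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-0.5, 0.5, size=(p, 2))
    A = np.abs(model.weights)
    k = 1.0 / np.sqrt(p)
    t0 = 0.1
    for it in range(iterations):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, np.inf)  # a node exerts no force on itself
        dist = np.maximum(dist, 1e-9)
        unit = delta / dist[..., None]
        rep = (k * k / dist)[..., None] * unit
        dist_f = np.where(np.isfinite(dist), dist, 0.0)
        att = (A * dist_f * dist_f / k)[..., None] * unit
        disp = (rep - att).sum(axis=1)
        norm_d = np.linalg.norm(disp, axis=1, keepdims=True)
        norm_d = np.maximum(norm_d, 1e-12)
        t = t0 * (1.0 - it / iterations)
        pos = pos + disp / norm_d * np.minimum(norm_d, t)
    return Layout(
        coordinates=pos, item_codes=model.item_codes, seed=seed, iterations=iterations
    )
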