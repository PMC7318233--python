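"""Tetrachoric correlation estimation for binary symptom data.

The tetrachoric correlation of two dichotomous items is the correlation of
the latent bivariate normal assumed to generate their 2x2 contingency
table — the binary special case of the polychoric correlation.  Estimation
is two-step: the two thresholds are fixed from the marginal proportions,
then rho maximizes the multinomial log-likelihood of the table over
(-0.999, 0.999) by bounded one-dimensional optimization, with orthant
probabilities from the deterministic bivariate-normal CDF in `_bvn`.

A whole-matrix estimate need not be positive definite; `correlation_matrix`
repairs an indefinite estimate by eigenvalue clipping at a configurable
floor followed by rescaling to unit diagonal, and records that it did so.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm
from sklearn.base import BaseEstimator

from ._bvn import bvn_upper
from .cohort import SymptomMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationEstimate",
    "pair_table",
    "estimate_tetrachoric",
    "table_loglik",
    "TetrachoricCorrelation",
    "correlation_matrix",
]

RHO_BOUND = 0.999  # keeps downstream matrix inversion finite


@dataclass
class CorrelationEstimate:
    """p x p tetrachoric correlation matrix plus estimation metadata."""

    rho: np.ndarray
    thresholds: np.ndarray
    item_codes: tuple[str, ...]
    psd_repaired: bool
    min_eigenvalue_before_repair: float
    degenerate_items: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rho, index=list(self.item_codes), columns=list(self.item_codes)
        )

    def to_dict(self) -> dict:
        return {
            "item_codes": list(self.item_codes),
            "thresholds": [float(t) for t in self.thresholds],
            "psd_repaired": self.psd_repaired,
            "min_eigenvalue_before_repair": float(self.min_eigenvalue_before_repair),
            "degenerate_items": list(self.degenerate_items),
        }


def pair_table(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int]:
    """2x2 contingency counts (a, b, c, d) of two binary vectors.

    a = both present, b = x only, c = y only, d = both absent.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    return a, b, c, d


def _cell_probs(t1: float, t2: float, rho: float) -> tuple[float, float, float, float]:
    """Orthant probabilities (pa, pb, pc, pd) at thresholds t1, t2."""
    pa = bvn_upper(t1, t2, rho)
    p1 = norm.sf(t1)  # P(item 1 present)
    p2 = norm.sf(t2)
    pb = p1 - pa
    pc = p2 - pa
    pd_ = 1.0 - pa - pb - pc
    return pa, pb, pc, pd_


def table_loglik(table, rho: float, thresholds=None) -> float:
    """Bivariate-normal log-likelihood of a 2x2 table at correlation rho.

    Thresholds default to the values implied by the table margins (after
    the same zero-cell correction as `estimate_tetrachoric`).
    """
    a, b, c, d = (float(v) for v in table)
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    n = a + b + c + d
    if thresholds is None:
        t1 = norm.ppf(1.0 - (a + b) / n)
        t2 = norm.ppf(1.0 - (a + c) / n)
    else:
        t1, t2 = thresholds
    probs = _cell_probs(t1, t2, rho)
    tiny = 1e-300
    return float(
        sum(k * np.log(max(pr, tiny)) for k, pr in zip((a, b, c, d), probs))
    )


def estimate_tetrachoric(table) -> tuple[float, float, float]:
    """ML tetrachoric correlation and thresholds from a 2x2 table.

    Returns ``(rho, t1, t2)``.  If any cell is zero, 0.5 is added to every
    cell first (continuity correction).  Degenerate margins (an item always
    present or always absent) cannot identify rho; the pair is flagged with
    a warning and rho = 0 is returned.
    """
    a, b, c, d = (float(v) for v in table)
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be nonnegative")
    n_raw = a + b + c + d
    if n_raw < 2:
        raise ValueError("need at least two observations")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        warnings.warn(
            "degenerate margin (item all-present or all-absent); rho set to 0",
            stacklevel=2,
        )
        return 0.0, np.nan, np.nan
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    n = a + b + c + d
    t1 = norm.ppf(1.0 - (a + b) / n)
    t2 = norm.ppf(1.0 - (a + c) / n)

    def neg_loglik(rho: float) -> float:
        probs = _cell_probs(t1, t2, rho)
        tiny = 1e-300
        return -sum(
            k * np.log(max(pr, tiny)) for k, pr in zip((a, b, c, d), probs)
        )

    res = minimize_scalar(
        neg_loglik,
        bounds=(-RHO_BOUND, RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x), float(t1), float(t2)


def _clip_to_psd(R: np.ndarray, floor: float) -> np.ndarray:
    """Clip eigenvalues at `floor`, rebuild, rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(R)
    fixed = (vecs * np.maximum(vals, floor)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0


class TetrachoricCorrelation(BaseEstimator):
    """Pairwise tetrachoric correlation matrix estimator.

    Parameters
    ----------
    eig_floor : float, default 1e-6
        Smallest eigenvalue the fitted matrix is guaranteed to have; an
        indefinite pairwise estimate is repaired by clipping eigenvalues at
        this floor and rescaling to unit diagonal.

    Attributes
    ----------
    rho_ : ndarray (p, p)
        Estimated correlation matrix (unit diagonal, symmetric, PD).
    thresholds_ : ndarray (p,)
        Per-item latent thresholds from the marginal proportions.
    psd_repaired_ : bool
        Whether the eigenvalue repair was applied.
    min_eigenvalue_before_repair_ : float
    degenerate_items_ : tuple of str
        Items with an all-0 or all-1 column (their pairs are set to 0).
    """

    def __init__(self, eig_floor: float = 1e-6):
        self.eig_floor = eig_floor

    def fit(self, X, y=None):
        if isinstance(X, SymptomMatrix):
            values, codes = X.values, X.item_codes
        else:
            values = np.asarray(X)
            codes = tuple(f"V{j + 1}" for j in range(values.shape[1]))
        if values.ndim != 2 or values.shape[1] < 2:
            raise ValueError("need an n x p binary matrix with p >= 2")
        if not np.isin(values, (0, 1)).all():
            raise ValueError("input cells must be exactly 0 or 1")
        n, p = values.shape

        margins = values.mean(axis=0)
        degenerate = [j for j in range(p) if margins[j] in (0.0, 1.0)]
        thresholds = np.full(p, np.nan)
        ok = np.setdiff1d(np.arange(p), degenerate)
        thresholds[ok] = norm.ppf(1.0 - margins[ok])

        # both-present counts for all pairs in one matrix product
        V = values.astype(np.int64)
        both = V.T @ V
        ones = V.sum(axis=0)

        R = np.eye(p)
        for j in range(p):
            for k in range(j + 1, p):
                if j in degenerate or k in degenerate:
                    rho = 0.0
                else:
                    a = int(both[j, k])
                    b = int(ones[j] - a)
                    c = int(ones[k] - a)
                    d = int(n - a - b - c)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        rho, _, _ = estimate_tetrachoric((a, b, c, d))
                R[j, k] = R[k, j] = rho
        if degenerate:
            warnings.warn(
                f"degenerate margin(s) for {[codes[j] for j in degenerate]}; "
                "their correlations were set to 0",
                stacklevel=2,
            )

        min_eig = float(np.linalg.eigvalsh(R).min())
        repaired = min_eig < self.eig_floor
        if repaired:
            R = _clip_to_psd(R, self.eig_floor)

        self.rho_ = R
        self.thresholds_ = thresholds
        self.item_codes_ = tuple(codes)
        self.psd_repaired_ = repaired
        self.min_eigenvalue_before_repair_ = min_eig
        self.degenerate_items_ = tuple(codes[j] for j in degenerate)
        self.n_samples_ = n
        return self

    def estimate_(self) -> CorrelationEstimate:
        """Fitted result as a `CorrelationEstimate` record."""
        return CorrelationEstimate(
            rho=self.rho_,
            thresholds=self.thresholds_,
            item_codes=self.item_codes_,
            psd_repaired=self.psd_repaired_,
            min_eigenvalue_before_repair=self.min_eigenvalue_before_repair_,
            degenerate_items=self.degenerate_items_,
        )


def correlation_matrix(matrix: SymptomMatrix, eig_floor: float = 1e-6) -> CorrelationEstimate:
    """Estimate the full tetrachoric correlation matrix of a cohort."""
    return TetrachoricCorrelation(eig_floor=eig_floor).fit(matrix).estimate_()
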