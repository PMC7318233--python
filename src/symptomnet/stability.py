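"""Bootstrap stability of centralities and edges.

Two procedures, both re-running the whole estimation pipeline
(tetrachoric -> EBIC-GLASSO -> centrality) on each resample:

- case-dropping bootstrap / CS-coefficient: for an increasing grid of drop
  proportions, subsample cases without replacement and correlate the
  subsample centralities with the full-sample ones.  The CS-coefficient of
  an index is the largest tested proportion q such that the correlation is
  >= 0.7 in >= 95% of bootstraps at q and at every smaller tested
  proportion (0 if the smallest fails).  Indices are conventionally
  interpreted only when CS > 0.25, and preferably CS > 0.5.
- nonparametric difference test: resample cases with replacement and form
  percentile 95% confidence intervals of every pairwise difference between
  edge weights and between node strengths; a difference is flagged
  significant when its interval excludes 0.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .centrality import INDEX_NAMES, centrality_table
from .cohort import SymptomMatrix
from .network import EBICGraphLasso

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_DROP_PROPORTIONS",
    "StabilityReport",
    "DifferenceTest",
    "case_drop_bootstrap",
    "difference_bootstrap",
    "cs_interpretation",
]

#: Tested case-dropping grid; CS can therefore top out at 0.75.
DEFAULT_DROP_PROPORTIONS = tuple(round(0.05 * i, 2) for i in range(1, 16))

CS_CORRELATION_THRESHOLD = 0.7
CS_PROBABILITY = 0.95


def cs_interpretation(cs: float) -> str:
    if cs > 0.5:
        return "preferred"
    if cs > 0.25:
        return "interpretable"
    return "none"


@dataclass
class StabilityReport:
    """CS-coefficients plus the full drop-proportion x replicate table."""

    cs: dict[str, float]
    table: pd.DataFrame  # columns: proportion, replicate, index, correlation
    n_boot: int
    seed: int
    drop_proportions: tuple[float, ...]
    correlation: str
    interpretation: dict[str, str] = field(default_factory=dict)
    n_skipped: dict[float, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cs": {k: float(v) for k, v in self.cs.items()},
            "interpretation": dict(self.interpretation),
            "n_boot": self.n_boot,
            "seed": self.seed,
            "drop_proportions": list(self.drop_proportions),
            "correlation": self.correlation,
            "n_skipped": {str(k): v for k, v in self.n_skipped.items()},
        }


@dataclass
class DifferenceTest:
    """Percentile bootstrap 95% CIs for pairwise edge/strength differences."""

    edges: pd.DataFrame  # columns: edge_a, edge_b, lower, upper, significant
    strengths: pd.DataFrame  # columns: node_a, node_b, lower, upper, significant
    n_boot: int
    seed: int
    n_skipped: int

    def to_dict(self) -> dict:
        return {
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_skipped": self.n_skipped,
            "n_significant_edge_pairs": int(self.edges["significant"].sum()),
            "n_significant_strength_pairs": int(self.strengths["significant"].sum()),
        }


def _fit_centralities(matrix: SymptomMatrix, estimator_kwargs: dict) -> dict[str, np.ndarray]:
    est = EBICGraphLasso(covariance="tetrachoric", **estimator_kwargs).fit(matrix)
    model = est.model_()
    model.item_codes = matrix.item_codes
    tab = centrality_table(model)
    return {name: tab.raw(name).to_numpy() for name in INDEX_NAMES}


def _correlate(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    if method == "pearson":
        return float(np.corrcoef(a, b)[0, 1])
    if method == "spearman":
        return float(spearmanr(a, b).statistic)
    raise ValueError("correlation must be 'pearson' or 'spearman'")


def case_drop_bootstrap(
    matrix: SymptomMatrix,
    drop_proportions=DEFAULT_DROP_PROPORTIONS,
    n_boot: int = 1000,
    seed: int = 0,
    correlation: str = "pearson",
    indices=INDEX_NAMES,
    estimator_kwargs: dict | None = None,
    min_rows_factor: int = 3,
) -> StabilityReport:
    """Case-dropping bootstrap of centrality stability (CS-coefficient).

    One master seed derives an independent stream per (proportion,
    replicate), so any replicate is reproducible in isolation.  Replicates
    whose subsample is smaller than ``min_rows_factor * p`` are skipped and
    counted.  Proportions are evaluated in increasing order; once every
    index has failed the 95%/0.7 rule the remaining (larger) proportions
    cannot change any CS-coefficient and are not computed.
    """
    props = tuple(float(q) for q in drop_proportions)
    if not props or any(not 0.0 < q < 1.0 for q in props):
        raise ValueError("drop proportions must lie strictly inside (0, 1)")
    if any(q2 <= q1 for q1, q2 in zip(props, props[1:])):
        raise ValueError("drop proportions must be strictly increasing")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    kw = dict(estimator_kwargs or {})
    n, p = matrix.n, matrix.p

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        original = _fit_centralities(matrix, kw)

    records: list[dict] = []
    n_skipped: dict[float, int] = {}
    alive = set(indices)
    cs = {name: 0.0 for name in indices}
    for i_prop, prop in enumerate(props):
        if not alive:
            break
        size = math.ceil((1.0 - prop) * n)
        skipped = 0
        corrs: dict[str, list[float]] = {name: [] for name in alive}
        for rep in range(n_boot):
            if size < min_rows_factor * p:
                skipped += 1
                continue
            rng = np.random.default_rng(np.random.SeedSequence([seed, i_prop, rep]))
            idx = rng.choice(n, size=size, replace=False)
            sub = SymptomMatrix(matrix.values[idx], matrix.item_codes)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cents = _fit_centralities(sub, kw)
            for name in alive:
                r = _correlate(cents[name], original[name], correlation)
                corrs[name].append(r)
                records.append(
                    {
                        "proportion": prop,
                        "replicate": rep,
                        "index": name,
                        "correlation": r,
                    }
                )
        n_skipped[prop] = skipped
        for name in sorted(alive):
            vals = np.asarray(corrs[name], dtype=float)
            ok = vals >= CS_CORRELATION_THRESHOLD  # NaN compares False
            passed = vals.size > 0 and ok.mean() >= CS_PROBABILITY
            if passed:
                cs[name] = prop
            else:
                alive.discard(name)

    interpretation = {name: cs_interpretation(v) for name, v in cs.items()}
    table = pd.DataFrame(
        records, columns=["proportion", "replicate", "index", "correlation"]
    )
    return StabilityReport(
        cs=cs,
        table=table,
        n_boot=n_boot,
        seed=seed,
        drop_proportions=props,
        correlation=correlation,
        interpretation=interpretation,
        n_skipped=n_skipped,
    )


def _pair_indices(m: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(m, 1)


def difference_bootstrap(
    matrix: SymptomMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    estimator_kwargs: dict | None = None,
) -> DifferenceTest:
    """Nonparametric bootstrap difference test for edges and strengths."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    kw = dict(estimator_kwargs or {})
    n, p = matrix.n, matrix.p
    codes = matrix.item_codes
    iu, ju = np.triu_indices(p, 1)
    edge_names = [f"{codes[i]}--{codes[j]}" for i, j in zip(iu, ju)]

    boot_edges, boot_strengths = [], []
    skipped = 0
    for rep in range(n_boot):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        idx = rng.integers(0, n, size=n)
        values = matrix.values[idx]
        margins = values.mean(axis=0)
        if np.any((margins == 0.0) | (margins == 1.0)):
            skipped += 1  # degenerate resample: an item is constant
            continue
        sub = SymptomMatrix(values, codes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = EBICGraphLasso(covariance="tetrachoric", **kw).fit(sub)
        W = est.weights_
        boot_edges.append(W[iu, ju])
        boot_strengths.append(np.abs(W).sum(axis=0))
    if len(boot_edges) < 2:
        raise RuntimeError("too few non-degenerate bootstrap replicates")
    E = np.asarray(boot_edges)  # (R, n_edges)
    S = np.asarray(boot_strengths)  # (R, p)

    def _ci_frame(samples: np.ndarray, names: list[str], a_col: str, b_col: str) -> pd.DataFrame:
        ia, ib = _pair_indices(samples.shape[1])
        diffs = samples[:, ia] - samples[:, ib]
        lo = np.percentile(diffs, 2.5, axis=0)
        hi = np.percentile(diffs, 97.5, axis=0)
        return pd.DataFrame(
            {
                a_col: [names[i] for i in ia],
                b_col: [names[i] for i in ib],
                "lower": lo,
                "upper": hi,
                "significant": (lo > 0) | (hi < 0),
            }
        )

    edges = _ci_frame(E, edge_names, "edge_a", "edge_b")
    strengths = _ci_frame(S, list(codes), "node_a", "node_b")
    return DifferenceTest(
        edges=edges,
        strengths=strengths,
        n_boot=n_boot,
        seed=seed,
        n_skipped=skipped,
    )
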