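"""Synthetic binary symptom cohorts with known latent structure.

The generative model is the latent-Gaussian threshold (probit) model: each
patient draws a latent multivariate-normal vector with a user-specified
correlation matrix, and item j is scored "present" when its latent value
exceeds the threshold implied by the target marginal prevalence.  This is
exactly the model under which the tetrachoric correlation is the population
parameter, so estimator-recovery tests against these cohorts are
well-posed.  Subgroup heterogeneity is expressed as per-level overrides of
the prevalences and/or latent correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .cohort import ITEM_CODES, SymptomMatrix
from .reference import COHORT_SIZES, reference_prevalences

__all__ = [
    "GeneratorSpec",
    "SubgroupLevel",
    "make_thresholds",
    "generate",
    "make_planted_network",
    "make_matching_precision",
    "make_hub_chain_precision",
    "latent_from_precision",
    "default_cohort_spec",
]


def make_thresholds(prevalences) -> np.ndarray:
    """Latent thresholds t_j = Phi^-1(1 - prevalence_j).

    Item j is scored present when the latent z_j exceeds t_j, so a
    prevalence of 0.5 maps to a threshold of 0 and higher prevalence to a
    lower threshold.
    """
    prev = np.asarray(prevalences, dtype=float)
    if prev.size == 0 or np.any(prev <= 0.0) or np.any(prev >= 1.0):
        raise ValueError("prevalences must lie strictly inside (0, 1)")
    return norm.ppf(1.0 - prev)


def _check_correlation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("latent correlation must be square")
    if not np.allclose(R, R.T, atol=1e-12):
        raise ValueError("latent correlation must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-12):
        raise ValueError("latent correlation must have unit diagonal")
    return R


@dataclass
class SubgroupLevel:
    """One level of a subgroup plan: label, cohort fraction, optional overrides."""

    label: str
    fraction: float
    prevalences: list[float] | None = None
    latent_correlation: np.ndarray | None = None


@dataclass
class GeneratorSpec:
    """Recipe for a synthetic cohort.

    Parameters
    ----------
    n : int
        Cohort size.
    prevalences : sequence of float
        Target marginal presence probabilities, strictly inside (0, 1).
    latent_correlation : ndarray (p, p)
        Symmetric positive-definite latent correlation matrix.
    seed : int
        Reproducibility seed; fixing it fixes the output exactly.
    subgroup_column : str
        Name of the label column when a subgroup plan is present.
    subgroup_plan : list of SubgroupLevel
        Fractions must sum to 1; per-level overrides replace the top-level
        prevalences / latent correlation for that level's rows.
    """

    n: int
    prevalences: list[float]
    latent_correlation: np.ndarray
    seed: int = 0
    item_codes: tuple[str, ...] | None = None
    subgroup_column: str = "group"
    subgroup_plan: list[SubgroupLevel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.prevalences = list(np.asarray(self.prevalences, dtype=float))
        self.latent_correlation = _check_correlation(self.latent_correlation)
        p = self.latent_correlation.shape[0]
        if self.item_codes is None:
            self.item_codes = (
                ITEM_CODES if p == len(ITEM_CODES)
                else tuple(f"V{j + 1}" for j in range(p))
            )
        if len(self.prevalences) != p:
            raise ValueError("prevalences and latent correlation disagree on p")
        make_thresholds(self.prevalences)  # validates the open interval
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.subgroup_plan:
            total = sum(lv.fraction for lv in self.subgroup_plan)
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(f"subgroup fractions sum to {total}, expected 1")

    def to_dict(self) -> dict:
        def _mat(M):
            return None if M is None else [[float(v) for v in row] for row in np.asarray(M)]

        return {
            "n": self.n,
            "prevalences": [float(v) for v in self.prevalences],
            "latent_correlation": _mat(self.latent_correlation),
            "seed": self.seed,
            "item_codes": list(self.item_codes),
            "subgroup_column": self.subgroup_column,
            "subgroup_plan": [
                {
                    "label": lv.label,
                    "fraction": float(lv.fraction),
                    "prevalences": None if lv.prevalences is None
                    else [float(v) for v in lv.prevalences],
                    "latent_correlation": _mat(lv.latent_correlation),
                }
                for lv in self.subgroup_plan
            ],
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "GeneratorSpec":
        plan = [
            SubgroupLevel(
                label=lv["label"],
                fraction=lv["fraction"],
                prevalences=lv.get("prevalences"),
                latent_correlation=None if lv.get("latent_correlation") is None
                else np.asarray(lv["latent_correlation"], dtype=float),
            )
            for lv in raw.get("subgroup_plan", [])
        ]
        return cls(
            n=raw["n"],
            prevalences=raw["prevalences"],
            latent_correlation=np.asarray(raw["latent_correlation"], dtype=float),
            seed=raw.get("seed", 0),
            item_codes=tuple(raw["item_codes"]) if raw.get("item_codes") else None,
            subgroup_column=raw.get("subgroup_column", "group"),
            subgroup_plan=plan,
        )

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _draw_block(n, prevalences, R, rng) -> np.ndarray:
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "latent correlation is not positive definite"
        ) from exc
    z = rng.standard_normal((n, R.shape[0])) @ L.T
    return (z > make_thresholds(prevalences)).astype(np.int8)


def _level_sizes(n: int, fractions: list[float]) -> list[int]:
    """Largest-remainder apportionment of n rows across levels."""
    raw = np.asarray(fractions) * n
    sizes = np.floor(raw).astype(int)
    remainder = n - sizes.sum()
    order = np.argsort(-(raw - sizes))
    sizes[order[:remainder]] += 1
    return sizes.tolist()


def generate(spec: GeneratorSpec) -> SymptomMatrix:
    """Draw a cohort from the latent-Gaussian threshold model."""
    rng = np.random.default_rng(spec.seed)
    if not spec.subgroup_plan:
        values = _draw_block(
            spec.n, spec.prevalences, spec.latent_correlation, rng
        )
        return SymptomMatrix(values, spec.item_codes)

    sizes = _level_sizes(spec.n, [lv.fraction for lv in spec.subgroup_plan])
    blocks, labels = [], []
    for lv, size in zip(spec.subgroup_plan, sizes):
        if size == 0:
            continue
        prev = lv.prevalences if lv.prevalences is not None else spec.prevalences
        R = (
            _check_correlation(lv.latent_correlation)
            if lv.latent_correlation is not None
            else spec.latent_correlation
        )
        blocks.append(_draw_block(size, prev, R, rng))
        labels.extend([lv.label] * size)
    return SymptomMatrix(
        np.vstack(blocks),
        spec.item_codes,
        {spec.subgroup_column: np.asarray(labels)},
    )


def make_planted_network(
    p: int,
    blocks: list[list[int]] | int,
    within_weight: float,
    between_weight: float = 0.0,
):
    """Block-structured latent correlation with a known community partition.

    Parameters
    ----------
    blocks : int or list of node-index lists
        Either the number of equal contiguous blocks or an explicit
        partition of ``range(p)``.
    within_weight, between_weight : float
        Latent correlation inside / across blocks.

    Returns
    -------
    (R, partition) : (ndarray (p, p), ndarray (p,))
        The correlation matrix and 1-based true block membership.

    Under this model the precision matrix is block-structured, so the true
    conditional-dependence edges are exactly the within-block pairs (when
    ``between_weight`` is 0), giving downstream edge-recovery and community
    tests an exact ground truth.
    """
    if isinstance(blocks, int):
        if blocks < 1 or p % blocks:
            raise ValueError("p must divide evenly into the block count")
        size = p // blocks
        blocks = [list(range(b * size, (b + 1) * size)) for b in range(blocks)]
    membership = np.zeros(p, dtype=int)
    for b, nodes in enumerate(blocks, start=1):
        membership[np.asarray(nodes, dtype=int)] = b
    if (membership == 0).any():
        raise ValueError("blocks must partition all nodes")

    R = np.full((p, p), float(between_weight))
    for nodes in blocks:
        ix = np.ix_(nodes, nodes)
        R[ix] = within_weight
    np.fill_diagonal(R, 1.0)
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "within/between weights give a non-positive-definite matrix; "
            "reduce the weights or the block sizes"
        ) from exc
    return R, membership


def make_matching_precision(p: int = 10, weight: float = 0.35):
    """Sparse benchmark precision: disjoint conditionally dependent pairs.

    Nodes are matched (0-1, 2-3, ...; a trailing unmatched node stays
    isolated), each pair sharing one partial correlation of `weight`.
    Well-separated, equal-magnitude edges make this the identifiability
    benchmark for edge-recovery tests: every true edge is comfortably
    detectable at moderate n while no true structure leaks into the
    null pairs.

    Returns
    -------
    (K, edges) : precision matrix and the list of true (i, j) index pairs.
    """
    if not 0.0 < weight < 1.0:
        raise ValueError("weight must lie in (0, 1)")
    K = np.eye(p)
    edges = []
    for i in range(0, p - 1, 2):
        K[i, i + 1] = K[i + 1, i] = -weight
        edges.append((i, i + 1))
    return K, edges


def make_hub_chain_precision(p: int = 10):
    """Benchmark precision with strongly differentiated node strengths.

    Node 0 is a hub tied to nodes 1-3; a chain of weakening partial
    correlations runs onward, and the last node is isolated.  The
    resulting strength profile spans from ~1.2 (hub) down to 0
    (isolate), which is what case-dropping stability analyses need: a
    node ordering that a subsample can actually preserve.

    Returns
    -------
    (K, edges) : precision matrix and the list of true (i, j) index pairs.
    """
    if p < 6:
        raise ValueError("need at least six nodes")
    spec = [(0, 1, 0.45), (0, 2, 0.40), (0, 3, 0.35), (1, 2, 0.30), (3, 4, 0.30)]
    w = 0.25
    for i in range(4, p - 2):  # chain with weakening ties; node p-1 isolated
        spec.append((i, i + 1, max(w, 0.15)))
        w -= 0.05
    K = np.eye(p)
    for i, j, v in spec:
        K[i, j] = K[j, i] = -v
    if np.linalg.eigvalsh(K).min() <= 0:
        raise ValueError("hub-chain precision not positive definite for this p")
    return K, [(i, j) for i, j, _ in spec]


def latent_from_precision(precision: np.ndarray) -> np.ndarray:
    """Latent correlation implied by a (sparse) precision matrix.

    Inverts the precision and standardizes the result to unit diagonal, so
    a sparse conditional-independence specification can be used directly as
    generator input.
    """
    K = np.asarray(precision, dtype=float)
    vals = np.linalg.eigvalsh(K)
    if vals.min() <= 0:
        raise ValueError("precision matrix must be positive definite")
    C = np.linalg.inv(K)
    d = np.sqrt(np.diag(C))
    R = C / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def default_cohort_spec(seed: int = 0, latent_correlation=None) -> GeneratorSpec:
    """Template spec: published overall prevalences, n = 1174.

    With no latent correlation given, items are latently independent.
    """
    prev = reference_prevalences("overall")
    p = len(prev)
    R = np.eye(p) if latent_correlation is None else latent_correlation
    return GeneratorSpec(
        n=COHORT_SIZES["overall"],
        prevalences=prev,
        latent_correlation=R,
        seed=seed,
    )
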