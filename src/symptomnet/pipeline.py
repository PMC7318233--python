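"""Whole-cohort orchestration: overall and subgroup network analyses.

`run_analysis` reproduces the standard symptom-network report for a binary
cohort: per cohort (overall plus each declared subgroup level with enough
cases) it computes the prevalence table, the EBIC-GLASSO network with edge
counts and strongest associations, the spin-glass community partition with
outlier flags, the centrality table with top-3 central symptoms per index,
and — optionally, since they dominate run time — the case-dropping
stability report and bootstrap difference tests.  A single YAML-serializable
config plus one seed fully determines a run; the emitted JSON report is
byte-identical across repeated runs except for its timestamp field.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone

import yaml

from . import __version__
from .centrality import INDEX_NAMES, CentralityTable, centrality_table
from .cohort import ITEM_CODES, SymptomMatrix, prevalence
from .community import isolate_outliers, spinglass_detect
from .network import count_edges, estimate_network, fruchterman_reingold, top_associations
from .stability import (
    DEFAULT_DROP_PROPORTIONS,
    case_drop_bootstrap,
    difference_bootstrap,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "AnalysisReport", "run_analysis", "summarize_top3"]


@dataclass
class PipelineConfig:
    """One file's worth of knobs; fully determines a run together with data."""

    item_codes: tuple[str, ...] = ITEM_CODES
    subgroup_columns: tuple[str, ...] = ()
    seed: int = 0
    # network estimation
    gamma_ebic: float = 0.5
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    eig_floor: float = 1e-6
    # community detection (published call defaults)
    spinglass_gamma: float = 0.5
    spins: int = 17
    start_temp: float = 1.0
    stop_temp: float = 0.01
    cooling_factor: float = 0.99
    restarts: int = 1
    null_model: str = "abs"
    # stability / difference bootstraps
    run_stability: bool = True
    drop_proportions: tuple[float, ...] = DEFAULT_DROP_PROPORTIONS
    stability_n_boot: int = 1000
    stability_correlation: str = "pearson"
    run_difference: bool = True
    difference_n_boot: int = 1000
    # orchestration
    min_subgroup_n: int = 150
    layout_iterations: int = 200

    def estimator_kwargs(self) -> dict:
        return {
            "gamma": self.gamma_ebic,
            "n_lambdas": self.n_lambdas,
            "lambda_min_ratio": self.lambda_min_ratio,
            "eig_floor": self.eig_floor,
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["item_codes"] = list(self.item_codes)
        d["subgroup_columns"] = list(self.subgroup_columns)
        d["drop_proportions"] = [float(q) for q in self.drop_proportions]
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("item_codes", "subgroup_columns", "drop_proportions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def summarize_top3(table: CentralityTable) -> dict[str, list[str]]:
    """Top-3 nodes per centrality index, descending, lexicographic ties.

    A tie across the rank-3 boundary is resolved lexicographically and
    logged, so the reader knows the cut was arbitrary.
    """
    out = {}
    for name in INDEX_NAMES:
        s = table.raw(name)
        if len(s) < 3:
            raise ValueError("need at least three nodes")
        order = sorted(s.index, key=lambda c: (-s[c], c))
        top = order[:3]
        boundary = s[order[2]]
        tied = [c for c in order[3:] if s[c] == boundary]
        if tied:
            logger.info(
                "%s: tie at rank 3 between %s and %s resolved lexicographically",
                name, order[2], tied,
            )
        out[name] = top
    return out


@dataclass
class AnalysisReport:
    """Structured per-cohort results plus provenance."""

    cohorts: dict[str, dict]
    provenance: dict
    subgroup_sizes: dict[str, dict[str, int]] = field(default_factory=dict)
    skipped_subgroups: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cohorts": self.cohorts,
            "subgroup_sizes": self.subgroup_sizes,
            "skipped_subgroups": self.skipped_subgroups,
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def _analyse_cohort(matrix: SymptomMatrix, config: PipelineConfig, name: str) -> dict:
    logger.info("analysing cohort %s (n=%d)", name, matrix.n)
    prev = prevalence(matrix)
    model = estimate_network(matrix, **config.estimator_kwargs())
    nonzero, possible, pct = count_edges(model)
    top_edges = top_associations(model, min(3, nonzero) or 0)
    partition = spinglass_detect(
        model,
        seed=config.seed,
        gamma=config.spinglass_gamma,
        spins=config.spins,
        start_temp=config.start_temp,
        stop_temp=config.stop_temp,
        cooling_factor=config.cooling_factor,
        restarts=config.restarts,
        null_model=config.null_model,
    )
    partition = isolate_outliers(model, partition)
    cents = centrality_table(model)
    layout = fruchterman_reingold(model, seed=config.seed, iterations=config.layout_iterations)

    result = {
        "n": matrix.n,
        "prevalence": prev.to_dict(),
        "network": {
            "lambda_selected": float(model.lambda_selected),
            "ebic": float(model.ebic),
            "ebic_gamma": float(model.ebic_gamma),
            "nonzero_edges": nonzero,
            "possible_edges": possible,
            "edge_percentage": pct,
            "top_associations": [
                {"item_i": a, "item_j": b, "weight": float(w)} for a, b, w in top_edges
            ],
        },
        "communities": partition.to_dict(),
        "centrality": {
            "values": cents.to_dict(),
            "top3": summarize_top3(cents),
        },
        "layout": {
            "seed": layout.seed,
            "iterations": layout.iterations,
            "coordinates": {
                code: [float(x), float(y)]
                for code, (x, y) in zip(layout.item_codes, layout.coordinates)
            },
        },
    }
    if config.run_stability:
        report = case_drop_bootstrap(
            matrix,
            drop_proportions=config.drop_proportions,
            n_boot=config.stability_n_boot,
            seed=config.seed,
            correlation=config.stability_correlation,
            estimator_kwargs=config.estimator_kwargs(),
        )
        result["stability"] = report.to_dict()
    if config.run_difference:
        diff = difference_bootstrap(
            matrix,
            n_boot=config.difference_n_boot,
            seed=config.seed,
            estimator_kwargs=config.estimator_kwargs(),
        )
        result["difference_test"] = diff.to_dict()
    return result


def run_analysis(matrix: SymptomMatrix, config: PipelineConfig | None = None) -> AnalysisReport:
    """Overall plus per-subgroup full pipeline runs (deterministic given seed)."""
    config = config or PipelineConfig()
    if tuple(matrix.item_codes) != tuple(config.item_codes):
        raise ValueError("config item codes do not match the data")
    for col in config.subgroup_columns:
        if col not in matrix.subgroup_labels:
            raise ValueError(f"requested subgroup column {col!r} absent from data")

    cohorts = {"overall": _analyse_cohort(matrix, config, "overall")}
    subgroup_sizes: dict[str, dict[str, int]] = {}
    skipped: dict[str, str] = {}
    for col in config.subgroup_columns:
        sizes = {}
        for level in matrix.levels(col):
            sub = matrix.subset(col, level)
            sizes[level] = sub.n
            key = f"{col}={level}"
            if sub.n < config.min_subgroup_n:
                reason = (
                    f"subgroup n={sub.n} below minimum {config.min_subgroup_n}; "
                    "estimates would be unstable"
                )
                logger.warning("skipping %s: %s", key, reason)
                skipped[key] = reason
                continue
            cohorts[key] = _analyse_cohort(sub, config, key)
        subgroup_sizes[col] = sizes

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    return AnalysisReport(
        cohorts=cohorts,
        provenance=provenance,
        subgroup_sizes=subgroup_sizes,
        skipped_subgroups=skipped,
    )
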