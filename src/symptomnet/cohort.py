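"""Binary symptom-cohort containers, validation and CSV I/O.

The unit of analysis is a cohort of patients, each scored present/absent on
a fixed set of symptom indicators (for depression: the ten ICD-10 symptom
profiles in NICE listing order — SAD, INT, FAT, SLE, CON, SEL, APE, SUI,
AGI, GUI).  Rows with missing or non-binary symptom cells are rejected
listwise during loading and the rejected count is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ICD-10 depressive-symptom indicators in NICE listing order.
ITEM_CODES = ("SAD", "INT", "FAT", "SLE", "CON", "SEL", "APE", "SUI", "AGI", "GUI")

__all__ = [
    "ITEM_CODES",
    "SymptomMatrix",
    "PrevalenceTable",
    "load_symptom_matrix",
    "save_symptom_matrix",
    "prevalence",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (presentation rounding for tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SymptomMatrix:
    """n x p matrix of binary symptom indicators with optional subgroup labels.

    Parameters
    ----------
    values : ndarray of shape (n, p)
        0/1 indicators; 1 = symptom present.
    item_codes : sequence of str
        Unique short labels, one per column.
    subgroup_labels : dict of str -> ndarray, optional
        Per-row categorical labels, e.g. ``{"region": [...], "income": [...]}``.
    """

    values: np.ndarray
    item_codes: tuple[str, ...] = ITEM_CODES
    subgroup_labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if n < 1:
            raise ValueError("need at least one row")
        if p < 2:
            raise ValueError("need at least two symptom columns")
        self.item_codes = tuple(str(c) for c in self.item_codes)
        if len(self.item_codes) != p:
            raise ValueError(
                f"{len(self.item_codes)} item codes for {p} columns"
            )
        if len(set(self.item_codes)) != p:
            raise ValueError("item codes must be unique")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("all cells must be exactly 0 or 1")
        self.values = self.values.astype(np.int8)
        self.subgroup_labels = {
            k: np.asarray(v) for k, v in self.subgroup_labels.items()
        }
        for name, vec in self.subgroup_labels.items():
            if len(vec) != n:
                raise ValueError(
                    f"label column {name!r} has length {len(vec)}, expected {n}"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subset(self, column: str, level: str) -> "SymptomMatrix":
        """Rows whose label in `column` equals `level`."""
        if column not in self.subgroup_labels:
            raise KeyError(f"no subgroup column {column!r}")
        mask = self.subgroup_labels[column] == level
        if not mask.any():
            raise KeyError(f"no rows with {column}={level!r}")
        return SymptomMatrix(
            self.values[mask],
            self.item_codes,
            {k: v[mask] for k, v in self.subgroup_labels.items()},
        )

    def levels(self, column: str) -> list[str]:
        if column not in self.subgroup_labels:
            raise KeyError(f"no subgroup column {column!r}")
        return sorted(str(v) for v in np.unique(self.subgroup_labels[column]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.item_codes))
        for name, vec in self.subgroup_labels.items():
            df[name] = vec
        return df


@dataclass
class PrevalenceTable:
    """Per-item presence counts and one-decimal percentages for one cohort."""

    counts: dict[str, int]
    n: int
    cohort: str = "overall"

    def __post_init__(self) -> None:
        for code, c in self.counts.items():
            if not 0 <= c <= self.n:
                raise ValueError(f"count for {code} outside [0, n]")

    @property
    def percentages(self) -> dict[str, float]:
        return {
            code: round_half_up(100.0 * c / self.n, 1)
            for code, c in self.counts.items()
        }

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "item": list(self.counts),
                "count": list(self.counts.values()),
                "n": self.n,
                "percent": [pct[c] for c in self.counts],
                "cohort": self.cohort,
            }
        )

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "n": self.n,
            "counts": dict(self.counts),
            "percentages": self.percentages,
        }


def load_symptom_matrix(
    path,
    item_codes=ITEM_CODES,
    label_columns: tuple[str, ...] = (),
) -> SymptomMatrix:
    """Read a cohort CSV (header mandatory) into a validated SymptomMatrix.

    Rows with any missing or non-binary symptom cell are rejected listwise;
    the rejected count is logged as a warning.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    missing = [c for c in item_codes if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing symptom columns {missing}")
    if len(item_codes) < 2:
        raise ValueError("schema must declare at least two symptom columns")
    for c in label_columns:
        if c not in df.columns:
            raise ValueError(f"{path}: missing label column {c!r}")

    sym = df[list(item_codes)].apply(pd.to_numeric, errors="coerce")
    ok = sym.notna().all(axis=1) & sym.isin([0, 1]).all(axis=1)
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning(
            "rejected %d row(s) with missing or non-binary symptom cells",
            n_rejected,
        )
    if not ok.any():
        raise ValueError(f"{path}: no valid rows remain after validation")
    labels = {c: df.loc[ok, c].astype(str).to_numpy() for c in label_columns}
    return SymptomMatrix(sym.loc[ok].to_numpy(dtype=np.int8), item_codes, labels)


def save_symptom_matrix(matrix: SymptomMatrix, path) -> None:
    """Write a SymptomMatrix to CSV (round-trips with `load_symptom_matrix`)."""
    matrix.to_frame().to_csv(path, index=False)


def prevalence(matrix: SymptomMatrix, subgroup: tuple[str, str] | None = None) -> PrevalenceTable:
    """Presence counts and one-decimal percentages per item.

    Parameters
    ----------
    subgroup : (column, level), optional
        Restrict to rows whose label in `column` equals `level`; the
        percentage denominator is then the subgroup size.
    """
    if subgroup is None:
        sub, name = matrix, "overall"
    else:
        column, level = subgroup
        if level not in matrix.levels(column):
            raise KeyError(f"unknown level {level!r} for column {column!r}")
        sub, name = matrix.subset(column, level), f"{column}={level}"
    counts = {
        code: int(sub.values[:, j].sum()) for j, code in enumerate(sub.item_codes)
    }
    return PrevalenceTable(counts=counts, n=sub.n, cohort=name)
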