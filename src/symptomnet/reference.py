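"""Published symptom-prevalence counts from the REAP-AD depression cohort.

The REAP-AD multinational survey scored 1174 Asian patients with ICD-10
depressive disorders on the ten NICE-listed symptom indicators and reported
presence counts overall and within geographic (UN: East vs South/Southeast
Asia) and economic (World Bank: high- vs middle-income country) subgroups.
The raw patient-level data are not deposited; these printed integer counts
are the published summary and serve two purposes here: as the reporting
layer's arithmetic reference (counts -> one-decimal percentages) and as the
default marginal prevalences for the synthetic-cohort generator.

Note the published report is internally inconsistent about the
middle-income n (733 in the table header vs 773 in the text); 441 + 733 =
1174 and 733/1174 = 62.4%, matching the text's percentage, so 733 is used.
"""

from __future__ import annotations

from .cohort import ITEM_CODES, PrevalenceTable

__all__ = [
    "COHORT_SIZES",
    "SYMPTOM_COUNTS",
    "EDGE_COUNTS",
    "reference_prevalence_table",
    "reference_prevalences",
]

#: Cohort and subgroup sizes (patients).
COHORT_SIZES = {
    "overall": 1174,
    "East": 643,
    "SouthSoutheast": 531,
    "HIC": 441,
    "MIC": 733,
}

#: Published presence counts per symptom, per cohort.
SYMPTOM_COUNTS = {
    "overall": dict(zip(ITEM_CODES, (859, 623, 536, 748, 348, 268, 384, 268, 267, 185))),
    "East": dict(zip(ITEM_CODES, (484, 353, 310, 406, 143, 157, 215, 158, 160, 122))),
    "SouthSoutheast": dict(zip(ITEM_CODES, (375, 270, 226, 342, 205, 111, 169, 110, 107, 63))),
    "HIC": dict(zip(ITEM_CODES, (341, 209, 206, 265, 89, 98, 120, 87, 141, 61))),
    "MIC": dict(zip(ITEM_CODES, (518, 414, 330, 483, 259, 170, 264, 181, 126, 124))),
}

#: Published nonzero-edge counts of the estimated 10-node networks
#: (out of the 45 possible undirected edges).
EDGE_COUNTS = {
    "overall": 29,
    "East": 34,
    "SouthSoutheast": 33,
    "HIC": 22,
    "MIC": 29,
}


def reference_prevalence_table(cohort: str = "overall") -> PrevalenceTable:
    """Published counts for one cohort as a `PrevalenceTable`."""
    if cohort not in SYMPTOM_COUNTS:
        raise KeyError(f"unknown cohort {cohort!r}; choose from {sorted(SYMPTOM_COUNTS)}")
    return PrevalenceTable(
        counts=dict(SYMPTOM_COUNTS[cohort]), n=COHORT_SIZES[cohort], cohort=cohort
    )


def reference_prevalences(cohort: str = "overall") -> list[float]:
    """Published marginal presence rates (proportions, item order fixed)."""
    n = COHORT_SIZES[cohort]
    return [SYMPTOM_COUNTS[cohort][c] / n for c in ITEM_CODES]
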