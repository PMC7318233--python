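"""Node centrality indices for weighted symptom networks.

Three indices, matching the conventions of psychometric network analysis:

- strength: sum of absolute edge weights incident to a node (the primary
  index; a signed variant — "expected influence" — is available),
- closeness: inverse total shortest-path distance to the other nodes,
  with edge distance 1/|w|, scaled by the reachable fraction so that
  nodes in small components are penalized and isolates score 0,
- betweenness: Brandes shortest-path betweenness on the same distances,
  fractional credit for ties, endpoints excluded.

Each index is reported raw and z-standardized, with dense rankings
(rank 1 = most central, ties share a rank).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import NetworkModel

__all__ = [
    "strength",
    "closeness",
    "betweenness",
    "CentralityTable",
    "centrality_table",
]

INDEX_NAMES = ("strength", "closeness", "betweenness")


def strength(model: NetworkModel, signed: bool = False) -> np.ndarray:
    """Per-node strength: sum of |w| (or of signed w) over incident edges."""
    W = model.weights if signed else np.abs(model.weights)
    return W.sum(axis=0)


def closeness(model: NetworkModel) -> np.ndarray:
    """Per-node closeness on 1/|w| distances.

    closeness_i = (r_i / (p - 1)) / sum_j d_ij over the r_i reachable
    other nodes; isolated nodes score 0.
    """
    G = model.to_graph()
    p = model.p
    out = np.zeros(p)
    lengths = dict(nx.all_pairs_dijkstra_path_length(G, weight="distance"))
    for i, code in enumerate(model.item_codes):
        dists = lengths.get(code, {code: 0.0})
        reach = len(dists) - 1
        if reach == 0:
            continue
        total = sum(dists.values())
        out[i] = (reach / (p - 1)) / total
    return out


def betweenness(model: NetworkModel) -> np.ndarray:
    """Per-node shortest-path betweenness on 1/|w| distances (unnormalized)."""
    G = model.to_graph()
    bc = nx.betweenness_centrality(G, weight="distance", normalized=False)
    return np.array([bc[code] for code in model.item_codes])


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _dense_rank_desc(x: np.ndarray) -> np.ndarray:
    """Dense descending ranks: rank 1 = largest value, ties share rank."""
    s = pd.Series(x)
    return s.rank(method="dense", ascending=False).astype(int).to_numpy()


@dataclass
class CentralityTable:
    """Raw, z-standardized and ranked centrality indices per node."""

    table: pd.DataFrame  # index: item codes; columns raw/z/rank per index

    @property
    def item_codes(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    def raw(self, index: str) -> pd.Series:
        return self.table[index]

    def top(self, index: str, k: int = 3) -> list[str]:
        """Top-k nodes by raw value, descending, lexicographic tie-break."""
        s = self.table[index]
        order = sorted(s.index, key=lambda c: (-s[c], c))
        return order[:k]

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def to_dict(self) -> dict:
        return {
            col: {code: float(v) for code, v in self.table[col].items()}
            for col in self.table.columns
        }


def centrality_table(model: NetworkModel, signed_strength: bool = False) -> CentralityTable:
    """Compute all three indices with z-scores and dense rankings."""
    values = {
        "strength": strength(model, signed=signed_strength),
        "closeness": closeness(model),
        "betweenness": betweenness(model),
    }
    df = pd.DataFrame(index=list(model.item_codes))
    for name in INDEX_NAMES:
        v = values[name]
        df[name] = v
        df[f"{name}_z"] = _zscore(v)
        df[f"{name}_rank"] = _dense_rank_desc(v)
    return CentralityTable(df)
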