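"""Spin-glass community detection on the weighted signed symptom network.

Communities minimize a Reichardt-Bornholdt Potts Hamiltonian extended to
signed weights: within-community positive weight is rewarded, negative
weight penalized, and both are compared against a configuration-style null
model scaled by the resolution parameter gamma.  With the strengths of the
null model taken from absolute weights (default) the energy of assignment
sigma is

    H(sigma) = - sum_{i<j} delta(sigma_i, sigma_j) [ w_ij - gamma s_i s_j / (2m) ],

with s_i = sum_j |w_ij| and m = sum_{i<j} |w_ij|.  Optimization is
single-spin-flip simulated annealing with geometric cooling (the published
analysis parameters: start temperature 1, stop temperature 0.01, cooling
factor 0.99, at most 17 spin states), followed by a deterministic greedy
descent; the all-singleton and one-community partitions are always
evaluated as candidates, so the result is never worse than either.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .network import EDGE_TOL, NetworkModel

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityPartition",
    "hamiltonian",
    "coupling_matrix",
    "SpinglassCommunities",
    "spinglass_detect",
    "isolate_outliers",
]


@dataclass
class CommunityPartition:
    """Node -> community assignment (ids contiguous from 1) with its energy."""

    assignment: dict[str, int]
    hamiltonian: float
    params: dict
    seed: int
    isolated: tuple[str, ...] = ()
    largest_cluster: tuple[str, ...] = ()

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, c in self.assignment.items():
            out.setdefault(c, []).append(node)
        return out

    def as_sets(self) -> set[frozenset]:
        """Label-free representation for partition comparison."""
        return {frozenset(v) for v in self.groups().values()}

    def to_dict(self) -> dict:
        return {
            "assignment": dict(self.assignment),
            "n_communities": self.n_communities,
            "hamiltonian": float(self.hamiltonian),
            "params": dict(self.params),
            "seed": self.seed,
            "isolated": list(self.isolated),
            "largest_cluster": list(self.largest_cluster),
        }


def coupling_matrix(
    weights: np.ndarray, gamma: float = 0.5, null_model: str = "abs"
) -> np.ndarray:
    """Pairwise couplings B_ij = w_ij - gamma * p_ij (zero diagonal).

    ``null_model="abs"`` uses configuration-model expected weights built
    from absolute strengths; ``"signed"`` applies separate configuration
    null terms to the positive and negative parts.
    """
    W = np.asarray(weights, dtype=float)
    p = W.shape[0]
    B = W.copy()
    np.fill_diagonal(B, 0.0)
    if null_model == "abs":
        s = np.abs(B).sum(axis=1)
        two_m = s.sum()
        if two_m > 0:
            B = B - gamma * np.outer(s, s) / two_m
    elif null_model == "signed":
        for sign in (1.0, -1.0):
            part = np.clip(sign * B, 0.0, None)
            s = part.sum(axis=1)
            two_m = s.sum()
            if two_m > 0:
                B = B - sign * gamma * np.outer(s, s) / two_m
    else:
        raise ValueError("null_model must be 'abs' or 'signed'")
    np.fill_diagonal(B, 0.0)
    return B


def hamiltonian(
    weights: np.ndarray,
    assignment,
    gamma: float = 0.5,
    null_model: str = "abs",
) -> float:
    """Signed spin-glass energy of an assignment; lower is better."""
    B = coupling_matrix(weights, gamma, null_model)
    sigma = np.asarray(assignment)
    same = sigma[:, None] == sigma[None, :]
    return float(-0.5 * B[same].sum())


def _energy_from_coupling(B: np.ndarray, sigma: np.ndarray) -> float:
    same = sigma[:, None] == sigma[None, :]
    return float(-0.5 * B[same].sum())


def _greedy_descent(B: np.ndarray, sigma: np.ndarray, q: int) -> np.ndarray:
    """Deterministic best-improvement single-move descent to a local optimum."""
    p = B.shape[0]
    sigma = sigma.copy()
    improved = True
    while improved:
        improved = False
        for v in range(p):
            # gain of joining each spin state: sum of couplings to members
            gains = np.array([B[v, sigma == c].sum() for c in range(q)])
            gains[sigma[v]] = B[v, sigma == sigma[v]].sum()
            best = int(np.argmax(gains))
            if gains[best] > gains[sigma[v]] + 1e-12:
                sigma[v] = best
                improved = True
    return sigma


def _relabel(sigma: np.ndarray) -> np.ndarray:
    """Contiguous community ids from 1 in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(sigma)
    for i, c in enumerate(sigma):
        if c not in mapping:
            mapping[c] = len(mapping) + 1
        out[i] = mapping[c]
    return out


class SpinglassCommunities(BaseEstimator):
    """Simulated-annealing spin-glass community detection.

    Parameters
    ----------
    gamma : float, default 0.5
        Resolution: weight of the null-model term.
    spins : int, default 17
        Upper bound on the number of spin states (capped at p).
    start_temp, stop_temp, cooling_factor :
        Geometric annealing schedule (defaults 1.0, 0.01, 0.99).
    restarts : int, default 1
        Independent annealing runs; the best energy is kept.
    null_model : {"abs", "signed"}
    random_state : int, default 0

    Attributes
    ----------
    labels_ : ndarray (p,), community ids contiguous from 1.
    hamiltonian_ : float, energy of the returned assignment.
    """

    def __init__(
        self,
        gamma: float = 0.5,
        spins: int = 17,
        start_temp: float = 1.0,
        stop_temp: float = 0.01,
        cooling_factor: float = 0.99,
        restarts: int = 1,
        null_model: str = "abs",
        random_state: int = 0,
    ):
        self.gamma = gamma
        self.spins = spins
        self.start_temp = start_temp
        self.stop_temp = stop_temp
        self.cooling_factor = cooling_factor
        self.restarts = restarts
        self.null_model = null_model
        self.random_state = random_state

    def fit(self, X, y=None):
        """Detect communities on a weight matrix or NetworkModel."""
        if isinstance(X, NetworkModel):
            W, codes = X.weights, X.item_codes
        else:
            W = np.asarray(X, dtype=float)
            codes = tuple(f"V{j + 1}" for j in range(W.shape[1]))
        p = W.shape[0]
        if p < 2:
            raise ValueError("need at least two nodes")
        q = min(self.spins, p)
        B = coupling_matrix(W, self.gamma, self.null_model)
        rng = np.random.default_rng(self.random_state)

        best_sigma = np.arange(p) % q  # all-singleton when q >= p
        best_e = _energy_from_coupling(B, best_sigma)
        for cand in (np.zeros(p, dtype=int),):  # one-community candidate
            e = _energy_from_coupling(B, cand)
            if e < best_e:
                best_sigma, best_e = cand, e

        for _ in range(max(1, self.restarts)):
            sigma = rng.integers(0, q, size=p)
            energy = _energy_from_coupling(B, sigma)
            run_best, run_best_e = sigma.copy(), energy
            T = self.start_temp
            while T > self.stop_temp:
                for _ in range(p):
                    v = int(rng.integers(p))
                    new = int(rng.integers(q))
                    if new == sigma[v]:
                        continue
                    old = sigma[v]
                    # B[v, v] = 0, so including v in the old mask is harmless
                    dE = -(B[v, sigma == new].sum() - B[v, sigma == old].sum())
                    if dE < 0 or rng.random() < math.exp(-dE / T):
                        sigma[v] = new
                        energy += dE
                        if energy < run_best_e - 1e-15:
                            run_best, run_best_e = sigma.copy(), energy
                T *= self.cooling_factor
            refined = _greedy_descent(B, run_best, q)
            refined_e = _energy_from_coupling(B, refined)
            if refined_e < best_e:
                best_sigma, best_e = refined, refined_e

        self.labels_ = _relabel(best_sigma)
        self.hamiltonian_ = best_e
        self.item_codes_ = codes
        return self

    def partition_(self) -> CommunityPartition:
        return CommunityPartition(
            assignment={c: int(l) for c, l in zip(self.item_codes_, self.labels_)},
            hamiltonian=self.hamiltonian_,
            params={
                "gamma_resolution": self.gamma,
                "spins": self.spins,
                "start_temp": self.start_temp,
                "stop_temp": self.stop_temp,
                "cooling_factor": self.cooling_factor,
                "null_model": self.null_model,
                "restarts": self.restarts,
            },
            seed=self.random_state,
        )


def spinglass_detect(
    model: NetworkModel, seed: int = 0, **params
) -> CommunityPartition:
    """Community partition of a fitted network (see SpinglassCommunities)."""
    est = SpinglassCommunities(random_state=seed, **params).fit(model)
    est.item_codes_ = model.item_codes
    return est.partition_()


def isolate_outliers(
    model: NetworkModel, partition: CommunityPartition, tol: float = EDGE_TOL
) -> CommunityPartition:
    """Flag virtually disconnected nodes and report the largest cluster.

    A node whose total absolute connection weight is below `tol` is marked
    isolated/outlier (mirroring symptoms that sit apart from the main
    symptom constellation); the returned partition carries the flags and
    the membership of the largest community.
    """
    strength = np.abs(model.weights).sum(axis=0)
    isolated = tuple(
        code for code, s in zip(model.item_codes, strength) if s < tol
    )
    # an isolated node couples to nothing, so its community placement is
    # energy-neutral; exclude isolates from the largest-cluster report
    groups = {
        c: [n for n in nodes if n not in isolated]
        for c, nodes in partition.groups().items()
    }
    largest = max(groups.values(), key=lambda g: (len(g), g))
    return CommunityPartition(
        assignment=dict(partition.assignment),
        hamiltonian=partition.hamiltonian,
        params=dict(partition.params),
        seed=partition.seed,
        isolated=isolated,
        largest_cluster=tuple(sorted(largest)),
    )
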