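"""Modular decomposition and hub classification.

The network is decomposed with the Louvain algorithm (resolution gamma = 1);
because Louvain is stochastic, a consensus partition is formed by running it
150 times, building the node-pair co-assignment (agreement) matrix D,
zeroing entries below 50%, and re-clustering D until all runs agree. Nodes
are then characterized by their within-module degree z-score and
participation coefficient, and classified as provincial hubs
(z >= 1 and P < 0.3) or connector hubs (z < 1 and P >= 0.3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Partition",
    "modularity",
    "louvain",
    "consensus_partition",
    "within_module_degree",
    "participation_coefficient",
    "classify_hubs",
    "hub_prevalence",
    "count_hubs",
]


@dataclass
class Partition:
    """Node-to-module assignment with its modularity on the source graph."""

    assignment: np.ndarray  # module id per node, ids 0..M-1, every id used
    q: float

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        ids = np.unique(self.assignment)
        if not np.array_equal(ids, np.arange(ids.size)):
            # relabel to contiguous 0..M-1 preserving first-appearance order
            order = {m: i for i, m in enumerate(pd.unique(self.assignment))}
            self.assignment = np.array([order[m] for m in self.assignment])

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max()) + 1

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment)


def modularity(weights: np.ndarray, assignment: np.ndarray, gamma: float = 1.0) -> float:
    """Newman–Girvan weighted modularity Q^w of a partition.

    Q^w = (1/l^w) * sum_ij [w_ij - gamma * k_i^w k_j^w / l^w] delta(m_i, m_j),
    where l^w sums the full symmetric matrix (each undirected edge counted
    twice) and k_i^w is node strength. Two disconnected unit-weight
    triangles partitioned into their cliques give Q = 0.5 under this
    convention.
    """
    W = np.asarray(weights, dtype=float)
    if W.size == 0 or W.sum() == 0:
        raise ValueError("modularity undefined for an empty graph")
    m = np.asarray(assignment, dtype=int)
    if m.shape[0] != W.shape[0]:
        raise ValueError("assignment length does not match matrix size")
    lw = W.sum()
    k = W.sum(axis=1)
    q = 0.0
    for mod in np.unique(m):
        idx = m == mod
        q += W[np.ix_(idx, idx)].sum() / lw - gamma * (k[idx].sum() / lw) ** 2
    return float(q)


def louvain(weights: np.ndarray, gamma: float = 1.0, seed: int | None = None) -> Partition:
    """One Louvain run: greedy local moves plus graph aggregation.

    Node visit order is shuffled by ``seed``; the returned Q is the
    modularity of the returned assignment (self-consistent by construction).
    """
    W = np.asarray(weights, dtype=float)
    G = nx.from_numpy_array(W)
    comms = nx.community.louvain_communities(G, weight="weight", resolution=gamma, seed=seed)
    assignment = np.empty(W.shape[0], dtype=int)
    for mid, nodes in enumerate(comms):
        for v in nodes:
            assignment[v] = mid
    return Partition(assignment=assignment, q=modularity(W, assignment, gamma=gamma))


def agreement_matrix(weights: np.ndarray, n_reps: int = 150, gamma: float = 1.0,
                     seed: int | None = None) -> np.ndarray:
    """Node-pair co-assignment probabilities over repeated Louvain runs.

    D_ij is the fraction of runs assigning i and j to the same module;
    entries lie in [0, 1] and D_ii = 1.
    """
    W = np.asarray(weights, dtype=float)
    n = W.shape[0]
    rng = np.random.default_rng(seed)
    D = np.zeros((n, n))
    for _ in range(n_reps):
        a = louvain(W, gamma=gamma, seed=int(rng.integers(2**31 - 1))).assignment
        D += (a[:, None] == a[None, :]).astype(float)
    return D / n_reps


def _runs_agree(assignments: np.ndarray) -> bool:
    """True iff all rows of (n_runs, n_nodes) are identical up to relabeling."""
    ref = assignments[0]
    for row in assignments[1:]:
        # identical up to relabeling <=> co-assignment patterns match
        if not np.array_equal(
            ref[:, None] == ref[None, :], row[:, None] == row[None, :]
        ):
            return False
    return True


def consensus_partition(weights: np.ndarray, n_reps: int = 150, tau: float = 0.5,
                        gamma: float = 1.0, seed: int | None = None,
                        max_rounds: int = 20) -> Partition:
    """Consensus clustering over repeated Louvain runs.

    D_ij is the fraction of ``n_reps`` runs assigning i and j to the same
    module; entries below ``tau`` are zeroed and Louvain is re-run on D,
    iterating until all runs return one partition (or ``max_rounds`` is
    hit, in which case the modal partition is returned with a warning).
    The returned Q is the modularity of the final assignment on the
    *original* graph.
    """
    W = np.asarray(weights, dtype=float)
    n = W.shape[0]
    rng = np.random.default_rng(seed)
    current = W
    for _ in range(max_rounds):
        runs = np.empty((n_reps, n), dtype=int)
        for r in range(n_reps):
            runs[r] = louvain(current, gamma=gamma, seed=int(rng.integers(2**31 - 1))).assignment
        if _runs_agree(runs):
            final = runs[0]
            return Partition(assignment=final, q=modularity(W, final, gamma=gamma))
        D = np.zeros((n, n))
        for r in range(n_reps):
            a = runs[r]
            D += (a[:, None] == a[None, :]).astype(float)
        D /= n_reps
        D[D < tau] = 0.0
        np.fill_diagonal(D, 0.0)
        current = D
    warnings.warn("consensus did not converge; returning modal partition", stacklevel=2)
    keys = pd.Series([tuple((a[:, None] == a[None, :]).ravel()) for a in runs])
    modal_key = keys.value_counts().index[0]
    modal = runs[int((keys == modal_key).idxmax())]
    return Partition(assignment=modal, q=modularity(W, modal, gamma=gamma))


def within_module_degree(weights: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    """Within-module degree z-score per node, z_i = (k_i^m - mean_m) / sd_m.

    k_i^m is node i's summed weight to its own module; the mean and
    *population* standard deviation are taken over that module's nodes.
    A module with zero spread yields z = 0 for its nodes.
    """
    W = np.asarray(weights, dtype=float)
    m = np.asarray(assignment, dtype=int)
    z = np.zeros(W.shape[0])
    for mod in np.unique(m):
        idx = m == mod
        k_in = W[np.ix_(idx, idx)].sum(axis=1)
        sd = k_in.std()  # population SD
        if sd > 0:
            z[idx] = (k_in - k_in.mean()) / sd
    return z


def participation_coefficient(weights: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    """Participation coefficient p_i = 1 - sum_m (k_i^m / k_i)^2; p = 0 for isolated nodes."""
    W = np.asarray(weights, dtype=float)
    m = np.asarray(assignment, dtype=int)
    k = W.sum(axis=1)
    frac_sq = np.zeros(W.shape[0])
    for mod in np.unique(m):
        idx = m == mod
        k_m = W[:, idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_sq += np.where(k > 0, (k_m / np.where(k > 0, k, 1.0)) ** 2, 0.0)
    p = np.where(k > 0, 1.0 - frac_sq, 0.0)
    return p


def classify_hubs(z: np.ndarray, p: np.ndarray, z_thresh: float = 1.0,
                  p_thresh: float = 0.3) -> np.ndarray:
    """Classify nodes as 'provincial', 'connector', or 'neither'.

    Provincial: z >= z_thresh and p < p_thresh (hub wired within its
    community). Connector: z < z_thresh and p >= p_thresh (hub bridging
    communities). Nodes high on both measures satisfy neither conjunction
    and are labelled 'neither'.
    """
    z = np.asarray(z, dtype=float)
    p = np.asarray(p, dtype=float)
    out = np.full(z.shape, "neither", dtype=object)
    out[(z >= z_thresh) & (p < p_thresh)] = "provincial"
    out[(z < z_thresh) & (p >= p_thresh)] = "connector"
    return out


def hub_prevalence(hub_tables: list[np.ndarray], groups: list[str],
                   min_ratio: float = 0.2) -> pd.DataFrame:
    """Per group per node: fraction of subjects holding each hub class.

    Returns a tidy frame with columns group, node, class, prevalence,
    flagged (prevalence > ``min_ratio``).
    """
    if not hub_tables:
        raise ValueError("no subjects")
    n = len(hub_tables[0])
    rows = []
    for g in pd.unique(np.asarray(groups)):
        members = [t for t, gg in zip(hub_tables, groups) if gg == g]
        stack = np.vstack(members)
        for cls in ("provincial", "connector"):
            prev = (stack == cls).mean(axis=0)
            for node in range(n):
                rows.append({
                    "group": g, "node": node, "class": cls,
                    "prevalence": float(prev[node]),
                    "flagged": bool(prev[node] > min_ratio),
                })
    return pd.DataFrame(rows)


def count_hubs(hub_table: np.ndarray) -> tuple[int, int]:
    """Counts of (provincial, connector) hubs for one subject."""
    hub_table = np.asarray(hub_table)
    return int((hub_table == "provincial").sum()), int((hub_table == "connector").sum())
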