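"""Network construction: scaling, pruning, binarization, edge classes.

Raw streamline-count matrices are turned into analysis-ready networks by
(1) fractional scaling — division by the mean count over all node pairs,
removing per-subject tractography scale; (2) discarding the weakest 5% of
connections as likely spurious streamlines; (3) optional binarization at a
fixed sparsity for robustness analyses; (4) splitting edges into short- and
long-range classes by a fiber-length threshold; and (5) extraction of the
two intra-hemispheric subnetworks.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .connectome import Connectome


def _upper_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def fractional_scale(weights: np.ndarray, include_zeros: bool = True) -> np.ndarray:
    """Divide every entry by the mean weight over node pairs.

    With ``include_zeros`` (default) the mean is taken over all n(n-1)/2
    unordered pairs, zero entries included, so the scaled matrix has mean
    off-diagonal value exactly 1. Setting it False averages over connected
    pairs only.
    """
    W = np.asarray(weights, dtype=float)
    iu, ju = _upper_indices(W.shape[0])
    vals = W[iu, ju]
    if include_zeros:
        mean = vals.mean()
    else:
        nz = vals[vals > 0]
        mean = nz.mean() if nz.size else 0.0
    if mean == 0:
        raise ValueError("cannot fractionally scale an all-zero matrix")
    return W / mean


def prune_weakest(weights: np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """Zero out the weakest ``fraction`` of nonzero edges.

    The quota is floor(fraction * E) where E counts nonzero upper-triangle
    edges; ties at the cutoff weight are broken in ascending (weight, i, j)
    order so the result is deterministic.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    W = np.array(weights, dtype=float)
    if fraction == 0:
        return W
    iu, ju = _upper_indices(W.shape[0])
    vals = W[iu, ju]
    nz = np.flatnonzero(vals > 0)
    quota = int(np.floor(fraction * nz.size))
    if quota == 0:
        return W
    order = np.lexsort((ju[nz], iu[nz], vals[nz]))
    drop = nz[order[:quota]]
    W[iu[drop], ju[drop]] = 0.0
    W[ju[drop], iu[drop]] = 0.0
    return W


def binarize_at_sparsity(weights: np.ndarray, sparsity: float) -> np.ndarray:
    """Keep the strongest ``sparsity`` fraction of node pairs as 1-edges.

    Retains floor(sparsity * n(n-1)/2) pairs, descending (weight, i, j)
    tie order. If fewer nonzero weights exist than the quota, all nonzero
    edges are kept and a warning is emitted.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    W = np.asarray(weights, dtype=float)
    n = W.shape[0]
    iu, ju = _upper_indices(n)
    vals = W[iu, ju]
    quota = int(np.floor(sparsity * vals.size))
    nz = np.flatnonzero(vals > 0)
    if nz.size < quota:
        warnings.warn(
            f"only {nz.size} nonzero edges available for sparsity quota {quota}; keeping all",
            stacklevel=2,
        )
        keep = nz
    else:
        order = np.lexsort((-ju, -iu, vals))[::-1]  # descending (weight, i, j)
        keep = order[:quota]
        keep = keep[vals[keep] > 0]
    B = np.zeros_like(W)
    B[iu[keep], ju[keep]] = 1.0
    B[ju[keep], iu[keep]] = 1.0
    return B


def split_by_length(connectome: Connectome, length_threshold_mm: float) -> tuple[Connectome, Connectome]:
    """Partition edges into short-range (< threshold) and long-range (>= threshold) networks."""
    if connectome.lengths is None:
        raise ValueError("connectome has no edge-length matrix")
    W = connectome.weights
    L = connectome.lengths
    short_mask = L < length_threshold_mm
    short = np.where(short_mask, W, 0.0)
    long_ = np.where(~short_mask, W, 0.0)
    np.fill_diagonal(short, 0.0)
    np.fill_diagonal(long_, 0.0)
    return (
        connectome.copy_with(short, subject_id=connectome.subject_id + "_short"),
        connectome.copy_with(long_, subject_id=connectome.subject_id + "_long"),
    )


def hemisphere_subnetworks(connectome: Connectome) -> tuple[Connectome, Connectome]:
    """Extract the left and right intra-hemispheric subnetworks by masking."""
    hemi = np.asarray(connectome.node_hemisphere)
    out = []
    for side in ("L", "R"):
        idx = np.flatnonzero(hemi == side)
        sub = Connectome(
            weights=connectome.weights[np.ix_(idx, idx)],
            lengths=None if connectome.lengths is None else connectome.lengths[np.ix_(idx, idx)],
            node_labels=[connectome.node_labels[i] for i in idx],
            node_hemisphere=[side] * len(idx),
            subject_id=f"{connectome.subject_id}_{side}",
        )
        out.append(sub)
    return out[0], out[1]


def connective_density(weights: np.ndarray) -> float:
    """Fraction of node pairs with a nonzero connection."""
    W = np.asarray(weights, dtype=float)
    iu, ju = _upper_indices(W.shape[0])
    vals = W[iu, ju]
    return float(np.count_nonzero(vals) / vals.size)


def is_connected(weights: np.ndarray) -> bool:
    """True iff the nonzero-weight graph has a single component spanning all nodes."""
    W = np.asarray(weights, dtype=float)
    n_comp, _ = connected_components(csr_matrix(W != 0), directed=False)
    return bool(n_comp == 1)
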