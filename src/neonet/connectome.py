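"""Connectome container and plain-text I/O.

A connectome is a weighted, undirected, self-loop-free graph over a fixed
brain parcellation (90 regions by default), stored as a dense symmetric
matrix of normalized streamline counts, optionally accompanied by a matrix
of mean fiber lengths (mm) and a node table (label, hemisphere, coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SYMMETRY_TOL = 1e-8


def _check_weights(weights: np.ndarray, tol: float = SYMMETRY_TOL) -> np.ndarray:
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {weights.shape}")
    if np.max(np.abs(weights - weights.T)) > tol:
        raise ValueError("weight matrix is asymmetric beyond tolerance")
    if np.any(weights < 0):
        i, j = np.argwhere(weights < 0)[0]
        raise ValueError(f"negative weight at ({i}, {j})")
    weights = (weights + weights.T) / 2.0
    np.fill_diagonal(weights, 0.0)
    return weights


@dataclass
class Connectome:
    """One subject's structural network.

    Parameters
    ----------
    weights : (n, n) ndarray
        Symmetric nonnegative connectivity matrix, zero diagonal.
    lengths : (n, n) ndarray, optional
        Symmetric positive edge-length matrix in millimetres.
    node_labels : list of str
        Region labels, length n.
    node_hemisphere : list of {"L", "R"}
        Hemisphere of each region.
    subject_id : str
    """

    weights: np.ndarray
    lengths: np.ndarray | None = None
    node_labels: list[str] = field(default_factory=list)
    node_hemisphere: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.weights = _check_weights(self.weights)
        n = self.weights.shape[0]
        if not self.node_labels:
            self.node_labels = [f"node{i:03d}" for i in range(n)]
        if not self.node_hemisphere:
            half = n // 2
            self.node_hemisphere = ["L"] * half + ["R"] * (n - half)
        if len(self.node_labels) != n or len(self.node_hemisphere) != n:
            raise ValueError("node table length does not match matrix size")
        if self.lengths is not None:
            L = np.asarray(self.lengths, dtype=float)
            if L.shape != self.weights.shape:
                raise ValueError("length matrix shape mismatch")
            if np.max(np.abs(L - L.T)) > SYMMETRY_TOL:
                raise ValueError("length matrix is asymmetric beyond tolerance")
            off = ~np.eye(L.shape[0], dtype=bool)
            if np.any(L[off] <= 0):
                raise ValueError("edge lengths must be positive off-diagonal")
            self.lengths = (L + L.T) / 2.0

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def copy_with(self, weights: np.ndarray, subject_id: str | None = None) -> "Connectome":
        """Return a copy sharing the node table but carrying new weights."""
        return Connectome(
            weights=np.array(weights, dtype=float),
            lengths=None if self.lengths is None else self.lengths.copy(),
            node_labels=list(self.node_labels),
            node_hemisphere=list(self.node_hemisphere),
            subject_id=self.subject_id if subject_id is None else subject_id,
        )


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a headerless TSV matrix."""
    arr = np.loadtxt(path, delimiter="\t", ndmin=2)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{path}: matrix is {arr.shape[0]}x{arr.shape[1]}, expected square")
    return arr


def write_matrix(path: str | Path, matrix: np.ndarray) -> None:
    # full double precision so a write/read round trip is exact
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter="\t", fmt="%.17g")


def read_node_table(path: str | Path) -> pd.DataFrame:
    """Node table CSV with columns label,hemisphere,x,y,z."""
    df = pd.read_csv(path)
    required = {"label", "hemisphere"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: node table needs columns {sorted(required)}")
    bad = set(df["hemisphere"]) - {"L", "R"}
    if bad:
        raise ValueError(f"{path}: unknown hemisphere codes {sorted(bad)}")
    return df


def read_connectome(
    matrix_path: str | Path,
    nodes_path: str | Path | None = None,
    lengths_path: str | Path | None = None,
    subject_id: str = "",
) -> Connectome:
    weights = read_matrix(matrix_path)
    labels: list[str] = []
    hemis: list[str] = []
    if nodes_path is not None:
        nodes = read_node_table(nodes_path)
        if len(nodes) != weights.shape[0]:
            raise ValueError(
                f"node table has {len(nodes)} rows but matrix is {weights.shape[0]}x{weights.shape[0]}"
            )
        labels = nodes["label"].tolist()
        hemis = nodes["hemisphere"].tolist()
    lengths = read_matrix(lengths_path) if lengths_path is not None else None
    return Connectome(
        weights=weights,
        lengths=lengths,
        node_labels=labels,
        node_hemisphere=hemis,
        subject_id=subject_id or Path(matrix_path).stem,
    )


def write_connectome(connectome: Connectome, matrix_path: str | Path,
                     lengths_path: str | Path | None = None) -> None:
    write_matrix(matrix_path, connectome.weights)
    if lengths_path is not None and connectome.lengths is not None:
        write_matrix(lengths_path, connectome.lengths)
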