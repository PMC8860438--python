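"""Electrode montage geometry and neighborhood structure.

Channel neighborhoods drive the spatial clustering in the permutation
statistics.  Positions are schematic 2-D coordinates of the 10-20 system
(azimuthal projection, unit head radius).  The default neighbor relation
is the Delaunay triangulation of those positions, mirroring the
triangulation-based neighbor templates EEG toolboxes default to on sparse
montages; it links lateral, vertical and diagonal neighbors (24 edges on
the 11-channel montage).  A plain distance-threshold variant is also
available.  The minimum-neighbor count for cluster membership is zero: an
isolated supra-threshold electrode is a valid singleton cluster, which
matters on a montage this sparse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Schematic 2-D positions (x toward right ear, y toward nasion).
POSITIONS_1020 = {
    "F3": (-0.32, 0.41), "Fz": (0.0, 0.40), "F4": (0.32, 0.41),
    "C3": (-0.40, 0.00), "Cz": (0.0, 0.00), "C4": (0.40, 0.00),
    "P3": (-0.32, -0.41), "Pz": (0.0, -0.40), "P4": (0.32, -0.41),
    "O1": (-0.26, -0.73), "O2": (0.26, -0.73),
}


@dataclass
class Adjacency:
    """Symmetric, irreflexive channel-neighbor relation."""

    labels: tuple
    matrix: np.ndarray  # boolean (n, n)

    def __post_init__(self):
        self.labels = tuple(self.labels)
        m = np.asarray(self.matrix, dtype=bool)
        if m.shape != (len(self.labels),) * 2:
            raise ValueError("adjacency matrix shape does not match labels")
        if not np.array_equal(m, m.T):
            raise ValueError("adjacency must be symmetric")
        if m.diagonal().any():
            raise ValueError("adjacency must be irreflexive")
        self.matrix = m

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def neighbors(self, label: str) -> tuple:
        i = self.labels.index(label)
        return tuple(self.labels[j] for j in np.where(self.matrix[i])[0])

    def reorder(self, labels) -> "Adjacency":
        idx = [self.labels.index(l) for l in labels]
        return Adjacency(tuple(labels), self.matrix[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"channel": a, "neighbor": b}
            for i, a in enumerate(self.labels)
            for j, b in enumerate(self.labels)
            if self.matrix[i, j] and i < j
        ]
        return pd.DataFrame(rows, columns=["channel", "neighbor"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, labels=None) -> "Adjacency":
        if labels is None:
            labels = sorted(set(df["channel"]) | set(df["neighbor"]))
        labels = tuple(labels)
        m = np.zeros((len(labels), len(labels)), dtype=bool)
        for _, row in df.iterrows():
            i, j = labels.index(row["channel"]), labels.index(row["neighbor"])
            m[i, j] = m[j, i] = True
        return cls(labels, m)

    @classmethod
    def read_csv(cls, path, labels=None) -> "Adjacency":
        return cls.from_frame(pd.read_csv(path), labels)


def _positions(labels) -> np.ndarray:
    missing = [l for l in labels if l not in POSITIONS_1020]
    if missing:
        raise KeyError(f"no 10-20 position for channels {missing}")
    return np.array([POSITIONS_1020[l] for l in labels])


def montage_adjacency(labels, method: str = "triangulation",
                      max_distance: float = 0.45) -> Adjacency:
    """Channel adjacency from the schematic 10-20 positions.

    ``method="triangulation"`` links channels sharing a Delaunay-triangle
    edge (the toolbox-default-style neighborhood); ``method="distance"``
    links channels within ``max_distance``.
    """
    labels = tuple(labels)
    pos = _positions(labels)
    n = len(labels)
    m = np.zeros((n, n), dtype=bool)
    if method == "triangulation":
        if n < 3:
            m[:] = ~np.eye(n, dtype=bool)
            return Adjacency(labels, m)
        from scipy.spatial import Delaunay
        for simplex in Delaunay(pos).simplices:
            for i in range(3):
                a, b = simplex[i], simplex[(i + 1) % 3]
                m[a, b] = m[b, a] = True
    elif method == "distance":
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        m = (d <= max_distance) & ~np.eye(n, dtype=bool)
    else:
        raise ValueError(f"unknown adjacency method {method!r}")
    return Adjacency(labels, m)


def chain_adjacency(n: int) -> np.ndarray:
    """1-D lattice adjacency for ordered bins (time or frequency axes)."""
    m = np.zeros((n, n), dtype=bool)
    idx = np.arange(n - 1)
    m[idx, idx + 1] = m[idx + 1, idx] = True
    return m
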