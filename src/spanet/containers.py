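"""Labeled square-matrix containers shared across the pipeline.

The analysis moves between four views of the same node set: a distance
matrix between region capitals, a real-valued gravity (interaction
intensity) matrix, a binary directed association network, and generic
dyadic matrices used by QAP.  Each container pairs a square ``numpy``
array with an ordered list of region labels and validates the shape
invariants its role requires.  On-disk form is a labeled delimited table
(first row and first column are region labels) read and written through
pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "GravityMatrix",
    "DirectedNetwork",
    "DyadMatrix",
    "read_labeled_matrix",
    "write_labeled_matrix",
]


def read_labeled_matrix(path, sep=None) -> pd.DataFrame:
    """Read a square labeled matrix (labels in first row and column)."""
    df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row labels and column labels differ")
    return df


def write_labeled_matrix(m: np.ndarray, labels, path, sep=",", float_format=None) -> None:
    pd.DataFrame(m, index=labels, columns=labels).to_csv(
        path, sep=sep, float_format=float_format
    )


def _check_square(m: np.ndarray, labels) -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got shape {m.shape}")
    if len(labels) != m.shape[0]:
        raise ValueError(
            f"{len(labels)} labels for a {m.shape[0]}x{m.shape[0]} matrix"
        )
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate region labels")
    return m


@dataclass
class DistanceMatrix:
    """Symmetric positive inter-region distances (km), zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.labels = [str(x) for x in self.labels]
        self.d = _check_square(self.d, self.labels).astype(float)
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        off = self.d[~np.eye(len(self.labels), dtype=bool)]
        if off.size and off.min() <= 0:
            raise ValueError("off-diagonal distances must be strictly positive")

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def from_csv(cls, path, sep=None) -> "DistanceMatrix":
        df = read_labeled_matrix(path, sep=sep)
        return cls(list(df.index), df.to_numpy(dtype=float))

    def to_csv(self, path, sep=",") -> None:
        write_labeled_matrix(self.d, self.labels, path, sep=sep)


@dataclass
class GravityMatrix:
    """Gravity intensities y_ij with asymmetric contribution weights k_ij.

    ``y`` is nonnegative with a zero diagonal; ``k`` satisfies
    k_ij + k_ji = 1 off the diagonal (each dyad's intensity is split by
    the two regions' pollution shares).
    """

    labels: list[str]
    y: np.ndarray
    k: np.ndarray

    def __post_init__(self):
        self.y = _check_square(self.y, self.labels).astype(float)
        self.k = _check_square(self.k, self.labels).astype(float)
        n = len(self.labels)
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(np.diag(self.y), 0.0):
            raise ValueError("gravity matrix diagonal must be zero")
        if (self.y < -1e-12).any():
            raise ValueError("gravity intensities must be nonnegative")
        if n > 1 and not np.allclose((self.k + self.k.T)[off], 1.0):
            raise ValueError("contribution weights must satisfy k_ij + k_ji = 1")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_csv(self, path, sep=",") -> None:
        write_labeled_matrix(self.y, self.labels, path, sep=sep)


@dataclass
class DirectedNetwork:
    """Binary directed association network; a_ij = 1 means i sends a tie to j."""

    labels: list[str]
    a: np.ndarray

    def __post_init__(self):
        self.labels = [str(x) for x in self.labels]
        a = _check_square(self.a, self.labels)
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.a = a.astype(np.int8)
        np.fill_diagonal(self.a, 0)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_arcs(self) -> int:
        return int(self.a.sum())

    def in_degrees(self) -> np.ndarray:
        return self.a.sum(axis=0).astype(int)

    def out_degrees(self) -> np.ndarray:
        return self.a.sum(axis=1).astype(int)

    def symmetrized(self) -> np.ndarray:
        """Underlying undirected adjacency (weak symmetrization)."""
        return ((self.a + self.a.T) > 0).astype(np.int8)

    def to_networkx(self, directed: bool = True) -> nx.Graph:
        if directed:
            g = nx.from_numpy_array(self.a, create_using=nx.DiGraph)
        else:
            g = nx.from_numpy_array(self.symmetrized(), create_using=nx.Graph)
        return nx.relabel_nodes(g, dict(enumerate(self.labels)))

    @classmethod
    def from_csv(cls, path, sep=None) -> "DirectedNetwork":
        df = read_labeled_matrix(path, sep=sep)
        return cls(list(df.index), df.to_numpy(dtype=int))

    def to_csv(self, path, sep=",") -> None:
        write_labeled_matrix(self.a, self.labels, path, sep=sep)

    def to_edge_list(self) -> pd.DataFrame:
        src, dst = np.nonzero(self.a)
        return pd.DataFrame(
            {
                "source": [self.labels[i] for i in src],
                "target": [self.labels[j] for j in dst],
            }
        )

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


@dataclass
class DyadMatrix:
    """Square real matrix over ordered node pairs; the diagonal is ignored."""

    labels: list[str]
    m: np.ndarray

    def __post_init__(self):
        self.labels = [str(x) for x in self.labels]
        self.m = _check_square(self.m, self.labels).astype(float)

    @property
    def n(self) -> int:
        return len(self.labels)

    def offdiag(self) -> np.ndarray:
        """Vectorize the n(n-1) off-diagonal entries in row-major order."""
        n = self.n
        return self.m[~np.eye(n, dtype=bool)]

    @classmethod
    def from_csv(cls, path, sep=None) -> "DyadMatrix":
        df = read_labeled_matrix(path, sep=sep)
        return cls(list(df.index), df.to_numpy(dtype=float))

    def to_csv(self, path, sep=",") -> None:
        write_labeled_matrix(self.m, self.labels, path, sep=sep)
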