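"""Angular ordering of correlation matrices and thresholded network export.

A reference-set correlation matrix often carries more than one principal
component of interest.  Ordering the genes by the angle of their loadings
on the first two principal components (an eigendecomposition of the
correlation matrix itself) lays co-expressed clusters out contiguously, the
way corrplot-style ordered heatmaps do.  Applying an ordering derived from
one dataset to another tests whether the cluster structure replicates.

Thresholded networks keep an edge between two genes when |r| strictly
exceeds the significance cut-off; the signed r is retained so positively
and negatively correlated edges stay distinguishable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .coexpression import CorrelationMatrix
from .io import GeneSet

__all__ = ["GeneOrdering", "EdgeList", "angular_order", "cross_order", "build_network"]

TWO_PI = 2.0 * math.pi


@dataclass
class GeneOrdering:
    """A permutation of a matrix's genes, sorted by PC1/PC2 loading angle."""

    genes: tuple[str, ...]
    angles: np.ndarray  # radians in [0, 2*pi), aligned with `genes`

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.shape != (len(self.genes),):
            raise ValueError("one angle per gene required")
        if ((self.angles < 0) | (self.angles >= TWO_PI)).any():
            raise ValueError("angles must lie in [0, 2*pi)")
        if np.any(np.diff(self.angles) < 0):
            raise ValueError("genes must be sorted by ascending angle")

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": list(self.genes), "angle": self.angles})


@dataclass
class EdgeList:
    """Significant co-expression edges plus node role annotations."""

    edges: list[tuple[str, str, float]]
    roles: dict[str, str]  # gene -> "reference" | "candidate"
    cutoff: float

    def __post_init__(self) -> None:
        seen: set[frozenset[str]] = set()
        for a, b, r in self.edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate edge {a!r}-{b!r}")
            seen.add(key)
            if abs(r) <= self.cutoff:
                raise ValueError(f"edge {a!r}-{b!r} with |r|={abs(r):.3g} not above cut-off")

    def __len__(self) -> int:
        return len(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["gene_a", "gene_b", "r"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_graph(self) -> nx.Graph:
        graph = nx.Graph()
        for gene, role in self.roles.items():
            graph.add_node(gene, role=role)
        for a, b, r in self.edges:
            graph.add_edge(a, b, r=float(r))
        return graph

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_graph(), str(path))


def _sign_fixed_top_components(m: CorrelationMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvectors of the two largest eigenvalues, sign-fixed.

    The sign of each eigenvector is ambiguous; it is fixed by forcing the
    loading with the largest magnitude (first occurrence on ties) to be
    positive, which makes the ordering deterministic and invariant to gene
    permutations.  numpy's symmetric eigendecomposition resolves degenerate
    eigenvalues deterministically given the input, so repeated runs agree
    bit-exactly.
    """
    eigvals, eigvecs = np.linalg.eigh(m.r)
    pcs = []
    for col in (eigvecs[:, -1], eigvecs[:, -2]):  # eigh sorts ascending
        pivot = int(np.argmax(np.abs(col)))
        pcs.append(-col if col[pivot] < 0 else col)
    return pcs[0], pcs[1]


def angular_order(m: CorrelationMatrix) -> GeneOrdering:
    """Order genes by the angle of their (PC1, PC2) loadings.

    The PCA is performed on the correlation matrix itself; each gene's
    loadings on the two leading eigenvectors give an angle
    atan2(PC2, PC1) mapped to [0, 2π), and genes are sorted by ascending
    angle (ties broken by gene symbol).  The gene with the smallest angle
    after sign-fixing comes first.
    """
    if m.n < 3:
        raise ValueError("angular ordering needs at least three genes")
    pc1, pc2 = _sign_fixed_top_components(m)
    angles = np.mod(np.arctan2(pc2, pc1), TWO_PI)
    order = sorted(range(m.n), key=lambda i: (angles[i], m.genes[i]))
    return GeneOrdering(
        genes=tuple(m.genes[i] for i in order),
        angles=angles[order],
    )


def cross_order(m: CorrelationMatrix, ordering: GeneOrdering) -> CorrelationMatrix:
    """Reorder a correlation matrix by an ordering from another dataset.

    Genes in the ordering must all be present in the matrix; genes of the
    matrix absent from the ordering are dropped (the ordering may be a
    subset).  Used to test whether cluster structure found in one resource
    replicates in another.
    """
    missing = [g for g in ordering.genes if g not in m.genes]
    if missing:
        raise ValueError(f"ordering references genes absent from the matrix: {missing}")
    return m.submatrix(list(ordering.genes))


def build_network(
    m: CorrelationMatrix,
    cutoff: float,
    reference: GeneSet,
    candidates: GeneSet | None = None,
) -> EdgeList:
    """Thresholded co-expression network over the matrix's genes.

    Retains every unordered gene pair with |r| strictly above the cut-off,
    keeping the signed correlation, and annotates each node as reference or
    candidate.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    ref = set(reference.symbols)
    cand = set(candidates.symbols) if candidates is not None else set()
    roles = {g: ("reference" if g in ref else "candidate") for g in m.genes if g in ref | cand}

    ia, ib = np.triu_indices(m.n, k=1)
    keep = np.abs(m.r[ia, ib]) > cutoff
    edges = [
        (m.genes[a], m.genes[b], float(m.r[a, b]))
        for a, b in zip(ia[keep], ib[keep])
    ]
    return EdgeList(edges=edges, roles=roles, cutoff=cutoff)
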