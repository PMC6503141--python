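"""Tetrahedral mesh container and geometry utilities.

The pipeline works on 4-node linear tetrahedra internally (SI units, metres).
Quadratic 10-node tetrahedra are accepted by the Abaqus-deck reader and
subdivided into 8 linear tetrahedra on import (see :mod:`bonedyn.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MeshQualityError(ValueError):
    """Raised when a mesh contains degenerate or inverted elements."""


@dataclass
class TetMesh:
    """Linear tetrahedral mesh.

    Parameters
    ----------
    nodes : (N, 3) float array
        Node coordinates in metres.
    elements : (E, 4) int array
        Connectivity; elements are canonically oriented (positive signed
        volume) by :meth:`orient`.
    node_sets, element_sets : dict of str -> int array
        Named index collections (couplings, clamps, recovery patches).
    landmarks : dict of str -> (3,) array
        Named reference points (joint centres, attachment sites).
    metadata : dict
        Free-form provenance (coordinate convention, generator parameters).
    """

    nodes: np.ndarray
    elements: np.ndarray
    node_sets: dict = field(default_factory=dict)
    element_sets: dict = field(default_factory=dict)
    landmarks: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.intp)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (N, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] != 4:
            raise ValueError("elements must be (E, 4) linear tetrahedra")
        if self.elements.size and self.elements.max() >= len(self.nodes):
            raise ValueError("connectivity index out of range")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def signed_volumes(self) -> np.ndarray:
        """Signed volume of every element (positive for canonical orientation)."""
        x = self.nodes[self.elements]
        d = x[:, 1:] - x[:, :1]
        return np.einsum("ei,ei->e", d[:, 0], np.cross(d[:, 1], d[:, 2])) / 6.0

    @property
    def volumes(self) -> np.ndarray:
        return np.abs(self.signed_volumes())

    def orient(self) -> "TetMesh":
        """Flip inverted elements in place so all signed volumes are positive."""
        v = self.signed_volumes()
        flip = v < 0
        if flip.any():
            self.elements[flip, 2], self.elements[flip, 3] = (
                self.elements[flip, 3].copy(),
                self.elements[flip, 2].copy(),
            )
        return self

    def validate(self, min_volume: float = 1e-16) -> "TetMesh":
        """Check element volumes and set indices; raise on defects."""
        v = self.signed_volumes()
        bad = np.where(v <= min_volume)[0]
        if bad.size:
            raise MeshQualityError(
                f"{bad.size} degenerate/inverted element(s) after orientation, "
                f"first: element {bad[0]} (signed volume {v[bad[0]]:.3e} m^3)"
            )
        for name, idx in self.node_sets.items():
            idx = np.asarray(idx)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_nodes):
                raise ValueError(f"node set {name!r} references invalid nodes")
        for name, idx in self.element_sets.items():
            idx = np.asarray(idx)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_elements):
                raise ValueError(f"element set {name!r} references invalid elements")
        return self

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def nodes_within(self, point, radius: float) -> np.ndarray:
        """Indices of all nodes with ``|x - point| <= radius``."""
        d = np.linalg.norm(self.nodes - np.asarray(point, dtype=float), axis=1)
        return np.where(d <= radius)[0]


def subdivide_quadratic_tets(nodes: np.ndarray, elements10: np.ndarray) -> np.ndarray:
    """Split 10-node tetrahedra into 8 conforming linear tetrahedra each.

    Node ordering follows the Abaqus C3D10 convention: corners 0-3, then
    mid-edge nodes 4=(01), 5=(12), 6=(02), 7=(03), 8=(13), 9=(23).
    The interior octahedron is cut along the (6, 8) diagonal, which is an
    interior edge, so adjacent elements stay conforming.
    """
    e = np.asarray(elements10, dtype=np.intp)
    if e.shape[1] != 10:
        raise ValueError("expected 10-node connectivity")
    corner = [
        (0, 4, 6, 7),
        (4, 1, 5, 8),
        (6, 5, 2, 9),
        (7, 8, 9, 3),
    ]
    octa = [
        (6, 8, 4, 5),
        (6, 8, 5, 9),
        (6, 8, 9, 7),
        (6, 8, 7, 4),
    ]
    out = np.concatenate([e[:, t] for t in corner + octa], axis=0)
    mesh = TetMesh(nodes, out)
    mesh.orient()
    return mesh.elements
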