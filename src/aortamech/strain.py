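"""Green-Lagrange strain of a deforming lumen surface.

Strain is evaluated per membrane triangle from the affine map between the
reference and deformed element, expressed in element-local orthonormal
tangent frames.  With a 0.01-mm membrane the through-thickness gradients
of an interpolated voxel displacement field are below imaging resolution,
so the transverse components e33, e13, e23 default to zero; an optional
incompressibility rule e33 = (J^-2 - 1)/2 (J the in-plane area ratio) is
provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .geometry import SurfaceMesh


@dataclass
class PhaseSequence:
    """Reference mesh plus per-phase nodal displacements and pressures.

    displacements : (P, N, 3) mm, phase 0 identically zero
    pressures_mpa : (P,) luminal pressure per phase, MPa
    """

    mesh: SurfaceMesh
    displacements: np.ndarray
    pressures_mpa: np.ndarray
    phase_indices: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        self.pressures_mpa = np.asarray(self.pressures_mpa, dtype=float)
        p, n, three = self.displacements.shape
        if three != 3 or n != self.mesh.n_nodes:
            raise ValueError("displacements must be (P, n_nodes, 3)")
        if self.pressures_mpa.shape != (p,):
            raise ValueError("pressures_mpa must have one entry per phase")
        if np.abs(self.displacements[0]).max() > 1e-12:
            raise ValueError("phase 0 is the reference: displacement must be 0")
        if self.phase_indices is None:
            self.phase_indices = np.arange(p)

    @property
    def n_phases(self) -> int:
        return self.displacements.shape[0]

    def deformed_nodes(self, phase: int) -> np.ndarray:
        return self.mesh.nodes + self.displacements[phase]


@dataclass
class ElementStrain:
    """Green-Lagrange components in the element-local tangent frame."""

    element_id: int
    e11: float
    e22: float
    e12: float
    e33: float = 0.0
    e13: float = 0.0
    e23: float = 0.0
    e_v: float = field(init=False)

    def __post_init__(self) -> None:
        self.e_v = float(equivalent_strain(
            np.array([self.e11, self.e22, self.e33,
                      self.e12, self.e13, self.e23])))


# ---------------------------------------------------------------------------
# element-level kinematics
# ---------------------------------------------------------------------------

def _local_frame(tri: np.ndarray) -> np.ndarray:
    """Orthonormal in-plane basis (2, 3): e1 along the first edge, e2 by
    Gram-Schmidt within the triangle plane.  Deterministic given the
    connectivity order."""
    d1 = tri[1] - tri[0]
    d2 = tri[2] - tri[0]
    e1 = d1 / np.linalg.norm(d1)
    d2p = d2 - (d2 @ e1) * e1
    n2 = np.linalg.norm(d2p)
    if n2 == 0.0:
        raise ValueError("degenerate triangle: collinear vertices")
    return np.stack([e1, d2p / n2])


def _edge_matrix_2d(tri: np.ndarray, frame: np.ndarray) -> np.ndarray:
    """2x2 matrix of the two edge vectors expressed in the local frame."""
    edges = np.stack([tri[1] - tri[0], tri[2] - tri[0]], axis=1)  # (3, 2)
    return frame @ edges


def element_deformation_gradient(ref_triangle: np.ndarray,
                                 def_triangle: np.ndarray) -> np.ndarray:
    """In-plane 2x2 deformation gradient of a membrane triangle.

    Maps reference edge vectors (in the reference local frame) to deformed
    edge vectors (in the deformed local frame); exact for any affine
    deformation of the triangle.
    """
    ref_triangle = np.asarray(ref_triangle, dtype=float)
    def_triangle = np.asarray(def_triangle, dtype=float)
    dr = _edge_matrix_2d(ref_triangle, _local_frame(ref_triangle))
    dd = _edge_matrix_2d(def_triangle, _local_frame(def_triangle))
    if abs(np.linalg.det(dr)) < 1e-14:
        raise ValueError("degenerate reference triangle")
    return dd @ np.linalg.inv(dr)


def green_lagrange(F: np.ndarray, transverse: str = "zero") -> np.ndarray:
    """Green-Lagrange components [e11, e22, e33, e12, e13, e23] from an
    in-plane 2x2 deformation gradient, E = (F^T F - I)/2.

    transverse : 'zero' (default) leaves e33 = 0; 'incompressible' sets
    e33 = (J^-2 - 1)/2 with J = det F the in-plane area ratio.
    """
    F = np.asarray(F, dtype=float)
    if F.shape == (3, 3):
        F = F[:2, :2]
    C = F.T @ F
    E = 0.5 * (C - np.eye(2))
    e33 = 0.0
    if transverse == "incompressible":
        J = np.linalg.det(F)
        e33 = 0.5 * (J ** -2 - 1.0)
    elif transverse != "zero":
        raise ValueError("transverse must be 'zero' or 'incompressible'")
    return np.array([E[0, 0], E[1, 1], e33, E[0, 1], 0.0, 0.0])


def equivalent_strain(components: np.ndarray) -> np.ndarray:
    """Equivalent (von-Mises-form) strain of [e11, e22, e33, e12, e13, e23].

    e_v = sqrt( ((e11-e22)^2 + (e33-e11)^2 + (e33-e22)^2
                 + 6 (e12^2 + e23^2 + e13^2)) / 2 )

    Zero in an equal-triaxial state; reduces to |e11| for uniaxial strain.
    Accepts a trailing components axis for batched input.
    """
    c = np.asarray(components, dtype=float)
    e11, e22, e33 = c[..., 0], c[..., 1], c[..., 2]
    e12, e13, e23 = c[..., 3], c[..., 4], c[..., 5]
    q = 0.5 * ((e11 - e22) ** 2 + (e33 - e11) ** 2 + (e33 - e22) ** 2
               + 6.0 * (e12 ** 2 + e23 ** 2 + e13 ** 2))
    return np.sqrt(np.maximum(q, 0.0))


# ---------------------------------------------------------------------------
# field-level evaluation
# ---------------------------------------------------------------------------

def _batched_local_frames(tri: np.ndarray) -> np.ndarray:
    d1 = tri[:, 1] - tri[:, 0]
    d2 = tri[:, 2] - tri[:, 0]
    e1 = d1 / np.linalg.norm(d1, axis=1, keepdims=True)
    d2p = d2 - np.einsum("ij,ij->i", d2, e1)[:, None] * e1
    e2 = d2p / np.linalg.norm(d2p, axis=1, keepdims=True)
    return np.stack([e1, e2], axis=1)  # (M, 2, 3)


def _batched_edge_2d(tri: np.ndarray, frames: np.ndarray) -> np.ndarray:
    edges = np.stack([tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]], axis=2)
    return frames @ edges  # (M, 2, 2)


def deformation_gradients(mesh: SurfaceMesh, deformed_nodes: np.ndarray
                          ) -> np.ndarray:
    """(M, 2, 2) in-plane deformation gradients for all elements at once."""
    ref_tri = mesh.triangles()
    def_tri = mesh.triangles(deformed_nodes)
    dr = _batched_edge_2d(ref_tri, _batched_local_frames(ref_tri))
    dd = _batched_edge_2d(def_tri, _batched_local_frames(def_tri))
    return dd @ np.linalg.inv(dr)


def strain_components(mesh: SurfaceMesh, deformed_nodes: np.ndarray,
                      transverse: str = "zero") -> np.ndarray:
    """(M, 6) Green-Lagrange components per element."""
    F = deformation_gradients(mesh, deformed_nodes)
    C = np.einsum("mji,mjk->mik", F, F)
    E = 0.5 * (C - np.eye(2))
    out = np.zeros((F.shape[0], 6))
    out[:, 0] = E[:, 0, 0]
    out[:, 1] = E[:, 1, 1]
    out[:, 3] = E[:, 0, 1]
    if transverse == "incompressible":
        J = np.linalg.det(F)
        out[:, 2] = 0.5 * (J ** -2 - 1.0)
    elif transverse != "zero":
        raise ValueError("transverse must be 'zero' or 'incompressible'")
    return out


@dataclass
class StrainField:
    """Per-element strain state of one phase."""

    phase: int
    components: np.ndarray  # (M, 6) [e11, e22, e33, e12, e13, e23]
    e_v: np.ndarray         # (M,)


def strain_field(seq: PhaseSequence, transverse: str = "zero"
                 ) -> List[StrainField]:
    """Per-phase element strain fields; phase 0 is identically zero."""
    fields: List[StrainField] = []
    for k in range(seq.n_phases):
        if not seq.displacements[k].any():
            # undeformed phase (the reference): identically zero field
            comp = np.zeros((seq.mesh.n_faces, 6))
            fields.append(StrainField(phase=k, components=comp,
                                      e_v=np.zeros(seq.mesh.n_faces)))
            continue
        try:
            comp = strain_components(seq.mesh, seq.deformed_nodes(k),
                                     transverse=transverse)
        except Exception as err:  # pragma: no cover - context decoration
            raise RuntimeError(f"strain evaluation failed at phase {k}: {err}")
        fields.append(StrainField(phase=k, components=comp,
                                  e_v=equivalent_strain(comp)))
    return fields
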