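"""Statically determinate membrane tension on the imaged lumen geometry.

The wall/thrombus compound is lumped into a thin elastic membrane on the
imaged (deformed) surface.  Because a pressurized thin membrane is
statically determinate, its tension field follows from equilibrium alone:
solving a forward finite-element problem with a very stiff material
(E = 2e5 MPa by default) on the imaged geometry leaves the geometry
essentially unchanged (displacements ~1e-6 of the radius) and recovers
the determinate tension without knowing the true tissue properties.

Elements are constant-strain membrane triangles; pressure is applied as a
dead load along outward element normals (one third of p*A to each
vertex).  Equivalent stress uses the same von-Mises functional as the
equivalent strain, with zero transverse stress (plane stress), and the
equivalent tension is tau_v = h * sigma_v.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.linalg import spsolve

from .geometry import MembraneModel, SurfaceMesh, boundary_loops
from .strain import PhaseSequence, equivalent_strain

#: diagonal regularization (relative to the mean stiffness diagonal) that
#: suppresses rigid-body and inextensional membrane mechanisms without
#: measurably perturbing the strain-producing response
REGULARIZATION = 1e-10


@dataclass
class MaterialSpec:
    """Stiff surrogate material for the inverse tension analysis.

    The defaults follow the static-determinacy argument: a very stiff
    material (2e5 MPa, nu = 0.45) whose only role is to keep the imaged
    geometry fixed while equilibrium distributes the pressure load.
    Density is carried for completeness; inertial terms are unused.
    """

    model: str = "linear_isotropic"     # 'linear_isotropic' | 'neo_hookean'
    youngs_modulus: float = 2.0e5       # MPa
    poisson_ratio: float = 0.45
    density: float = 1050.0             # kg m^-3

    def __post_init__(self) -> None:
        if self.model not in ("linear_isotropic", "neo_hookean"):
            raise ValueError("model must be linear_isotropic or neo_hookean")
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be > 0")
        if not (0.0 < self.poisson_ratio < 0.5):
            raise ValueError("Poisson ratio must lie in (0, 0.5)")

    @property
    def lame(self) -> Tuple[float, float]:
        e, nu = self.youngs_modulus, self.poisson_ratio
        lam = e * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
        mu = e / (2.0 * (1.0 + nu))
        return lam, mu


@dataclass
class TensionField:
    """Per-element membrane stress/tension state at one phase."""

    stress_local: np.ndarray      # (M, 3) [s11, s22, s12] in element frame, MPa
    sigma_v: np.ndarray           # (M,) equivalent stress, MPa
    tau_v: np.ndarray             # (M,) equivalent tension, N/mm
    pressure_mpa: float
    phase: int = 0
    h: float = 0.01
    displacement: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    reaction_sum: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    load_sum: np.ndarray = field(default=None, repr=False)      # type: ignore[assignment]
    residual_history: List[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# element precomputation
# ---------------------------------------------------------------------------

class _Elements:
    """Batched CST membrane element data on a fixed geometry."""

    def __init__(self, mesh: SurfaceMesh):
        tri = mesh.triangles()
        d1 = tri[:, 1] - tri[:, 0]
        d2 = tri[:, 2] - tri[:, 0]
        e1 = d1 / np.linalg.norm(d1, axis=1, keepdims=True)
        d2p = d2 - np.einsum("ij,ij->i", d2, e1)[:, None] * e1
        e2 = d2p / np.linalg.norm(d2p, axis=1, keepdims=True)
        self.frame = np.stack([e1, e2], axis=1)           # (M, 2, 3)
        # local 2D node coordinates: P1=(0,0), P2=(x2,0), P3=(x3,y3)
        x2 = np.einsum("ij,ij->i", d1, e1)
        x3 = np.einsum("ij,ij->i", d2, e1)
        y3 = np.einsum("ij,ij->i", d2, e2)
        self.area = 0.5 * x2 * y3
        if (self.area <= 0).any():
            raise ValueError("degenerate or inverted element encountered")
        m = tri.shape[0]
        # CST strain-displacement matrix B (M, 3, 6), local dofs
        # [u1 v1 u2 v2 u3 v3]
        b = np.zeros((m, 3, 6))
        y23, y31, y12 = -y3, y3, np.zeros(m)
        x32, x13, x21 = x3 - x2, -x3, x2
        inv2a = 1.0 / (2.0 * self.area)
        for i, (yy, xx) in enumerate(((y23, x32), (y31, x13), (y12, x21))):
            b[:, 0, 2 * i] = yy * inv2a
            b[:, 1, 2 * i + 1] = xx * inv2a
            b[:, 2, 2 * i] = xx * inv2a
            b[:, 2, 2 * i + 1] = yy * inv2a
        self.B = b
        # reference in-plane edge matrix and its inverse (for TL kinematics)
        self.Gref = np.zeros((m, 2, 2))
        self.Gref[:, 0, 0] = x2
        self.Gref[:, 0, 1] = x3
        self.Gref[:, 1, 1] = y3
        self.Ginv = np.linalg.inv(self.Gref)
        self.faces = mesh.faces
        self.n_nodes = mesh.n_nodes
        # outward normals and per-element vertex load directions
        n = np.cross(d1, d2)
        self.normal = n / np.linalg.norm(n, axis=1, keepdims=True)

    def local_transform(self) -> np.ndarray:
        """(M, 6, 9) mapping global nodal dofs to local in-plane dofs."""
        m = self.frame.shape[0]
        t = np.zeros((m, 6, 9))
        for i in range(3):
            t[:, 2 * i, 3 * i:3 * i + 3] = self.frame[:, 0]
            t[:, 2 * i + 1, 3 * i:3 * i + 3] = self.frame[:, 1]
        return t


def _plane_stress_D(material: MaterialSpec) -> np.ndarray:
    e, nu = material.youngs_modulus, material.poisson_ratio
    f = e / (1.0 - nu * nu)
    return f * np.array([[1.0, nu, 0.0],
                         [nu, 1.0, 0.0],
                         [0.0, 0.0, 0.5 * (1.0 - nu)]])


def _assemble_stiffness(el: _Elements, D: np.ndarray, h: float) -> csc_matrix:
    t = el.local_transform()                              # (M, 6, 9)
    bd = np.einsum("ij,mjk->mik", D, el.B)                # (M, 3, 6)
    k6 = np.einsum("mji,mjk->mik", el.B, bd)              # (M, 6, 6)
    k6 *= (el.area * h)[:, None, None]
    k9 = np.einsum("mji,mjk,mkl->mil", t, k6, t)          # (M, 9, 9)
    dof = (3 * el.faces[:, :, None] + np.arange(3)).reshape(-1, 9)
    rows = np.repeat(dof, 9, axis=1).ravel()
    cols = np.tile(dof, (1, 9)).ravel()
    k = coo_matrix((k9.ravel(), (rows, cols)),
                   shape=(3 * el.n_nodes, 3 * el.n_nodes))
    return k.tocsc()


def _pressure_load(el: _Elements, pressure: float) -> np.ndarray:
    """Dead pressure load along outward normals, p*A/3 per vertex."""
    f = np.zeros((el.n_nodes, 3))
    contrib = (pressure * el.area / 3.0)[:, None] * el.normal
    for k in range(3):
        np.add.at(f, el.faces[:, k], contrib)
    return f.ravel()


def _fixed_dofs(mesh: SurfaceMesh, bc: Union[str, Sequence[int]]) -> np.ndarray:
    """Dirichlet dof indices for the requested boundary-condition scheme.

    'clamp_rings' clamps all translations on every boundary ring (the cut
    ends of an open tube); 'none' relies on the diagonal regularization to
    fix rigid modes of a closed surface under self-equilibrated pressure;
    an explicit dof index list is passed through.
    """
    if isinstance(bc, str):
        if bc == "none":
            return np.empty(0, dtype=int)
        if bc == "clamp_rings":
            loops = boundary_loops(mesh)
            if not loops:
                raise ValueError(
                    "clamp_rings requested but the mesh is closed; use "
                    "bc='none' or an explicit dof list")
            nodes = np.concatenate(loops)
            return (3 * nodes[:, None] + np.arange(3)).ravel()
        raise ValueError(f"unknown boundary condition scheme '{bc}'")
    return np.asarray(bc, dtype=int)


def _apply_bc(k: csc_matrix, f: np.ndarray, fixed: np.ndarray
              ) -> Tuple[csc_matrix, np.ndarray]:
    if fixed.size == 0:
        return k, f
    k = k.tolil()
    k[fixed, :] = 0.0
    k[:, fixed] = 0.0
    for d in fixed:
        k[d, d] = 1.0
    f = f.copy()
    f[fixed] = 0.0
    return k.tocsc(), f


# ---------------------------------------------------------------------------
# stress evaluation
# ---------------------------------------------------------------------------

def _small_strain_stress(el: _Elements, D: np.ndarray, u: np.ndarray
                         ) -> np.ndarray:
    t = el.local_transform()
    u9 = u.reshape(-1, 3)[el.faces].reshape(-1, 9)
    u_loc = np.einsum("mij,mj->mi", t, u9)
    eps = np.einsum("mij,mj->mi", el.B, u_loc)
    return np.einsum("ij,mj->mi", D, eps)


def _neo_hookean_stress(el: _Elements, material: MaterialSpec,
                        u: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Plane-stress compressible neo-Hookean 2nd Piola-Kirchhoff stress.

    Returns (S (M,2,2), Ftilde (M,3,2)).  The thickness stretch solves the
    zero-transverse-stress condition S33 = 0 by a few Newton steps.
    """
    lam, mu = material.lame
    x = u.reshape(-1, 3)
    tri0 = el.faces
    # deformed edge matrix in global coordinates
    nodes = x[tri0]                                       # (M, 3, 3) disp
    # caller passes displacements; deformed edges = ref edges + disp edges
    dref = np.einsum("mij,mjk->mik", el.frame.transpose(0, 2, 1), el.Gref)
    ddef = dref + np.stack([nodes[:, 1] - nodes[:, 0],
                            nodes[:, 2] - nodes[:, 0]], axis=2)
    Ft = ddef @ el.Ginv                                   # (M, 3, 2)
    C = np.einsum("mji,mjk->mik", Ft, Ft)                 # (M, 2, 2)
    detC = C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] * C[:, 1, 0]
    a = np.sqrt(np.maximum(detC, 1e-30))                  # in-plane area ratio
    # thickness stretch t from S33 = mu (1 - t^-2) + lam ln(a t) t^-2 = 0
    t = np.ones_like(a)
    for _ in range(30):
        t2 = t * t
        g = mu * (1.0 - 1.0 / t2) + lam * np.log(a * t) / t2
        dg = 2.0 * mu / (t * t2) + lam / (t * t2) \
            - 2.0 * lam * np.log(a * t) / (t * t2)
        step = g / dg
        t = np.clip(t - step, 0.2, 5.0)
        if np.abs(step).max() < 1e-14:
            break
    lnJ = np.log(a * t)
    Cinv = np.linalg.inv(C)
    eye = np.eye(2)
    S = mu * (eye - Cinv) + (lam * lnJ)[:, None, None] * Cinv
    return S, Ft


def _internal_force_tl(el: _Elements, S: np.ndarray, Ft: np.ndarray,
                       h: float) -> np.ndarray:
    """Total-Lagrangian internal nodal forces of the membrane elements."""
    fD = np.einsum("m,mij,mjk,mlk->mil", el.area * h, Ft, S, el.Ginv)
    f = np.zeros((el.n_nodes, 3))
    np.add.at(f, el.faces[:, 1], fD[:, :, 0])
    np.add.at(f, el.faces[:, 2], fD[:, :, 1])
    np.add.at(f, el.faces[:, 0], -(fD[:, :, 0] + fD[:, :, 1]))
    return f.ravel()


def _geometric_stiffness(el: _Elements, S: np.ndarray, h: float
                         ) -> csc_matrix:
    """Stress (geometric) stiffness of the TL membrane elements.

    With the 2nd Piola-Kirchhoff stress held fixed, the second variation
    of the strain energy on the edge vectors d1, d2 is A h (G^-1 S G^-T)
    Kronecker I3; it stabilizes the inextensional mechanisms that the
    material stiffness alone leaves soft.
    """
    H = np.einsum("m,mij,mjk,mlk->mil", el.area * h, el.Ginv, S, el.Ginv)
    m = el.faces.shape[0]
    k9 = np.zeros((m, 9, 9))
    eye3 = np.eye(3)
    # node pair coefficients from L^T H L with L rows (-1, 1, 0), (-1, 0, 1)
    lmat = np.array([[-1.0, 1.0, 0.0], [-1.0, 0.0, 1.0]])
    coeff = np.einsum("ai,mab,bj->mij", lmat, H, lmat)   # (m, 3, 3) nodes
    for a in range(3):
        for b in range(3):
            k9[:, 3 * a:3 * a + 3, 3 * b:3 * b + 3] = \
                coeff[:, a, b, None, None] * eye3
    dof = (3 * el.faces[:, :, None] + np.arange(3)).reshape(-1, 9)
    rows = np.repeat(dof, 9, axis=1).ravel()
    cols = np.tile(dof, (1, 9)).ravel()
    kg = coo_matrix((k9.ravel(), (rows, cols)),
                    shape=(3 * el.n_nodes, 3 * el.n_nodes))
    return kg.tocsc()


def _sigma_v_plane_stress(stress: np.ndarray) -> np.ndarray:
    """Von-Mises functional with zero transverse stress."""
    comps = np.zeros((stress.shape[0], 6))
    comps[:, 0] = stress[:, 0]
    comps[:, 1] = stress[:, 1]
    comps[:, 3] = stress[:, 2]
    return equivalent_strain(comps)


# ---------------------------------------------------------------------------
# solves
# ---------------------------------------------------------------------------

def solve_membrane_tension(
        model: MembraneModel,
        pressure_mpa: float,
        material: Optional[MaterialSpec] = None,
        bc: Union[str, Sequence[int]] = "auto",
        newton_tol: float = 1e-9,
        max_newton: int = 30,
        phase: int = 0,
) -> TensionField:
    """Equivalent membrane tension under uniform luminal pressure.

    A single sparse SPD solve for the linear isotropic material; modified
    Newton iterations (linear stiffness as tangent) for the neo-Hookean
    law.  ``bc='auto'`` clamps boundary rings on open tubes and relies on
    regularization for closed surfaces.
    """
    material = material or MaterialSpec()
    mesh = model.mesh
    if bc == "auto":
        bc = "clamp_rings" if boundary_loops(mesh) else "none"
    el = _Elements(mesh)
    D = _plane_stress_D(material)
    k = _assemble_stiffness(el, D, model.h)
    diag_scale = float(np.abs(k.diagonal()).mean())
    f = _pressure_load(el, pressure_mpa)
    fixed = _fixed_dofs(mesh, bc)
    kb, fb = _apply_bc(k, f, fixed)
    kb = kb + REGULARIZATION * diag_scale * _identity(kb.shape[0])
    history: List[float] = []

    if material.model == "linear_isotropic" or pressure_mpa == 0.0:
        u = spsolve(kb, fb)
        stress = _small_strain_stress(el, D, u)
    else:
        u = np.zeros(3 * mesh.n_nodes)
        fnorm = max(np.linalg.norm(fb), 1e-30)
        from scipy.sparse.linalg import splu
        free_mask = np.ones(3 * mesh.n_nodes, dtype=bool)
        free_mask[fixed] = False
        for _ in range(max_newton):
            S, Ft = _neo_hookean_stress(el, material, u)
            r = _internal_force_tl(el, S, Ft, model.h) - f
            r[fixed] = 0.0
            rel = np.linalg.norm(r) / fnorm
            history.append(rel)
            if rel < newton_tol:
                break
            # material + geometric tangent (stress stiffness stabilizes
            # the inextensional membrane mechanisms)
            from scipy.sparse import diags
            dmask = diags(free_mask.astype(float), format="csc")
            kg = dmask @ _geometric_stiffness(el, S, model.h) @ dmask
            lu = splu((kb + kg).tocsc())
            u = u - lu.solve(r)
        else:
            raise RuntimeError(
                "neo-Hookean Newton did not converge; residual history: "
                + ", ".join(f"{x:.3e}" for x in history))
        S, Ft = _neo_hookean_stress(el, material, u)
        # 2nd PK ~ Cauchy at the tiny strains of the stiff solve
        stress = np.stack([S[:, 0, 0], S[:, 1, 1], S[:, 0, 1]], axis=1)

    sigma_v = _sigma_v_plane_stress(stress)
    tau_v = model.h * sigma_v
    # global equilibrium audit: reactions at constrained dofs vs total load
    reaction = (k @ u - f)
    if fixed.size:
        mask = np.zeros(reaction.size, dtype=bool)
        mask[fixed] = True
        r_sum = np.where(mask, reaction, 0.0).reshape(-1, 3).sum(axis=0)
    else:
        r_sum = np.zeros(3)
    load_sum = f.reshape(-1, 3).sum(axis=0)
    return TensionField(stress_local=stress, sigma_v=sigma_v, tau_v=tau_v,
                        pressure_mpa=float(pressure_mpa), phase=phase,
                        h=model.h, displacement=u.reshape(-1, 3),
                        reaction_sum=r_sum, load_sum=load_sum,
                        residual_history=history)


def _identity(n: int) -> csc_matrix:
    from scipy.sparse import identity
    return identity(n, format="csc")


# ---------------------------------------------------------------------------
# sensitivity studies
# ---------------------------------------------------------------------------

def thickness_sensitivity(
        model: MembraneModel, pressure_mpa: float,
        h1: float = 0.1, h2: float = 0.01,
        material: Optional[MaterialSpec] = None,
        bc: Union[str, Sequence[int]] = "auto",
        exclude: Optional[np.ndarray] = None,
) -> Dict[str, Union[float, np.ndarray]]:
    """Relative tau_v difference between two membrane thicknesses.

    Analytically the Laplace tension is thickness-free (tau = h*sigma with
    sigma ~ 1/h); the observed difference measures the numerical
    sensitivity of the discrete solve.  Returns per-element relative
    differences and the model average (fractions, not %).
    """
    if h1 <= 0 or h2 <= 0:
        raise ValueError("thicknesses must be > 0")
    from .geometry import MembraneModel as MM
    t1 = solve_membrane_tension(MM(model.mesh, h1), pressure_mpa, material, bc)
    t2 = solve_membrane_tension(MM(model.mesh, h2), pressure_mpa, material, bc)
    keep = np.ones(t1.tau_v.size, dtype=bool)
    if exclude is not None:
        keep[np.asarray(exclude)] = False
    ref = np.maximum(np.abs(t1.tau_v[keep]), 1e-30)
    rel = np.abs(t1.tau_v[keep] - t2.tau_v[keep]) / ref
    return {"per_element": rel, "average": float(rel.mean()),
            "max": float(rel.max())}


def material_sensitivity(
        model: MembraneModel, pressure_mpa: float,
        materials: Sequence[MaterialSpec],
        bc: Union[str, Sequence[int]] = "auto",
        exclude: Optional[np.ndarray] = None,
) -> Dict[str, Union[float, List[float]]]:
    """Max relative tau_v difference of each material vs linear isotropic."""
    if len(materials) < 2:
        raise ValueError("need at least 2 materials")
    base_mat = MaterialSpec(model="linear_isotropic",
                            youngs_modulus=materials[0].youngs_modulus,
                            poisson_ratio=materials[0].poisson_ratio)
    base = solve_membrane_tension(model, pressure_mpa, base_mat, bc)
    keep = np.ones(base.tau_v.size, dtype=bool)
    if exclude is not None:
        keep[np.asarray(exclude)] = False
    ref = np.maximum(np.abs(base.tau_v[keep]), 1e-30)
    diffs: List[float] = []
    for mat in materials:
        t = solve_membrane_tension(model, pressure_mpa, mat, bc)
        diffs.append(float(np.max(np.abs(t.tau_v[keep] - base.tau_v[keep])
                                  / ref)))
    return {"max_rel_diff": max(diffs), "per_material": diffs}


def tension_over_phases(
        seq: PhaseSequence, h: float = 0.01,
        material: Optional[MaterialSpec] = None,
        bc: Union[str, Sequence[int]] = "auto",
) -> List[TensionField]:
    """Solve the membrane tension on each phase's deformed geometry with
    that phase's pressure (DBP at the beginning phase, SBP at the peak)."""
    fields: List[TensionField] = []
    for k in range(seq.n_phases):
        mesh_k = SurfaceMesh(seq.deformed_nodes(k), seq.mesh.faces.copy())
        try:
            t = solve_membrane_tension(MembraneModel(mesh_k, h),
                                       float(seq.pressures_mpa[k]),
                                       material, bc, phase=k)
        except Exception as err:
            raise RuntimeError(f"tension solve failed at phase {k}: {err}")
        fields.append(t)
    return fields
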