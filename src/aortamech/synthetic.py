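"""Synthetic deforming vessels, voxel displacement fields and cohorts.

Every downstream stage of the pipeline is testable against this module's
analytic ground truth without any imaging data:

* pulsating straight cylinders, whose hoop Green strain and Laplace-law
  membrane tension are exact closed forms;
* fusiform aneurysms (Gaussian radius bump) with approximate local-radius
  ground truth;
* voxelized displacement fields of the analytic phase motion;
* cohorts of per-quadrant stiffness/hardening indices with a configurable
  order-of-magnitude gap between healthy and aneurysmal groups.

Units: mm, N, MPa internally; blood pressures are accepted in mmHg at the
boundary (1 mmHg = 1.33322e-4 MPa).  Geometry generation is fully
deterministic; randomness is isolated to the cohort generator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .geometry import SurfaceMesh
from .image_ops import VoxelDisplacementField
from .strain import PhaseSequence

MMHG_TO_MPA = 1.33322e-4
SQRT3_2 = np.sqrt(3.0) / 2.0

#: allowed range for the number of dilation phases (the imaging protocol
#: captures 34 phases per cardiac cycle; dilation runs span 6-9 of them,
#: but any plausible sub-run is accepted)
PHASE_BOUNDS = (2, 34)


@dataclass
class SyntheticCaseSpec:
    """Parameters of one synthetic deforming vessel."""

    shape: str = "cylinder"            # 'cylinder' | 'fusiform'
    R0: float = 10.0                   # base radius, mm
    bump_amplitude: float = 10.0       # fusiform bump height, mm
    bump_center_z: float = 60.0        # mm
    bump_width: float = 15.0           # Gaussian width, mm
    length: float = 120.0              # mm
    n_circ: int = 64
    n_axial: int = 48                  # axial element rows
    n_phases: int = 7
    peak_hoop_stretch: float = 1.05    # lambda_theta at peak systole
    pressures: Tuple[float, float] = (80.0, 120.0)  # (DBP, SBP), mmHg
    seed: int = 0
    curve_law: Optional[Tuple[float, float]] = None  # (lambda1, lambda2)

    def __post_init__(self) -> None:
        if self.shape not in ("cylinder", "fusiform"):
            raise ValueError("shape must be 'cylinder' or 'fusiform'")
        if self.R0 <= 0 or self.length <= 0:
            raise ValueError("R0 and length must be > 0")
        if self.n_circ < 8 or self.n_axial < 4:
            raise ValueError("degenerate mesh resolution: "
                             "need n_circ >= 8 and n_axial >= 4")
        if not (PHASE_BOUNDS[0] <= self.n_phases <= PHASE_BOUNDS[1]):
            raise ValueError(f"n_phases must lie in {PHASE_BOUNDS}")
        if self.peak_hoop_stretch < 1.0:
            raise ValueError("peak hoop stretch must be >= 1")
        dbp, sbp = self.pressures
        if not (sbp > dbp > 0):
            raise ValueError("need SBP > DBP > 0")


@dataclass
class GroundTruth:
    """Analytic per-phase truth of a generated case.

    hoop_strain : (P, S) hoop Green strain at the S axial stations
    tension     : (P, S) equivalent membrane tension, N/mm (Laplace law)
    exact       : False when the tension is a local-radius approximation
                  (fusiform geometry)
    curve_params: (lambda1, lambda2, lambda3) when the phase schedule was
                  constructed from a prescribed tension-strain power law
    """

    stations_z: np.ndarray
    hoop_strain: np.ndarray
    tension: np.ndarray
    radial_scale: np.ndarray            # (P,) scale factor c_k
    exact: bool = True
    curve_params: Optional[Tuple[float, float, float]] = None


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def raised_cosine_schedule(n_phases: int) -> np.ndarray:
    """Smooth monotone 0 -> 1 schedule over the dilation phases."""
    k = np.arange(n_phases)
    return 0.5 * (1.0 - np.cos(np.pi * k / (n_phases - 1)))


def pressure_schedule_mpa(spec: SyntheticCaseSpec) -> np.ndarray:
    """Linear DBP -> SBP ramp over the phase index, in MPa."""
    dbp, sbp = spec.pressures
    k = np.arange(spec.n_phases)
    mmhg = dbp + (sbp - dbp) * k / (spec.n_phases - 1)
    return mmhg * MMHG_TO_MPA


def _radial_scales(spec: SyntheticCaseSpec,
                   pressures_mpa: np.ndarray) -> Tuple[np.ndarray, Optional[Tuple[float, float, float]]]:
    """Per-phase radial scale factors c_k.

    Default: c_k = 1 + (lambda_theta - 1) * s_k with a raised-cosine s_k.
    With ``curve_law=(l1, l2)`` the scales are instead chosen so the
    cylinder's analytic (e_v, tau_v) pairs lie exactly on the power law
    tau = l1 * e^l2 + l3, with l3 pinned by the zero-strain phase:
    l3 = (sqrt(3)/2) * p_0 * R0.
    """
    if spec.curve_law is None:
        s = raised_cosine_schedule(spec.n_phases)
        return 1.0 + (spec.peak_hoop_stretch - 1.0) * s, None
    l1, l2 = spec.curve_law
    if l1 <= 0 or l2 <= 1:
        raise ValueError("curve_law requires lambda1 > 0 and lambda2 > 1")
    l3 = SQRT3_2 * pressures_mpa[0] * spec.R0
    scales = [1.0]
    for p in pressures_mpa[1:]:
        def f(c: float) -> float:
            e = 0.5 * (c * c - 1.0)
            return SQRT3_2 * p * c * spec.R0 - l1 * e ** l2 - l3
        scales.append(brentq(f, 1.0, 4.0, xtol=1e-14))
    return np.asarray(scales), (l1, l2, l3)


# ---------------------------------------------------------------------------
# geometry generators
# ---------------------------------------------------------------------------

def _radius_profile(spec: SyntheticCaseSpec, z: np.ndarray) -> np.ndarray:
    r = np.full_like(z, spec.R0, dtype=float)
    if spec.shape == "fusiform" and spec.bump_amplitude != 0.0:
        r = r + spec.bump_amplitude * np.exp(
            -((z - spec.bump_center_z) / spec.bump_width) ** 2)
    return r


def _tube_mesh(spec: SyntheticCaseSpec) -> Tuple[SurfaceMesh, np.ndarray]:
    """Quad-split triangulated tube; returns (mesh, station z levels)."""
    nz = spec.n_axial + 1
    z = np.linspace(0.0, spec.length, nz)
    theta = 2.0 * np.pi * np.arange(spec.n_circ) / spec.n_circ
    r = _radius_profile(spec, z)
    nodes = np.empty((nz * spec.n_circ, 3))
    for i in range(nz):
        base = i * spec.n_circ
        nodes[base:base + spec.n_circ, 0] = r[i] * np.cos(theta)
        nodes[base:base + spec.n_circ, 1] = r[i] * np.sin(theta)
        nodes[base:base + spec.n_circ, 2] = z[i]
    faces = []
    for i in range(spec.n_axial):
        for j in range(spec.n_circ):
            jn = (j + 1) % spec.n_circ
            a = i * spec.n_circ + j
            b = i * spec.n_circ + jn
            c = (i + 1) * spec.n_circ + j
            d = (i + 1) * spec.n_circ + jn
            # outward orientation for CCW theta and +z axial order
            faces.append((a, b, d))
            faces.append((a, d, c))
    return SurfaceMesh(nodes, np.asarray(faces, dtype=np.int64)), z


def _build_sequence(spec: SyntheticCaseSpec
                    ) -> Tuple[PhaseSequence, GroundTruth]:
    pressures = pressure_schedule_mpa(spec)
    scales, curve_params = _radial_scales(spec, pressures)
    mesh, z = _tube_mesh(spec)
    disp = np.zeros((spec.n_phases, mesh.n_nodes, 3))
    for k, c in enumerate(scales):
        disp[k, :, 0] = (c - 1.0) * mesh.nodes[:, 0]
        disp[k, :, 1] = (c - 1.0) * mesh.nodes[:, 1]
    seq = PhaseSequence(mesh=mesh, displacements=disp,
                        pressures_mpa=pressures)
    r_ref = _radius_profile(spec, z)
    hoop = 0.5 * (scales[:, None] ** 2 - 1.0) * np.ones_like(r_ref)
    tension = SQRT3_2 * pressures[:, None] * scales[:, None] * r_ref[None, :]
    gt = GroundTruth(stations_z=z, hoop_strain=hoop, tension=tension,
                     radial_scale=scales,
                     exact=(spec.shape == "cylinder"
                            or spec.bump_amplitude == 0.0),
                     curve_params=curve_params)
    return seq, gt


def gen_pulsating_cylinder(spec: SyntheticCaseSpec
                           ) -> Tuple[PhaseSequence, GroundTruth]:
    """Straight cylinder dilating radially over the cardiac phases.

    Ground truth: hoop Green strain e = ((r_k/R0)^2 - 1)/2 and closed-
    cylinder equivalent tension tau_v = (sqrt(3)/2) p_k r_k (Laplace hoop
    tension p r combined with the axial p r / 2 through the von-Mises
    functional).
    """
    if spec.shape != "cylinder":
        spec = replace(spec, shape="cylinder")
    return _build_sequence(spec)


def gen_fusiform_aneurysm(spec: SyntheticCaseSpec
                          ) -> Tuple[PhaseSequence, GroundTruth]:
    """Fusiform aneurysm: radius R0 + A exp(-((z-z0)/w)^2), dilating
    radially.  The maximum-diameter plane sits at z0 by construction; the
    local-radius Laplace tension is approximate (GroundTruth.exact=False)
    except in the degenerate A=0 case, which reduces to the cylinder.
    """
    if spec.shape != "fusiform":
        spec = replace(spec, shape="fusiform")
    if spec.bump_amplitude < 0:
        raise ValueError("bump_amplitude must be >= 0")
    if spec.bump_amplitude > 0:
        z0, w, L = spec.bump_center_z, spec.bump_width, spec.length
        if not (0.0 <= z0 - 2.0 * w and z0 + 2.0 * w <= L):
            raise ValueError("bump (z0 +/- 2w) exceeds the vessel length")
    return _build_sequence(spec)


def generate_case(spec: SyntheticCaseSpec
                  ) -> Tuple[PhaseSequence, GroundTruth]:
    if spec.shape == "cylinder":
        return gen_pulsating_cylinder(spec)
    return gen_fusiform_aneurysm(spec)


# ---------------------------------------------------------------------------
# voxel displacement fields
# ---------------------------------------------------------------------------

def gen_voxel_displacement_field(
        seq: PhaseSequence,
        spacing: Sequence[float] = (0.4, 0.4, 0.3),
        margin: float = 4.0,
) -> List[VoxelDisplacementField]:
    """Voxelize the analytic phase motion on a grid enclosing the mesh.

    The generated motion is a radial scaling about the z axis, so the
    displacement continues smoothly off the surface as
    u(x, y, z) = (c_k - 1) (x, y, 0); it is sampled at voxel centers.
    Default spacing 0.4 x 0.4 x 0.3 mm matches the imaging protocol.
    """
    spacing = tuple(float(s) for s in spacing)
    if min(spacing) <= 0:
        raise ValueError("spacing must be > 0 in each axis")
    # enclose reference and all deformed configurations
    lo = seq.mesh.nodes.min(axis=0)
    hi = seq.mesh.nodes.max(axis=0)
    for k in range(seq.n_phases):
        d = seq.deformed_nodes(k)
        lo = np.minimum(lo, d.min(axis=0))
        hi = np.maximum(hi, d.max(axis=0))
    lo -= margin
    hi += margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    origin = tuple(lo)
    xs = lo[0] + spacing[0] * np.arange(shape[0])
    ys = lo[1] + spacing[1] * np.arange(shape[1])
    fields: List[VoxelDisplacementField] = []
    # recover c_k from any off-axis node (generators keep node 0 off-axis)
    ref_xy = seq.mesh.nodes[0, :2]
    for k in range(seq.n_phases):
        c = 1.0 + seq.displacements[k, 0, 0] / ref_xy[0] \
            if abs(ref_xy[0]) > 1e-9 else \
            1.0 + seq.displacements[k, 0, 1] / ref_xy[1]
        data = np.zeros((*shape, 3))
        data[..., 0] = (c - 1.0) * xs[:, None, None]
        data[..., 1] = (c - 1.0) * ys[None, :, None]
        fields.append(VoxelDisplacementField(data=data, spacing=spacing,
                                             origin=origin))
    return fields


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: healthy-group median indices used as cohort anchors (per-quadrant scale
#: of a normal abdominal aorta in this package's unit convention)
HEALTHY_MEDIAN_SSI = 3.4
HEALTHY_MEDIAN_DSSI = 38.0

#: log10 standard deviations of the case-level factor and the quadrant
#: jitter.  The total spread (~0.22 decades, IQR about a factor 2) mimics
#: the within-group variability seen in quadrant box-whisker summaries
#: while keeping the configured group gap dominant.
SIGMA_CASE = 0.18
SIGMA_QUADRANT = 0.12

QUADRANTS = ("A", "L", "P", "R")


def gen_cohort(n_healthy: int, n_aaa: int, gap: float = 10.0,
               seed: int = 0) -> pd.DataFrame:
    """Synthetic per-quadrant index table for two groups.

    SSI and dSSI are drawn from log-normal distributions whose group
    medians differ by the factor ``gap`` (default 10, an order of
    magnitude); the two indices share a case-level factor so they are
    positively correlated, and the diameter is positively coupled to the
    case's SSI level.  Reproducible under a fixed seed.

    The log-normal distributional model is this package's own choice of a
    realistic multiplicative-spread emulation; it is not derived from any
    measured cohort.
    """
    if n_healthy < 2 or n_aaa < 2:
        raise ValueError("need at least 2 cases per group")
    if gap < 1.0:
        raise ValueError("gap must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    case_id = 0
    for group, n_cases in (("healthy", n_healthy), ("aneurysm", n_aaa)):
        lg = np.log10(gap) if group == "aneurysm" else 0.0
        for _ in range(n_cases):
            z1, z2 = rng.standard_normal(2)
            mu_ssi = np.log10(HEALTHY_MEDIAN_SSI) + lg + SIGMA_CASE * z1
            mu_dssi = np.log10(HEALTHY_MEDIAN_DSSI) + lg \
                + SIGMA_CASE * (0.8 * z1 + 0.6 * z2)
            diameter = 18.0 + 22.0 * (mu_ssi - np.log10(HEALTHY_MEDIAN_SSI)) \
                + rng.normal(0.0, 2.0)
            diameter = max(diameter, 8.0)
            for quadrant in QUADRANTS:
                rows.append({
                    "case_id": f"case{case_id:03d}",
                    "group": group,
                    "diameter_mm": round(diameter, 3),
                    "quadrant": quadrant,
                    "SSI": 10.0 ** (mu_ssi
                                    + SIGMA_QUADRANT * rng.standard_normal()),
                    "dSSI": 10.0 ** (mu_dssi
                                     + SIGMA_QUADRANT * rng.standard_normal()),
                })
            case_id += 1
    return pd.DataFrame(rows)
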