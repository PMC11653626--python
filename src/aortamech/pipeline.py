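"""End-to-end case and cohort orchestration.

A case run executes the full chain
phase selection -> (optional) voxel-field node interpolation ->
smoothing QC -> strain -> tension -> regional tension-strain curves ->
SSI/dSSI per quadrant, and writes CSV/JSON/VTK artifacts.  Runs are
deterministic given config + seed; a completed output directory with a
matching config hash is reused instead of recomputed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_stats
from . import curves as curve_ops
from . import geometry, io, synthetic, tension
from .image_ops import (VolumeCurve, interpolate_node_displacement,
                        load_displacement_nifti, select_dilation_phases)
from .strain import PhaseSequence, strain_field

log = logging.getLogger("aortamech")

QUADRANTS = geometry.QUADRANTS


@dataclass
class RunConfig:
    """Configuration of one case run (synthetic or file-based inputs)."""

    case_id: str = "case"
    group: str = "healthy"
    # exactly one input route
    synthetic: Optional[Dict] = None          # SyntheticCaseSpec kwargs
    mesh_path: Optional[str] = None
    displacement_paths: Optional[List[str]] = None
    pressures: Tuple[float, float] = (80.0, 120.0)   # (DBP, SBP), mmHg
    # processing settings
    use_voxel_fields: bool = False            # voxelize + re-interpolate
    voxel_spacing: Tuple[float, float, float] = (0.4, 0.4, 0.3)
    smoothing_iterations: int = 0
    smoothing_step: float = 0.5
    h: float = 0.01                           # membrane thickness, mm
    material_model: str = "linear_isotropic"
    bc: str = "auto"
    segment_length: float = 20.0
    anterior: Tuple[float, float, float] = (0.0, 1.0, 0.0)
    N: int = 16
    out_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        has_synth = self.synthetic is not None
        has_real = self.mesh_path is not None \
            or self.displacement_paths is not None
        if has_synth == has_real:
            raise ValueError(
                "config must specify exactly one of synthetic spec or "
                "real input paths")
        if has_real:
            if not (self.mesh_path and self.displacement_paths):
                raise ValueError("real inputs need mesh_path and "
                                 "displacement_paths")
            for p in [self.mesh_path, *self.displacement_paths]:
                if not Path(p).exists():
                    raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "pressures" in data:
            data["pressures"] = tuple(data["pressures"])
        if "anterior" in data:
            data["anterior"] = tuple(data["anterior"])
        if "voxel_spacing" in data:
            data["voxel_spacing"] = tuple(data["voxel_spacing"])
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CaseResult:
    """Per-case outputs feeding the cohort table."""

    case_id: str
    group: str
    diameter_mm: float
    fits: Dict[str, curve_ops.CurveFit]
    indices: Dict[str, curve_ops.IndexResult]
    regional_e: Dict[str, np.ndarray]       # per quadrant, per phase
    regional_tau: Dict[str, np.ndarray]
    qc: Dict = dc_field(default_factory=dict)

    def rows(self) -> List[Dict]:
        out = []
        for q in QUADRANTS:
            res = self.indices.get(q)
            out.append({
                "case_id": self.case_id, "group": self.group,
                "diameter_mm": self.diameter_mm, "quadrant": q,
                "SSI": res.SSI if res else np.nan,
                "dSSI": res.dSSI if res else np.nan})
        return out


def _load_sequence(config: RunConfig) -> Tuple[PhaseSequence, Dict]:
    qc: Dict = {}
    if config.synthetic is not None:
        spec = synthetic.SyntheticCaseSpec(
            **{**config.synthetic, "pressures": tuple(config.pressures)})
        seq, gt = synthetic.generate_case(spec)
        qc["ground_truth_exact"] = gt.exact
        return seq, qc
    mesh = io.read_stl(config.mesh_path)
    fields = [load_displacement_nifti(p) for p in config.displacement_paths]
    disp = np.stack([interpolate_node_displacement(f, mesh.nodes)
                     for f in fields])
    n = len(fields)
    dbp, sbp = config.pressures
    pres = (dbp + (sbp - dbp) * np.arange(n) / max(n - 1, 1)) \
        * synthetic.MMHG_TO_MPA
    return PhaseSequence(mesh=mesh, displacements=disp,
                         pressures_mpa=pres), qc


def run_case(config: RunConfig) -> CaseResult:
    """Execute the full biomechanical chain for one case."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        stamp = out_dir / "config.hash"
        result_file = out_dir / f"{config.case_id}_result.json"
        if stamp.exists() and stamp.read_text().strip() == config.digest() \
                and result_file.exists():
            log.info("cache hit for %s; skipping recomputation",
                     config.case_id)
            return _load_case_result(result_file)

    seq, qc = _load_sequence(config)
    mesh = seq.mesh

    # voxel route: voxelize the motion and re-interpolate at the nodes,
    # emulating a registration-derived displacement field
    if config.use_voxel_fields and config.synthetic is not None:
        fields = synthetic.gen_voxel_displacement_field(
            seq, spacing=config.voxel_spacing)
        disp = np.stack([interpolate_node_displacement(f, mesh.nodes)
                         for f in fields])
        qc["voxel_roundtrip_max_err"] = float(
            np.abs(disp - seq.displacements).max())
        disp[0] = 0.0
        seq = PhaseSequence(mesh=mesh, displacements=disp,
                            pressures_mpa=seq.pressures_mpa)

    # smoothing QC: volume-loss audit of the reconstruction settings
    if config.smoothing_iterations > 0:
        _, loss = geometry.laplace_smooth(mesh, config.smoothing_iterations,
                                          config.smoothing_step)
        qc["smoothing_volume_loss"] = loss
        log.info("smoothing volume loss %.3f%%", 100 * loss)

    # phase selection from the lumen volume curve
    volumes = np.array([geometry.mesh_volume(
        geometry.SurfaceMesh(seq.deformed_nodes(k), mesh.faces))
        for k in range(seq.n_phases)])
    begin, peak, phases = select_dilation_phases(VolumeCurve(volumes))
    qc["phase_selection"] = {"begin": begin, "peak": peak,
                             "n_dilation_phases": len(phases)}

    # strain and tension over the dilation phases
    ref_nodes = mesh.nodes + seq.displacements[phases[0]]
    sub = PhaseSequence(
        mesh=geometry.SurfaceMesh(ref_nodes, mesh.faces.copy()),
        displacements=seq.displacements[phases]
        - seq.displacements[phases[0]],
        pressures_mpa=seq.pressures_mpa[phases])
    strains = strain_field(sub)
    mat = tension.MaterialSpec(model=config.material_model)
    tensions = tension.tension_over_phases(sub, h=config.h, material=mat,
                                           bc=config.bc)

    # region selection: max-diameter plane for aneurysms, mid-vessel for
    # healthy cases
    axis = np.array([0.0, 0.0, 1.0])
    cl = geometry.centerline_and_diameters(mesh, axis_hint=axis)
    z_max, d_max = geometry.max_diameter_plane(cl)
    if config.group == "healthy":
        z_center = float(np.median(mesh.nodes @ axis))
    else:
        z_center = z_max
    region = geometry.RegionSpec(center=z_center,
                                 half_length=config.segment_length / 2.0,
                                 anterior=config.anterior, axis=axis)
    parts = geometry.extract_segment_quadrants(mesh, region, centerline=cl)
    areas = sub.mesh.face_areas()

    regional_e: Dict[str, np.ndarray] = {}
    regional_tau: Dict[str, np.ndarray] = {}
    fits: Dict[str, curve_ops.CurveFit] = {}
    indices: Dict[str, curve_ops.IndexResult] = {}
    p_s = float(config.pressures[1])
    for q in QUADRANTS:
        elems = {q: parts["elements"][q]}
        e_series = np.array([curve_ops.regional_average(s.e_v, areas, elems)[q]
                             for s in strains])
        t_series = np.array([curve_ops.regional_average(t.tau_v, areas,
                                                        elems)[q]
                             for t in tensions])
        regional_e[q] = e_series
        regional_tau[q] = t_series
        fits[q] = curve_ops.fit_power_law(e_series, t_series, region=q)
        indices[q] = curve_ops.compute_indices(
            fits[q], e_max=float(e_series[-1]), p_s_mmhg=p_s, N=config.N,
            region=q)

    result = CaseResult(case_id=config.case_id, group=config.group,
                        diameter_mm=d_max, fits=fits, indices=indices,
                        regional_e=regional_e, regional_tau=regional_tau,
                        qc=qc)
    if out_dir:
        _write_case_outputs(result, config, out_dir, mesh, strains, tensions)
    return result


def _write_case_outputs(result: CaseResult, config: RunConfig, out_dir: Path,
                        mesh, strains, tensions) -> None:
    rows = []
    for q in QUADRANTS:
        for k, (e, t) in enumerate(zip(result.regional_e[q],
                                       result.regional_tau[q])):
            rows.append({"quadrant": q, "phase": k, "e_v": e, "tau_v": t})
    io.write_csv(pd.DataFrame(rows), out_dir / f"{config.case_id}_curves.csv")
    io.write_vtk(mesh, out_dir / f"{config.case_id}_peak.vtk",
                 cell_data={"e_v": strains[-1].e_v,
                            "tau_v": tensions[-1].tau_v})
    io.write_json(_case_result_dict(result),
                  out_dir / f"{config.case_id}_result.json")
    (out_dir / "config.hash").write_text(config.digest() + "\n")


def _case_result_dict(result: CaseResult) -> Dict:
    return {
        "case_id": result.case_id, "group": result.group,
        "diameter_mm": result.diameter_mm, "qc": result.qc,
        "quadrants": {
            q: {"lambda1": result.fits[q].lambda1,
                "lambda2": result.fits[q].lambda2,
                "lambda3": result.fits[q].lambda3,
                "residual": result.fits[q].residual,
                "SSI": result.indices[q].SSI,
                "dSSI": result.indices[q].dSSI,
                "e_max": result.indices[q].e_max,
                "e_v": result.regional_e[q],
                "tau_v": result.regional_tau[q]}
            for q in QUADRANTS},
    }


def _load_case_result(path: Path) -> CaseResult:
    data = json.loads(path.read_text())
    fits, indices, reg_e, reg_t = {}, {}, {}, {}
    for q, d in data["quadrants"].items():
        fits[q] = curve_ops.CurveFit(
            lambda1=d["lambda1"], lambda2=d["lambda2"], lambda3=d["lambda3"],
            residual=d["residual"], region=q)
        indices[q] = curve_ops.IndexResult(
            SSI=d["SSI"], dSSI=d["dSSI"], e_max=d["e_max"],
            p_s_mmhg=np.nan, N=0, region=q)
        reg_e[q] = np.asarray(d["e_v"])
        reg_t[q] = np.asarray(d["tau_v"])
    return CaseResult(case_id=data["case_id"], group=data["group"],
                      diameter_mm=data["diameter_mm"], fits=fits,
                      indices=indices, regional_e=reg_e, regional_tau=reg_t,
                      qc=data["qc"])


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def cohort_table_from_cases(results: Sequence[CaseResult]) -> pd.DataFrame:
    rows: List[Dict] = []
    for r in results:
        rows.extend(r.rows())
    return pd.DataFrame(rows)


def run_cohort(table_or_results, out_dir: Optional[str] = None,
               log_scale: bool = True) -> Dict:
    """Full statistical analysis of a cohort table (or list of case
    results): Pearson vs diameter, quadrant summaries, univariate and
    combined logistic models with ROC/AUC and Youden thresholds."""
    if isinstance(table_or_results, pd.DataFrame):
        table = table_or_results
    else:
        table = cohort_table_from_cases(list(table_or_results))
    report = cohort_stats.cohort_report(table, log_scale=log_scale)
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_csv(table, out / "cohort_table.csv")
        io.write_json(report, out / "cohort_report.json")
    return report
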