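"""Tension-strain curves and the stiffness/hardening indices.

Across the dilation phases each region (or node) yields sample pairs
(e_v, tau_v).  A power law with a constant offset,

    tau_v = lambda1 * e_v**lambda2 + lambda3,
    lambda1 > 0, lambda2 > 1, lambda3 >= 0,

is fitted by constrained least squares (lambda3 covers the residual
tension carried at the reference phase, which a controlled ex vivo test
would not have).  From a fitted curve two scalar indices follow:

    SSI  = 1/(e_max * p_s) * mean_i lambda1 lambda2 e_i**(lambda2-1)
    dSSI = 1/(e_max * p_s) * mean_i lambda1 lambda2 (lambda2-1) e_i**(lambda2-2)

i.e. the mean slope and mean curvature of the fitted curve over sampled
strains e_i, normalized by the strain amplitude at peak systole (e_max)
and the systolic pressure p_s.  The offset lambda3 is annihilated by the
derivatives and never enters the indices.

Unit convention (stated because absolute index values depend on it):
tau_v in N/mm, strains dimensionless, p_s in mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

LAMBDA2_FLOOR = 1.0 + 1e-6


@dataclass
class CurveFit:
    """Constrained power-law fit of one region's tension-strain samples."""

    lambda1: float                  # N/mm
    lambda2: float                  # dimensionless, > 1
    lambda3: float                  # N/mm, >= 0
    residual: float                 # RMS misfit, N/mm
    e_v: np.ndarray = field(default=None, repr=False)    # type: ignore[assignment]
    tau_v: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    region: Optional[str] = None
    lambda2_at_bound: bool = False

    def predict(self, e: np.ndarray) -> np.ndarray:
        e = np.asarray(e, dtype=float)
        return self.lambda1 * e ** self.lambda2 + self.lambda3


@dataclass
class IndexResult:
    """SSI/dSSI evaluation of a fitted curve."""

    SSI: float
    dSSI: float
    e_max: float
    p_s_mmhg: float
    N: int
    e_i: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    region: Optional[str] = None


# ---------------------------------------------------------------------------
# regional averaging
# ---------------------------------------------------------------------------

def regional_average(values: np.ndarray, areas: np.ndarray,
                     regions: Dict[str, np.ndarray]) -> Dict[str, float]:
    """Area-weighted mean of a per-element field over each region."""
    values = np.asarray(values, dtype=float)
    areas = np.asarray(areas, dtype=float)
    out: Dict[str, float] = {}
    for name, idx in regions.items():
        idx = np.asarray(idx)
        if idx.size == 0:
            raise ValueError(f"region '{name}' is empty")
        w = areas[idx]
        out[name] = float(np.sum(values[idx] * w) / np.sum(w))
    return out


# ---------------------------------------------------------------------------
# power-law fitting
# ---------------------------------------------------------------------------

def _starts(e: np.ndarray, tau: np.ndarray) -> List[np.ndarray]:
    """Deterministic multi-start initializations.

    Primary start: lambda2 = 2, lambda1 from the secant through the two
    extreme samples, lambda3 = min tau; plus three fixed alternates for
    robustness on flat or strongly curved data.
    """
    order = np.argsort(e)
    e_lo, e_hi = e[order[0]], e[order[-1]]
    t_lo, t_hi = tau[order[0]], tau[order[-1]]
    l3 = max(float(tau.min()), 0.0)
    denom = max(e_hi ** 2 - e_lo ** 2, 1e-12)
    l1 = max((t_hi - t_lo) / denom, 1e-8)
    starts = [np.array([l1, 2.0, l3])]
    for l2 in (1.2, 3.0, 5.0):
        denom = max(e_hi ** l2 - e_lo ** l2, 1e-12)
        starts.append(np.array([max((t_hi - t_lo) / denom, 1e-8), l2, l3]))
    return starts


def fit_power_law(e_v: Sequence[float], tau_v: Sequence[float],
                  region: Optional[str] = None) -> CurveFit:
    """Constrained least-squares fit of tau = l1 * e**l2 + l3.

    Bounds l1 > 0, l2 > 1, l3 >= 0; a fit whose exponent lands on the
    lower bound (linear-like data) is flagged via ``lambda2_at_bound``.
    """
    e = np.asarray(e_v, dtype=float)
    tau = np.asarray(tau_v, dtype=float)
    if e.shape != tau.shape or e.ndim != 1:
        raise ValueError("e_v and tau_v must be equal-length 1D sequences")
    if e.size < 4:
        raise ValueError("need at least 4 (strain, tension) pairs")
    if np.unique(np.round(e, 12)).size < 3:
        raise ValueError("need at least 3 distinct strain levels")
    if (e < 0).any():
        raise ValueError("strains must be non-negative")

    def resid(x: np.ndarray) -> np.ndarray:
        return x[0] * e ** x[1] + x[2] - tau

    lo = np.array([1e-12, LAMBDA2_FLOOR, 0.0])
    hi = np.array([np.inf, np.inf, np.inf])
    best = None
    for x0 in _starts(e, tau):
        x0 = np.clip(x0, lo + 1e-12, None)
        sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    l1, l2, l3 = best.x
    rms = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    return CurveFit(lambda1=float(l1), lambda2=float(l2), lambda3=float(l3),
                    residual=rms, e_v=e, tau_v=tau, region=region,
                    lambda2_at_bound=bool(l2 < LAMBDA2_FLOOR + 1e-4))


# ---------------------------------------------------------------------------
# index evaluation
# ---------------------------------------------------------------------------

def sample_curve(e_max: float, N: int = 16, e_min: float = 0.0) -> np.ndarray:
    """Uniform strain sampling grid e_i on (e_min, e_max], i = 1..N.

    The default grid e_i = (i/N) e_max excludes zero, keeping the
    curvature term e**(lambda2-2) finite for exponents below 2.  Note the
    zero-anchored grid makes the dSSI mean a Riemann sum of a singular
    integrand for lambda2 < 2 (convergence in N at rate N**(lambda2-1));
    ``e_min`` can anchor the grid at the smallest measured strain instead.
    """
    if e_max <= 0:
        raise ValueError("e_max must be > 0")
    if N < 2:
        raise ValueError("N must be >= 2")
    if not (0.0 <= e_min < e_max):
        raise ValueError("need 0 <= e_min < e_max")
    i = np.arange(1, N + 1)
    return e_min + (i / N) * (e_max - e_min)


def compute_indices(fit: CurveFit, e_max: float, p_s_mmhg: float,
                    N: int = 16, e_min: float = 0.0,
                    region: Optional[str] = None) -> IndexResult:
    """Evaluate SSI and dSSI of a fitted curve.

    p_s is the systolic pressure in mmHg (the package's index unit
    convention); e_max is the regional strain amplitude at peak systole.
    """
    if fit.lambda2 <= 1.0:
        raise ValueError("fit violates the lambda2 > 1 contract")
    if p_s_mmhg <= 0:
        raise ValueError("p_s must be > 0")
    e_i = sample_curve(e_max, N, e_min)
    l1, l2 = fit.lambda1, fit.lambda2
    scale = 1.0 / (e_max * p_s_mmhg)
    ssi = scale * float(np.mean(l1 * l2 * e_i ** (l2 - 1.0)))
    dssi = scale * float(np.mean(l1 * l2 * (l2 - 1.0) * e_i ** (l2 - 2.0)))
    return IndexResult(SSI=ssi, dSSI=dssi, e_max=float(e_max),
                       p_s_mmhg=float(p_s_mmhg), N=int(N), e_i=e_i,
                       region=region or fit.region)


# ---------------------------------------------------------------------------
# nodal maps
# ---------------------------------------------------------------------------

def element_to_node(values: np.ndarray, faces: np.ndarray, areas: np.ndarray,
                    n_nodes: int) -> np.ndarray:
    """Area-weighted average of a per-element field onto nodes."""
    num = np.zeros(n_nodes)
    den = np.zeros(n_nodes)
    for k in range(3):
        np.add.at(num, faces[:, k], values * areas)
        np.add.at(den, faces[:, k], areas)
    den[den == 0.0] = 1.0
    return num / den


def nodal_index_map(
        faces: np.ndarray, areas: np.ndarray, n_nodes: int,
        strain_per_phase: Iterable[np.ndarray],
        tension_per_phase: Iterable[np.ndarray],
        p_s_mmhg: float, N: int = 16,
) -> Dict[str, np.ndarray]:
    """Per-node SSI/dSSI surface maps.

    Element fields are averaged onto nodes per phase; each node's
    (e_v, tau_v) trajectory is fitted and evaluated at the node's own
    peak strain.  Nodes whose fit fails carry NaN and a False status
    flag, never a silent zero.
    """
    e_node = np.stack([element_to_node(ev, faces, areas, n_nodes)
                       for ev in strain_per_phase])
    t_node = np.stack([element_to_node(tv, faces, areas, n_nodes)
                       for tv in tension_per_phase])
    ssi = np.full(n_nodes, np.nan)
    dssi = np.full(n_nodes, np.nan)
    ok = np.zeros(n_nodes, dtype=bool)
    for n in range(n_nodes):
        try:
            fit = fit_power_law(e_node[:, n], t_node[:, n])
            res = compute_indices(fit, e_max=float(e_node[:, n].max()),
                                  p_s_mmhg=p_s_mmhg, N=N)
            ssi[n], dssi[n] = res.SSI, res.dSSI
            ok[n] = True
        except (ValueError, RuntimeError):
            continue
    return {"SSI": ssi, "dSSI": dssi, "ok": ok,
            "e_v": e_node, "tau_v": t_node}
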