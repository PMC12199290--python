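"""Reference toy experiments: the tilted double-well binding surrogate.

A single Langevin particle in a tilted 1D quartic double well stands in for
a ligand moving between a bound basin (S = 0) and an unbound basin (S = 1)
along a straight 21-waypoint reference path padded with 3 fictitious frames
per end.  Because the potential is analytic, the Landau free energy along S
is available by direct quadrature, so the complete nonequilibrium pipeline
— bidirectional SMD, piecewise Crooks/Bennett profile, well-tempered
metadynamics cross-check, partition-ratio binding free energy — can be
validated against exact references.

The default parameters ARE the study conditions used by the test suite and
the reproduction script; they are chosen once for a well-conditioned
barrier (~3.5 kcal/mol from the deep basin at 300 K) and are not tuning
knobs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .path_model import ReferencePath, pad_endpoints
from .thermo import ThermoContext
from .toy_dynamics import (
    DoubleWell1D,
    HillsParams,
    MetaDResult,
    SMDSchedule,
    ToySystem,
    WorkTrace,
    linear_toy_path,
    smd_run,
    wtmetad_run,
)

#: frozen toy study conditions
BARRIER_KCAL = 2.5
HALF_WIDTH_A = 1.5
TILT_KCAL = -1.0
TEMPERATURE_K = 300.0
MASS_AMU = 12.0
FRICTION_PS = 5.0
N_WAYPOINTS = 21
N_PAD = 3
SMD_K = 2000.0         # kcal/mol per unit S²; stiff enough that the
                       # restrained profile tracks the Landau profile
SMD_DURATION_PS = 40.0
SMD_DT_PS = 0.002
N_REPLICAS = 30
METAD_HILLS = HillsParams(
    height=0.5, sigma_s=0.025, sigma_z=1.0, stride_steps=250, bias_factor=5.0
)
METAD_DURATION_PS = 3000.0
METAD_DT_PS = 0.004


@dataclass(frozen=True)
class DoubleWellStudy:
    """Bundled system, padded path and thermodynamic context."""

    system: ToySystem
    path: ReferencePath
    thermo: ThermoContext

    @property
    def nodes(self) -> np.ndarray:
        return self.path.physical_node_s()


def make_double_well_study() -> DoubleWellStudy:
    thermo = ThermoContext(TEMPERATURE_K)
    pot = DoubleWell1D(height=BARRIER_KCAL, half_width=HALF_WIDTH_A, tilt=TILT_KCAL)
    system = ToySystem(pot, dim=1, mass=MASS_AMU, friction=FRICTION_PS, thermo=thermo)
    path = pad_endpoints(
        linear_toy_path(-HALF_WIDTH_A, HALF_WIDTH_A, N_WAYPOINTS), N_PAD, 1.0
    ).with_lambda("printed")
    return DoubleWellStudy(system=system, path=path, thermo=thermo)


def s_of_x(study: DoubleWellStudy, x: np.ndarray) -> np.ndarray:
    """Normalized S as a function of the particle coordinate (vectorized)."""
    path = study.path
    W = np.array([w.coords[0, 0] for w in path.waypoints])
    d = (np.asarray(x)[:, None] - W[None, :]) ** 2
    a = np.exp(-path.lambda_ * d)
    s_raw = (a * np.arange(1.0, len(W) + 1.0)).sum(axis=1) / a.sum(axis=1)
    return (s_raw - 1.0 - path.n_padded_head) / (path.n_physical - 1.0)


def landau_profile(
    study: DoubleWellStudy,
    x_lo: float = -2.2,
    x_hi: float = 2.2,
    n_grid: int = 6001,
) -> np.ndarray:
    """Exact Landau free energy at the path nodes, anchored at node 0.

    In one dimension the change of variables x → s gives
    F(s) = V(x(s)) + RT ln|ds/dx| + const; both terms are evaluated on a
    dense grid and interpolated at the node S values.
    """
    xg = np.linspace(x_lo, x_hi, n_grid)
    sg = s_of_x(study, xg)
    V = np.array([study.system.potential.energy(np.array([x])) for x in xg])
    F = V + study.thermo.RT * np.log(np.abs(np.gradient(sg, xg)))
    x_nodes = np.interp(study.nodes, sg, xg)
    F_nodes = np.interp(x_nodes, xg, F)
    return F_nodes - F_nodes[0]


def basin_populations(
    study: DoubleWellStudy,
    s_split: float,
    x_lo: float = -2.2,
    x_hi: float = 2.2,
    n_grid: int = 20001,
) -> float:
    """ΔF_b = −RT ln(P_site/P_bulk) by direct Boltzmann quadrature over x.

    The site region is {x : s(x) < s_split} within the path span; this is
    the independent reference for the FES partition-ratio route.
    """
    xg = np.linspace(x_lo, x_hi, n_grid)
    sg = s_of_x(study, xg)
    V = np.array([study.system.potential.energy(np.array([x])) for x in xg])
    w = np.exp(-study.thermo.beta * (V - V.min()))
    inside = (sg >= 0.0) & (sg <= 1.0)
    site = inside & (sg < s_split)
    bulk = inside & (sg >= s_split)
    p_site = np.trapezoid(np.where(site, w, 0.0), xg)
    p_bulk = np.trapezoid(np.where(bulk, w, 0.0), xg)
    return float(-study.thermo.RT * np.log(p_site / p_bulk))


def run_smd_batch(
    study: DoubleWellStudy,
    n_replicas: int = N_REPLICAS,
    duration: float = SMD_DURATION_PS,
    dt: float = SMD_DT_PS,
    seed: int = 0,
) -> tuple[list[WorkTrace], list[WorkTrace]]:
    """Equal numbers of unbinding (0→1) and binding (1→0) SMD work traces."""
    fwd, bwd = [], []
    for i in range(n_replicas):
        _, tr_f = smd_run(
            study.system,
            study.path,
            SMDSchedule(k=SMD_K, s_start=0.0, s_end=1.0, duration=duration,
                        direction="unbinding"),
            dt=dt,
            seed=(seed * 1_000_003 + 2 * i) % 2**31,
        )
        _, tr_b = smd_run(
            study.system,
            study.path,
            SMDSchedule(k=SMD_K, s_start=1.0, s_end=0.0, duration=duration,
                        direction="binding"),
            dt=dt,
            seed=(seed * 1_000_003 + 2 * i + 1) % 2**31,
        )
        fwd.append(tr_f)
        bwd.append(tr_b)
    return fwd, bwd


def run_metad(
    study: DoubleWellStudy,
    duration: float = METAD_DURATION_PS,
    dt: float = METAD_DT_PS,
    seed: int = 0,
) -> MetaDResult:
    """Well-tempered metadynamics run starting in the bound basin."""
    return wtmetad_run(
        study.system,
        study.path,
        METAD_HILLS,
        duration=duration,
        dt=dt,
        x0=-HALF_WIDTH_A,
        stride=10,
        seed=seed,
    )


def node_bin_edges(study: DoubleWellStudy, refine: int = 4) -> np.ndarray:
    """Histogram edges spanning the nodes, ``refine``× finer than the node
    spacing (fine bins keep the Boltzmann bin-average close to the pointwise
    free energy; the profile is then interpolated back at the nodes)."""
    nodes = study.nodes
    half = 0.5 * (nodes[1] - nodes[0])
    return np.linspace(nodes[0] - half, nodes[-1] + half,
                       refine * len(nodes) + 1)
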