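"""Desk-scale Langevin engine with the biased-sampling repertoire.

A single particle moves on an analytic low-dimensional potential under BAOAB
Langevin dynamics.  On top of the bare potential the engine implements the
bias types used in path-based binding free energy work:

* constant-velocity steered MD (SMD) on the normalized path variable S with
  a flat-bottom wall on Z, accumulating Jarzynski work;
* adiabatic-bias MD (ABMD): a ratchet restraint active only when a chosen
  collective variable regresses from its best value toward the target;
* well-tempered metadynamics on (S, Z) with decaying Gaussian hills;
* a Debye–Hückel (screened Coulomb) interaction energy collective variable.

Toy reference paths are sequences of single-atom conformations in the toy
coordinate space, so the exact PCV arithmetic of :mod:`pathwork.pcv` is
exercised (here with closed-form gradients).  Units: Å, ps, kcal/mol, amu, K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .path_model import Conformation, ReferencePath, Trajectory
from .thermo import (
    COULOMB_KCAL_A_E2,
    KCALMOL_TO_AMU_A2_PS2,
    KJ_TO_KCAL,
    ThermoContext,
)

#: Default Z-wall position: 0.05 nm² converted to Å².
Z_WALL_A2 = 5.0
#: Default Z-wall force constant: 4×10⁷ kJ mol⁻¹ nm⁻⁴ converted to
#: kcal mol⁻¹ Å⁻⁴ (harmonic in the Z coordinate, which carries units of Å²).
Z_WALL_K = 4.0e7 * KJ_TO_KCAL / 1.0e4


class DynamicsError(RuntimeError):
    """Integration diverged (non-finite or runaway coordinates)."""


# ---------------------------------------------------------------------------
# potentials

class Potential:
    """Analytic potential: energy (kcal/mol) and force (kcal/mol/Å)."""

    dim: int

    def energy(self, x: np.ndarray) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def force(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class Flat(Potential):
    dim: int = 1

    def energy(self, x: np.ndarray) -> float:
        return 0.0

    def force(self, x: np.ndarray) -> np.ndarray:
        return np.zeros(self.dim)


@dataclass(frozen=True)
class Harmonic(Potential):
    """V = ½ k |x − center|²  (k in kcal/mol/Å²)."""

    k: float = 1.0
    center: tuple[float, ...] = (0.0,)

    @property
    def dim(self) -> int:
        return len(self.center)

    def energy(self, x: np.ndarray) -> float:
        d = x - np.asarray(self.center)
        return 0.5 * self.k * float(d @ d)

    def force(self, x: np.ndarray) -> np.ndarray:
        return -self.k * (x - np.asarray(self.center))


@dataclass(frozen=True)
class DoubleWell1D(Potential):
    """Tilted quartic double well, V = h((x/b)² − 1)² + c·x/b.

    ``height`` h is the barrier height of the untilted well (kcal/mol),
    ``half_width`` b the minima positions ±b (Å), ``tilt`` c skews the two
    basins (the x>0 basin is lower for c < 0).
    """

    height: float = 2.5
    half_width: float = 1.5
    tilt: float = 0.0
    dim: int = 1

    def energy(self, x: np.ndarray) -> float:
        u = x[0] / self.half_width
        return self.height * (u * u - 1.0) ** 2 + self.tilt * u

    def force(self, x: np.ndarray) -> np.ndarray:
        u = x[0] / self.half_width
        dvdx = (4.0 * self.height * u * (u * u - 1.0) + self.tilt) / self.half_width
        out = np.zeros(x.shape)
        out[0] = -dvdx
        return out


@dataclass(frozen=True)
class DoubleWell2D(Potential):
    """1D tilted double well along x plus a harmonic transverse mode."""

    height: float = 2.5
    half_width: float = 1.5
    tilt: float = 0.0
    k_transverse: float = 2.0
    dim: int = 2

    def energy(self, x: np.ndarray) -> float:
        u = x[0] / self.half_width
        return (
            self.height * (u * u - 1.0) ** 2
            + self.tilt * u
            + 0.5 * self.k_transverse * float(x[1:] @ x[1:])
        )

    def force(self, x: np.ndarray) -> np.ndarray:
        u = x[0] / self.half_width
        out = -self.k_transverse * x
        out[0] = -(4.0 * self.height * u * (u * u - 1.0) + self.tilt) / self.half_width
        return out


_POTENTIALS = {
    "flat": Flat,
    "harmonic": Harmonic,
    "double_well": DoubleWell1D,
    "double_well_2d": DoubleWell2D,
}


def make_potential(kind: str, **params) -> Potential:
    try:
        cls = _POTENTIALS[kind]
    except KeyError:
        raise ValueError(f"unknown potential kind {kind!r}; "
                         f"known: {sorted(_POTENTIALS)}") from None
    return cls(**params)


# ---------------------------------------------------------------------------
# system and schedules

@dataclass(frozen=True)
class ToySystem:
    """One particle on an analytic potential in a Langevin thermostat."""

    potential: Potential
    dim: int = 1
    mass: float = 12.0           # amu
    friction: float = 5.0        # ps⁻¹
    thermo: ThermoContext = field(default_factory=ThermoContext)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.friction > 0:
            raise ValueError("friction must be positive")
        if not self.mass > 0:
            raise ValueError("mass must be positive")


@dataclass(frozen=True)
class SMDSchedule:
    """Constant-velocity moving restraint Ŝ(t) on normalized S.

    The restraint is R(x,t) = ½ k (S(x) − Ŝ(t))² with Ŝ linear in t from
    ``s_start`` to ``s_end`` over ``duration`` ps; ``k`` is in kcal/mol per
    unit S².  A flat-bottom wall ½ k_wall (Z − z_wall)² acts only when
    Z(x) exceeds ``z_wall`` (Å²).
    """

    k: float
    s_start: float
    s_end: float
    duration: float             # ps
    direction: str = "unbinding"
    z_wall: float = Z_WALL_A2
    z_wall_k: float = Z_WALL_K

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.direction not in ("binding", "unbinding"):
            raise ValueError("direction must be 'binding' or 'unbinding'")

    def s_hat(self, t) -> np.ndarray | float:
        frac = np.clip(np.asarray(t) / self.duration, 0.0, 1.0)
        return self.s_start + (self.s_end - self.s_start) * frac


@dataclass(frozen=True)
class WorkTrace:
    """Accumulated Jarzynski work along one pulling schedule."""

    times: np.ndarray       # ps
    s_hat: np.ndarray       # schedule position
    s_inst: np.ndarray      # instantaneous S(x)
    w_accum: np.ndarray     # kcal/mol, w_accum[0] == 0

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("s_hat", "s_inst", "w_accum"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if n and self.w_accum[0] != 0.0:
            raise ValueError("w_accum must start at 0")

    @property
    def total_work(self) -> float:
        return float(self.w_accum[-1])


@dataclass(frozen=True)
class HillsParams:
    """Well-tempered metadynamics hill parameters.

    Defaults follow common production practice (deposition every 250 steps,
    Z wall at 0.05 nm² with a 4×10⁷ kJ mol⁻¹ nm⁻⁴ constant); height, widths
    and bias factor must be sized to the FES being explored.
    """

    height: float = 1.0          # kcal/mol, initial hill height h₀
    sigma_s: float = 0.2         # width along normalized S
    sigma_z: float = 1.0         # width along Z, Å² (0.01 nm²)
    stride_steps: int = 250      # MD steps between depositions
    bias_factor: float = 15.0    # γ > 1
    z_wall: float = Z_WALL_A2
    z_wall_k: float = Z_WALL_K

    def __post_init__(self) -> None:
        if not self.bias_factor > 1:
            raise ValueError("bias factor γ must exceed 1")
        if not (self.sigma_s > 0 and self.sigma_z > 0):
            raise ValueError("hill widths must be positive")


@dataclass(frozen=True)
class HillsLog:
    """Deposited Gaussians of one well-tempered metadynamics run."""

    times: np.ndarray
    centers_s: np.ndarray
    centers_z: np.ndarray
    sigma_s: float
    sigma_z: float
    heights: np.ndarray
    bias_factor: float

    def bias(self, s, z) -> np.ndarray:
        """Total bias (kcal/mol) at points (s, z), broadcast over inputs."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        z = np.atleast_1d(np.asarray(z, dtype=float))
        out = np.empty(len(s))
        # chunk the (points × hills) kernel matrix to bound memory
        step = max(1, int(2e7) // max(len(self.heights), 1))
        for i in range(0, len(s), step):
            ds = (s[i:i + step, None] - self.centers_s[None, :]) / self.sigma_s
            dz = (z[i:i + step, None] - self.centers_z[None, :]) / self.sigma_z
            out[i:i + step] = np.exp(-0.5 * (ds * ds + dz * dz)) @ self.heights
        return out


@dataclass(frozen=True)
class DebyeHuckelParams:
    """Screened-Coulomb interaction between two charge sets."""

    kappa: float = 0.0           # inverse screening length, Å⁻¹
    eps_r: float = 1.0
    charges_A: tuple[float, ...] = (1.0,)
    charges_B: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if not self.eps_r > 0:
            raise ValueError("eps_r must be positive")


def debye_huckel_energy(
    coords_A: np.ndarray,
    coords_B: np.ndarray,
    params: DebyeHuckelParams,
) -> float:
    """E = C Σᵢⱼ qᵢ qⱼ e^{−κ rᵢⱼ} / (ε_r rᵢⱼ), kcal/mol (C = 332.0637).

    With κ = 0 this is the bare Coulomb energy; κ → ∞ screens it to zero.
    """
    a = np.atleast_2d(np.asarray(coords_A, dtype=float))
    b = np.atleast_2d(np.asarray(coords_B, dtype=float))
    qa = np.asarray(params.charges_A, dtype=float)
    qb = np.asarray(params.charges_B, dtype=float)
    r = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    if np.any(r < 1e-9):
        raise ValueError("coincident atoms across the two sets (r = 0)")
    e = np.exp(-params.kappa * r) / r
    return float(COULOMB_KCAL_A_E2 / params.eps_r * (qa[:, None] * qb[None, :] * e).sum())


# ---------------------------------------------------------------------------
# fast PCV evaluation for single-atom toy paths

class ToyPCV:
    """Closed-form S/Z values and gradients for a toy (1-atom) path."""

    def __init__(self, path: ReferencePath):
        if path.lambda_ is None:
            raise ValueError("path.lambda_ must be set")
        if any(w.n_atoms != 1 for w in path.waypoints):
            raise ValueError("toy paths must have single-atom waypoints")
        if path.align_selection is not None:
            raise ValueError("toy paths are evaluated without superposition")
        self.W = np.stack([w.coords[0] for w in path.waypoints])  # (p, 3)
        self.lam = float(path.lambda_)
        self.idx = np.arange(1.0, self.W.shape[0] + 1.0)
        self.n_head = path.n_padded_head
        self.n_phys = path.n_physical

    def eval(self, x3: np.ndarray):
        """Return (s_norm, z, grad_s_norm, grad_z) at 3-vector ``x3``."""
        diff = x3[None, :] - self.W               # (p, 3)
        d = np.einsum("ij,ij->i", diff, diff)     # MSD of a 1-atom frame
        a = -self.lam * d
        m = a.max()
        w = np.exp(a - m)
        wsum = w.sum()
        psoft = w / wsum
        s_raw = float(self.idx @ psoft)
        z = float(-(m + np.log(wsum)) / self.lam)
        # ∂d_i/∂x = 2(x − W_i)
        grad_s_raw = -2.0 * self.lam * ((self.idx - s_raw) * psoft) @ diff
        grad_z = 2.0 * (psoft @ diff)
        denom = self.n_phys - 1.0
        s_norm = (s_raw - 1.0 - self.n_head) / denom
        return s_norm, z, grad_s_raw / denom, grad_z


def linear_toy_path(
    x_start: float,
    x_end: float,
    n_waypoints: int,
    lambda_convention: str = "printed",
) -> ReferencePath:
    """Straight single-atom reference path along the first coordinate."""
    xs = np.linspace(x_start, x_end, n_waypoints)
    wps = tuple(
        Conformation(("X",), np.array([[x, 0.0, 0.0]])) for x in xs
    )
    path = ReferencePath(wps, align_selection=None, path_selection=None)
    return path.with_lambda(lambda_convention)


# ---------------------------------------------------------------------------
# BAOAB core

def _ou_coeffs(system: ToySystem, dt: float) -> tuple[float, float]:
    c1 = float(np.exp(-system.friction * dt))
    sigma_v = np.sqrt(system.thermo.RT * KCALMOL_TO_AMU_A2_PS2 / system.mass)
    return c1, float(np.sqrt(1.0 - c1 * c1) * sigma_v)


def _check_state(x: np.ndarray, step: int, bound: float = 1e5) -> None:
    if not np.all(np.isfinite(x)) or np.any(np.abs(x) > bound):
        raise DynamicsError(f"dynamics diverged at step {step}: x = {x}")


def _validate_dt(dt: float, duration: float) -> int:
    if not dt > 0:
        raise ValueError("dt must be positive")
    n = int(round(duration / dt))
    if n < 1:
        raise ValueError("duration must cover at least one step")
    return n


def _as_frame(x: np.ndarray) -> Conformation:
    x3 = np.zeros(3)
    x3[: len(x)] = x
    return Conformation(("X",), x3[None, :])


def _pad3(x0, dim: int) -> np.ndarray:
    x = np.zeros(dim)
    arr = np.atleast_1d(np.asarray(x0, dtype=float))
    x[: len(arr)] = arr
    return x


def langevin_run(
    system: ToySystem,
    bias: Callable[[np.ndarray, float], np.ndarray] | None = None,
    duration: float = 10.0,
    dt: float = 0.002,
    x0=0.0,
    v0=None,
    stride: int = 10,
    seed: int | None = None,
) -> Trajectory:
    """BAOAB Langevin trajectory; deterministic for a given seed.

    ``bias(x, t)`` may add a force (kcal/mol/Å) on top of the potential.
    """
    n_steps = _validate_dt(dt, duration)
    rng = np.random.default_rng(system.seed if seed is None else seed)
    conv = KCALMOL_TO_AMU_A2_PS2 / system.mass
    c1, c2 = _ou_coeffs(system, dt)

    x = _pad3(x0, system.dim)
    v = np.zeros(system.dim) if v0 is None else np.asarray(v0, dtype=float).copy()

    def total_force(xx: np.ndarray, t: float) -> np.ndarray:
        f = system.potential.force(xx)
        if bias is not None:
            f = f + bias(xx, t)
        return f

    frames = [_as_frame(x)]
    times = [0.0]
    F = total_force(x, 0.0)
    for step in range(n_steps):
        v += 0.5 * dt * conv * F
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(system.dim)
        x += 0.5 * dt * v
        F = total_force(x, (step + 1) * dt)
        v += 0.5 * dt * conv * F
        if (step + 1) % stride == 0:
            _check_state(x, step + 1)
            frames.append(_as_frame(x))
            times.append((step + 1) * dt)
    _check_state(x, n_steps)
    return Trajectory(tuple(frames), np.array(times))


def smd_run(
    system: ToySystem,
    path: ReferencePath,
    schedule: SMDSchedule,
    dt: float = 0.002,
    x0=None,
    stride: int = 10,
    seed: int | None = None,
) -> tuple[Trajectory, WorkTrace]:
    """Constant-velocity SMD on S with a Z wall, accumulating Jarzynski work.

    The discrete work rule is ΔW = k (Ŝ(t+Δt/2) − S(x_t)) ΔŜ — the force
    conjugate to the schedule coordinate times the schedule displacement —
    with the midpoint schedule value so the frozen-particle limit integrates
    exactly to ½kΔ².  Work is additive over time subintervals by
    construction.
    """
    n_steps = _validate_dt(dt, schedule.duration)
    rng = np.random.default_rng(system.seed if seed is None else seed)
    conv = KCALMOL_TO_AMU_A2_PS2 / system.mass
    c1, c2 = _ou_coeffs(system, dt)
    engine = ToyPCV(path)

    if x0 is None:
        # start on the waypoint nearest to the schedule start
        node_x = engine.W[engine.n_head :][: engine.n_phys]
        i0 = int(round(schedule.s_start * (engine.n_phys - 1)))
        x = node_x[np.clip(i0, 0, engine.n_phys - 1), : system.dim].copy()
    else:
        x = _pad3(x0, system.dim)
    v = np.zeros(system.dim)

    def forces(xx: np.ndarray, t: float):
        x3 = np.zeros(3)
        x3[: system.dim] = xx
        s, z, gs, gz = engine.eval(x3)
        f = system.potential.force(xx)
        f = f + (-schedule.k * (s - schedule.s_hat(t))) * gs[: system.dim]
        if z > schedule.z_wall:
            f = f + (-schedule.z_wall_k * (z - schedule.z_wall)) * gz[: system.dim]
        return f, s

    times = np.arange(n_steps + 1) * dt
    s_hat_arr = np.asarray(schedule.s_hat(times), dtype=float)
    s_inst = np.empty(n_steps + 1)
    w_accum = np.zeros(n_steps + 1)

    F, s = forces(x, 0.0)
    s_inst[0] = s
    frames = [_as_frame(x)]
    frame_times = [0.0]
    for step in range(n_steps):
        s_hat_mid = schedule.s_hat((step + 0.5) * dt)
        dw = schedule.k * (s_hat_mid - s) * (s_hat_arr[step + 1] - s_hat_arr[step])
        w_accum[step + 1] = w_accum[step] + dw

        v += 0.5 * dt * conv * F
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(system.dim)
        x += 0.5 * dt * v
        F, s = forces(x, (step + 1) * dt)
        v += 0.5 * dt * conv * F
        s_inst[step + 1] = s
        if (step + 1) % stride == 0:
            _check_state(x, step + 1)
            frames.append(_as_frame(x))
            frame_times.append((step + 1) * dt)
    _check_state(x, n_steps)
    trace = WorkTrace(times=times, s_hat=s_hat_arr, s_inst=s_inst, w_accum=w_accum)
    return Trajectory(tuple(frames), np.array(frame_times)), trace


@dataclass(frozen=True)
class ABMDResult:
    """Trajectory plus ratchet diagnostics of one ABMD run."""

    trajectory: Trajectory
    cv_values: np.ndarray        # CV at every step
    rho: np.ndarray              # ratchet reference at every step
    bias_energy: np.ndarray      # kcal/mol at every step
    reached_target: bool


def abmd_run(
    system: ToySystem,
    cv: Callable[[np.ndarray], tuple[float, np.ndarray]],
    target: float,
    k_abmd: float,
    duration: float,
    dt: float = 0.002,
    x0=0.0,
    stride: int = 10,
    seed: int | None = None,
    target_tol: float = 1e-2,
) -> ABMDResult:
    """Adiabatic-bias run: ratchet the CV toward ``target``.

    ``cv(x)`` returns (value, gradient).  The ratchet reference ρ is the best
    CV value achieved so far toward the target (monotone, capped at the
    target); the one-sided restraint ½ k_abmd (CV − ρ)² acts only when the CV
    regresses past ρ, so progress is driven by thermal fluctuations alone.
    """
    if not np.isfinite(target):
        raise ValueError("target must be finite")
    n_steps = _validate_dt(dt, duration)
    rng = np.random.default_rng(system.seed if seed is None else seed)
    conv = KCALMOL_TO_AMU_A2_PS2 / system.mass
    c1, c2 = _ou_coeffs(system, dt)

    x = _pad3(x0, system.dim)
    v = np.zeros(system.dim)
    c0, _ = cv(x)
    sign = 1.0 if target >= c0 else -1.0
    rho = c0

    def forces(xx: np.ndarray, rho_now: float):
        val, grad = cv(xx)
        f = system.potential.force(xx)
        lag = (rho_now - val) * sign        # > 0 when regressed past ρ
        done = (rho_now - target) * sign >= 0.0   # ratchet reached the target
        e_bias = 0.0
        if lag > 0 and not done:
            f = f + (-k_abmd * (val - rho_now)) * grad[: system.dim]
            e_bias = 0.5 * k_abmd * (val - rho_now) ** 2
        return f, val, e_bias

    cv_arr = np.empty(n_steps + 1)
    rho_arr = np.empty(n_steps + 1)
    e_arr = np.empty(n_steps + 1)
    F, val, e = forces(x, rho)
    cv_arr[0], rho_arr[0], e_arr[0] = val, rho, e
    frames = [_as_frame(x)]
    frame_times = [0.0]
    for step in range(n_steps):
        v += 0.5 * dt * conv * F
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(system.dim)
        x += 0.5 * dt * v
        F, val, e = forces(x, rho)
        v += 0.5 * dt * conv * F
        # advance the ratchet after the step, clamped at the target
        if sign > 0:
            rho = min(max(rho, val), target)
        else:
            rho = max(min(rho, val), target)
        cv_arr[step + 1], rho_arr[step + 1], e_arr[step + 1] = val, rho, e
        if (step + 1) % stride == 0:
            _check_state(x, step + 1)
            frames.append(_as_frame(x))
            frame_times.append((step + 1) * dt)
    _check_state(x, n_steps)
    reached = bool(abs(rho - target) <= target_tol)
    return ABMDResult(
        Trajectory(tuple(frames), np.array(frame_times)),
        cv_arr, rho_arr, e_arr, reached,
    )


def coordinate_cv(index: int = 0, dim: int = 1):
    """CV = one Cartesian coordinate of the toy particle."""

    grad = np.zeros(dim)
    grad[index] = 1.0

    def cv(x: np.ndarray) -> tuple[float, np.ndarray]:
        return float(x[index]), grad

    return cv


def debye_huckel_cv(
    site_coords: np.ndarray,
    params: DebyeHuckelParams,
    dim: int = 3,
):
    """CV = Debye–Hückel energy between the toy particle and fixed sites.

    The particle carries ``params.charges_A[0]``; the fixed sites carry
    ``params.charges_B``.  Target 0 corresponds to full dissociation.
    """
    sites = np.atleast_2d(np.asarray(site_coords, dtype=float))[:, :dim]
    qa = params.charges_A[0]
    qb = np.asarray(params.charges_B, dtype=float)
    pref = COULOMB_KCAL_A_E2 / params.eps_r

    def cv(x: np.ndarray) -> tuple[float, np.ndarray]:
        diff = x[None, :dim] - sites
        r = np.linalg.norm(diff, axis=1)
        if np.any(r < 1e-9):
            raise ValueError("particle coincides with a site charge")
        e = np.exp(-params.kappa * r) / r
        val = pref * float(qa * qb @ e)
        # dE/dx = C q q' e^{-κr} (−κ r − 1)/r² · r̂
        coef = pref * qa * qb * e * (-params.kappa - 1.0 / r) / r
        grad = (coef[:, None] * diff).sum(axis=0)
        return val, grad

    return cv


@dataclass(frozen=True)
class MetaDResult:
    """Trajectory, deposited hills and the (S, Z) series of one MetaD run."""

    trajectory: Trajectory
    hills: HillsLog
    s: np.ndarray          # S at every recorded frame
    z: np.ndarray          # Z at every recorded frame (Å²)

    def converged(self, fraction: float = 0.1, last: int = 50) -> bool:
        """Residual hill height below ``fraction`` of the initial height,
        averaged over the ``last`` depositions (the standard convergence
        check alongside full diffusivity along S)."""
        h = self.hills.heights
        if len(h) < last:
            return False
        h0 = self.hills.heights.max()
        return bool(h[-last:].mean() < fraction * h0)


def wtmetad_run(
    system: ToySystem,
    path: ReferencePath,
    hills_params: HillsParams,
    duration: float,
    dt: float = 0.002,
    x0=None,
    stride: int = 10,
    seed: int | None = None,
) -> MetaDResult:
    """Well-tempered metadynamics on (S, Z) over a toy path.

    Every ``stride_steps`` steps a Gaussian of height
    h₀·exp(−V_bias(s,z)/((γ−1)RT)) is deposited at the current (s, z); the
    bias is the sum of deposited hills, with the same flat-bottom Z wall as
    in SMD.  Heights decay toward zero as the bias fills the FES.
    """
    n_steps = _validate_dt(dt, duration)
    rng = np.random.default_rng(system.seed if seed is None else seed)
    conv = KCALMOL_TO_AMU_A2_PS2 / system.mass
    c1, c2 = _ou_coeffs(system, dt)
    engine = ToyPCV(path)
    hp = hills_params
    gamma = hp.bias_factor
    rt = system.thermo.RT

    n_hills_max = n_steps // hp.stride_steps + 1
    h_s = np.empty(n_hills_max)
    h_z = np.empty(n_hills_max)
    h_h = np.empty(n_hills_max)
    h_t = np.empty(n_hills_max)
    nh = 0

    def bias_value_grad(s: float, z: float):
        if nh == 0:
            return 0.0, 0.0, 0.0
        ds = (s - h_s[:nh]) / hp.sigma_s
        dz = (z - h_z[:nh]) / hp.sigma_z
        g = h_h[:nh] * np.exp(-0.5 * (ds * ds + dz * dz))
        v = g.sum()
        return float(v), float(-(g * ds).sum() / hp.sigma_s), float(
            -(g * dz).sum() / hp.sigma_z
        )

    if x0 is None:
        x = engine.W[engine.n_head, : system.dim].copy()
    else:
        x = _pad3(x0, system.dim)
    v = np.zeros(system.dim)

    def forces(xx: np.ndarray):
        x3 = np.zeros(3)
        x3[: system.dim] = xx
        s, z, gs, gz = engine.eval(x3)
        vb, dvds, dvdz = bias_value_grad(s, z)
        # force from the metadynamics bias: −∂V/∂s ∇s − ∂V/∂z ∇z
        f = system.potential.force(xx) - dvds * gs[: system.dim] - dvdz * gz[: system.dim]
        if z > hp.z_wall:
            f = f - hp.z_wall_k * (z - hp.z_wall) * gz[: system.dim]
        return f, s, z, vb

    frames = [_as_frame(x)]
    frame_times = [0.0]
    F, s, z, vb = forces(x)
    s_series, z_series = [s], [z]
    for step in range(n_steps):
        v += 0.5 * dt * conv * F
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(system.dim)
        x += 0.5 * dt * v
        F, s, z, vb = forces(x)
        v += 0.5 * dt * conv * F
        if (step + 1) % hp.stride_steps == 0:
            h_s[nh] = s
            h_z[nh] = z
            h_h[nh] = hp.height * np.exp(-vb / ((gamma - 1.0) * rt))
            h_t[nh] = (step + 1) * dt
            nh += 1
            F, s, z, vb = forces(x)   # refresh force with the new hill
        if (step + 1) % stride == 0:
            _check_state(x, step + 1)
            frames.append(_as_frame(x))
            frame_times.append((step + 1) * dt)
            s_series.append(s)
            z_series.append(z)
    _check_state(x, n_steps)
    log = HillsLog(
        times=h_t[:nh].copy(),
        centers_s=h_s[:nh].copy(),
        centers_z=h_z[:nh].copy(),
        sigma_s=hp.sigma_s,
        sigma_z=hp.sigma_z,
        heights=h_h[:nh].copy(),
        bias_factor=gamma,
    )
    return MetaDResult(
        Trajectory(tuple(frames), np.array(frame_times)),
        log,
        np.array(s_series),
        np.array(z_series),
    )


def fes_from_hills(hills: HillsLog, s_grid: np.ndarray, z_eval) -> np.ndarray:
    """FES estimate −(γ/(γ−1))·V_bias(s, z_eval), shifted to min 0."""
    gamma = hills.bias_factor
    z = np.full_like(np.asarray(s_grid, dtype=float), float(np.mean(z_eval))) \
        if np.ndim(z_eval) == 0 else np.asarray(z_eval, dtype=float)
    f = -(gamma / (gamma - 1.0)) * hills.bias(s_grid, z)
    return f - f.min()


def reweight_log_weights(
    s_samples: np.ndarray,
    z_samples: np.ndarray,
    hills: HillsLog,
    thermo: ThermoContext,
) -> np.ndarray:
    """Per-sample log weights β·V_bias,final(s, z), shifted to max 0.

    Final-bias reweighting: once the well-tempered bias has nearly
    converged, the biased samples are re-Boltzmannized by
    exp(+β V_bias(s,z)).  Computing the weights once decouples the O(n·hills)
    bias evaluation from any subsequent (block-)bootstrap over samples.
    """
    logw = thermo.beta * hills.bias(s_samples, z_samples)
    return logw - logw.max()


def weighted_fes(
    s_samples: np.ndarray,
    log_weights: np.ndarray,
    thermo: ThermoContext,
    s_edges: np.ndarray,
) -> np.ndarray:
    """F(s) = −RT ln Σ w over bins (up to a constant; empty bins → NaN)."""
    hist, _ = np.histogram(s_samples, bins=np.asarray(s_edges), weights=np.exp(log_weights))
    with np.errstate(divide="ignore"):
        f = -thermo.RT * np.log(hist)
    f[hist == 0] = np.nan
    return f - np.nanmin(f)


def reweighted_fes(
    s_samples: np.ndarray,
    z_samples: np.ndarray,
    hills: HillsLog,
    thermo: ThermoContext,
    s_edges: np.ndarray,
) -> np.ndarray:
    """FES along S from final-bias reweighting of visited configurations."""
    logw = reweight_log_weights(s_samples, z_samples, hills, thermo)
    return weighted_fes(s_samples, logw, thermo, s_edges)


def metad_fes_block_bootstrap(
    s_samples: np.ndarray,
    z_samples: np.ndarray,
    hills: HillsLog,
    thermo: ThermoContext,
    s_edges: np.ndarray,
    n_blocks: int = 10,
    n_boot: int = 400,
    seed: int | None = None,
    eval_s: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(FES, per-point stderr) by block bootstrap of the reweighted histogram.

    The time series is cut into ``n_blocks`` contiguous blocks which are
    resampled with replacement ``n_boot`` times.  With ``eval_s`` given,
    every replicate profile is interpolated from the finite histogram bins
    at those S values (use bins finer than the feature scale to avoid
    bin-averaging bias, then evaluate at the path nodes); profiles are
    anchored at their first point before taking per-point deviations.
    """
    s_samples = np.asarray(s_samples)
    centers = 0.5 * (np.asarray(s_edges)[:-1] + np.asarray(s_edges)[1:])
    logw = reweight_log_weights(s_samples, z_samples, hills, thermo)

    def estimate(s, lw):
        f = weighted_fes(s, lw, thermo, s_edges)
        if eval_s is None:
            return f
        ok = np.isfinite(f)
        return np.interp(eval_s, centers[ok], f[ok])

    point = estimate(s_samples, logw)
    rng = np.random.default_rng(seed)
    blocks = np.array_split(np.arange(len(s_samples)), n_blocks)
    boots = np.empty((n_boot, len(point)))
    for b in range(n_boot):
        idx = np.concatenate([blocks[j] for j in rng.integers(0, n_blocks, n_blocks)])
        boots[b] = estimate(s_samples[idx], logw[idx])
    boots -= boots[:, :1]
    err = np.nanstd(boots, axis=0, ddof=1)
    return point, err
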