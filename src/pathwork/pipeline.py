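"""Configuration schema and the five-step toy pipeline.

The pipeline mirrors the nonequilibrium binding strategy end to end on a
toy system: (1) an ABMD run (or a straight line) provides the guess path;
(2) the guess is resampled to equidistant waypoints and (3) λ is
calibrated; (4) equal numbers of forward (unbinding, S: 0→1) and backward
(binding, S: 1→0) SMD replicas accumulate Jarzynski work; (5) the piecewise
Crooks/Bennett profile is assembled into a standard binding free energy.

Every stochastic stage draws its seed from the master seed through named
substreams, so each replica is reproducible in isolation and a rerun of the
same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import io as pwio
from .binding_energy import (
    assemble_standard,
    integrate_partition_ratio,
    select_discriminating_index,
)
from .neq_estimators import build_segment_work_set, cft_profile
from .path_model import Conformation, ReferencePath, pad_endpoints, reparametrize_equidistant
from .thermo import STANDARD_VOLUME_A3, ThermoContext
from .toy_dynamics import (
    SMDSchedule,
    ToySystem,
    Z_WALL_A2,
    Z_WALL_K,
    abmd_run,
    coordinate_cv,
    linear_toy_path,
    make_potential,
    smd_run,
)

logger = logging.getLogger("pathwork")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PotentialSpec(_Strict):
    kind: str = "double_well"
    params: dict[str, float] = Field(
        default_factory=lambda: {"height": 2.5, "half_width": 1.5, "tilt": -1.0}
    )


class SystemSpec(_Strict):
    potential: PotentialSpec = Field(default_factory=PotentialSpec)
    dim: int = 1
    mass: float = 12.0
    friction: float = 5.0


class ABMDSpec(_Strict):
    k_abmd: float = 20.0       # kcal/mol per squared CV unit
    duration: float = 100.0    # ps
    dt: float = 0.002
    target: Optional[float] = None   # defaults to path x_end


class PathSpec(_Strict):
    x_start: float = -1.5      # bound-basin minimum
    x_end: float = 1.5         # unbound-basin minimum
    n_waypoints: int = 21
    lambda_convention: Literal["printed", "mean-gap"] = "printed"
    guess: Literal["line", "abmd"] = "line"
    abmd: ABMDSpec = Field(default_factory=ABMDSpec)
    reparam_tol: float = 0.01
    pad_n: int = 3
    pad_step_scale: float = 1.0


class SMDSpec(_Strict):
    k: float = 2000.0          # kcal/mol per unit S²
    duration: float = 40.0     # ps per replica
    dt: float = 0.002
    n_replicas: int = 30       # per direction
    z_wall: float = Z_WALL_A2
    z_wall_k: float = Z_WALL_K


class EstimatorSpec(_Strict):
    n_boot: int = 200


class BindingSpec(_Strict):
    split_index: Optional[int] = None     # None → automatic barrier search
    v_bulk: float = STANDARD_VOLUME_A3    # Å³
    corrections: dict[str, float] = Field(default_factory=dict)


class RunConfig(_Strict):
    """Full declaration of one toy pipeline run (unknown keys rejected)."""

    version: int = 1
    seed: int = 0
    temperature: float = 300.0
    system: SystemSpec = Field(default_factory=SystemSpec)
    path: PathSpec = Field(default_factory=PathSpec)
    smd: SMDSpec = Field(default_factory=SMDSpec)
    estimator: EstimatorSpec = Field(default_factory=EstimatorSpec)
    binding: BindingSpec = Field(default_factory=BindingSpec)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.model_validate(data)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def substream_seed(master: int, *key: int) -> int:
    """Deterministic child seed (< 2³¹) from the master seed and a key."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def build_toy_system(config: RunConfig) -> ToySystem:
    pot = make_potential(config.system.potential.kind, **config.system.potential.params)
    return ToySystem(
        potential=pot,
        dim=config.system.dim,
        mass=config.system.mass,
        friction=config.system.friction,
        thermo=ThermoContext(config.temperature),
    )


def build_guess_path(config: RunConfig, system: ToySystem) -> ReferencePath:
    """Guess path from a straight line or from an ABMD unbinding run."""
    ps = config.path
    if ps.guess == "line":
        return linear_toy_path(ps.x_start, ps.x_end, max(ps.n_waypoints, 2))
    target = ps.abmd.target if ps.abmd.target is not None else ps.x_end
    res = abmd_run(
        system,
        coordinate_cv(0, system.dim),
        target=target,
        k_abmd=ps.abmd.k_abmd,
        duration=ps.abmd.duration,
        dt=ps.abmd.dt,
        x0=ps.x_start,
        stride=1,
        seed=substream_seed(config.seed, 0),
    )
    if not res.reached_target:
        raise RuntimeError(
            "stage guess-path: ABMD run did not reach the target CV value; "
            "increase duration or k_abmd"
        )
    # keep only frames where the ratchet advanced → monotone guess skeleton
    rho = res.rho
    advance = np.nonzero(np.diff(rho) > 1e-6)[0] + 1
    keep = [0, *advance.tolist()]
    frames = [res.trajectory.frames[min(i, len(res.trajectory) - 1)] for i in keep]
    # pin the exact endpoints so the path spans the declared range
    first = Conformation(("X",), np.array([[ps.x_start, 0.0, 0.0]]))
    last = Conformation(("X",), np.array([[target, 0.0, 0.0]]))
    return ReferencePath(tuple([first, *frames[1:], last]), align_selection=None)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full toy pipeline; artifacts are written to ``out_dir``.

    Returns a summary dict (also stored as ``binding.json``).  Any stage
    failure raises with the stage name; artifacts produced so far remain on
    disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thermo = ThermoContext(config.temperature)
    chash = config_hash(config)
    logger.info("pipeline start: hash=%s seed=%d", chash, config.seed)

    def stage(name):
        logger.info("stage %s", name)
        return name

    current = stage("system")
    try:
        system = build_toy_system(config)

        current = stage("guess-path")
        guess = build_guess_path(config, system)

        current = stage("reparametrize")
        path = reparametrize_equidistant(
            guess, config.path.n_waypoints, tol=config.path.reparam_tol
        )

        current = stage("lambda")
        path = path.with_lambda(config.path.lambda_convention)
        if config.path.pad_n:
            path = pad_endpoints(path, config.path.pad_n, config.path.pad_step_scale)
            path = path.with_lambda(config.path.lambda_convention)
        logger.info(
            "lambda=%.6g A^-2 (%s convention), p=%d",
            path.lambda_, config.path.lambda_convention, path.p,
        )
        pwio.write_path_frames(out / "path.xyz", path.waypoints)

        current = stage("smd")
        smd = config.smd
        fwd_traces, bwd_traces = [], []
        for i in range(smd.n_replicas):
            for direction, bucket, key in (
                ("unbinding", fwd_traces, 1),
                ("binding", bwd_traces, 2),
            ):
                s0, s1 = (0.0, 1.0) if direction == "unbinding" else (1.0, 0.0)
                sched = SMDSchedule(
                    k=smd.k, s_start=s0, s_end=s1, duration=smd.duration,
                    direction=direction, z_wall=smd.z_wall, z_wall_k=smd.z_wall_k,
                )
                _, trace = smd_run(
                    system, path, sched, dt=smd.dt,
                    seed=substream_seed(config.seed, key, i),
                )
                bucket.append(trace)
                tag = "f" if direction == "unbinding" else "b"
                pwio.write_colvar(
                    out / f"colvar_{tag}{i:02d}.tsv",
                    {
                        "time": trace.times[::10],
                        "s_hat": trace.s_hat[::10],
                        "s_inst": trace.s_inst[::10],
                        "w_accum": trace.w_accum[::10],
                    },
                )

        current = stage("cft-fes")
        segments = build_segment_work_set(fwd_traces, bwd_traces, path)
        fes = cft_profile(
            segments, thermo,
            n_boot=config.estimator.n_boot,
            seed=substream_seed(config.seed, 3),
        )
        pwio.write_fes(out / "fes.tsv", fes.s, fes.F, fes.stderr)

        current = stage("binding")
        split = select_discriminating_index(fes, override=config.binding.split_index)
        ratio, dF_b = integrate_partition_ratio(fes, split, thermo)
        from .binding_energy import volume_correction

        dF_v = volume_correction(config.binding.v_bulk, thermo)
        result = assemble_standard(
            dF_b, dF_v, config.binding.corrections,
            term_errors={"dF_b": float(fes.stderr[-1])},
            partition_ratio=ratio,
            V_bulk=config.binding.v_bulk,
            discriminating_index=split,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    summary = {
        "config_hash": chash,
        "seed": config.seed,
        "temperature_K": config.temperature,
        "lambda_A-2": path.lambda_,
        "lambda_convention": config.path.lambda_convention,
        "work_sign_convention": "backward works stored in forward convention",
        "n_waypoints": path.p,
        "n_replicas_per_direction": config.smd.n_replicas,
        "discriminating_index": result.discriminating_index,
        "partition_ratio": result.partition_ratio,
        "dF_b_kcal_mol": result.dF_b,
        "dF_v_kcal_mol": result.dF_v,
        "extra_corrections_kcal_mol": result.extra_corrections,
        "dF_standard_kcal_mol": result.dF_standard,
        "stderr_kcal_mol": result.stderr,
    }
    with open(out / "binding.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline done: dF_standard=%.4f kcal/mol", result.dF_standard)
    return summary
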