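"""Nonequilibrium free-energy estimators.

Work traces from bidirectional steered simulations are segmented along the
reference path and the Crooks fluctuation theorem (CFT) is applied piecewise
through its maximum-likelihood (Bennett) form:

    ⟨{1 + exp[β(W_f − ΔF)]}⁻¹⟩_f  =  ⟨{1 + exp[−β(W_b − ΔF)]}⁻¹⟩_b

solved self-consistently per segment, with equal numbers of forward and
backward replicas.  Chaining the segment ΔF's gives the free energy profile
along the normalized path variable S.  Unidirectional Jarzynski estimates
(−β⁻¹ ln⟨e^{−βW}⟩), dissipated-work diagnostics, bootstrap errors and a
Crooks-consistent synthetic work generator complete the layer.

Sign convention (the single source of truth): backward work values are
always expressed in the *forward* convention, i.e. the negative of the work
measured along the reverse process.  Under this convention
w_f = w_b = w ⇒ ΔF = w, and the Gaussian pair
(N(ΔF + βσ²/2, σ²), N(ΔF − βσ²/2, σ²)) satisfies the CFT identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .path_model import ReferencePath
from .thermo import ThermoContext
from .toy_dynamics import WorkTrace


@dataclass(frozen=True)
class SegmentWorkSet:
    """Forward/backward work increments per path segment.

    ``w_forward[i]`` / ``w_backward[i]`` hold one increment per replica over
    the segment (node_s[i], node_s[i+1]); backward increments are already in
    the forward sign convention.
    """

    node_s: np.ndarray               # (n_nodes,)
    w_forward: np.ndarray            # (n_segments, n_replicas)
    w_backward: np.ndarray           # (n_segments, n_replicas)

    def __post_init__(self) -> None:
        node_s = np.asarray(self.node_s, dtype=float)
        wf = np.asarray(self.w_forward, dtype=float)
        wb = np.asarray(self.w_backward, dtype=float)
        if wf.shape[0] != len(node_s) - 1 or wb.shape[0] != len(node_s) - 1:
            raise ValueError("need one work row per segment")
        if wf.shape[1] != wb.shape[1]:
            raise ValueError(
                "equal numbers of forward and backward replicas are required "
                f"(got {wf.shape[1]} vs {wb.shape[1]})"
            )
        if not (np.all(np.isfinite(wf)) and np.all(np.isfinite(wb))):
            raise ValueError("work increments must be finite")
        object.__setattr__(self, "node_s", node_s)
        object.__setattr__(self, "w_forward", wf)
        object.__setattr__(self, "w_backward", wb)

    @property
    def n_replicas(self) -> int:
        return self.w_forward.shape[1]

    @property
    def n_segments(self) -> int:
        return self.w_forward.shape[0]


@dataclass(frozen=True)
class FESProfile:
    """Free energy along normalized S, anchored at F[0] = 0 (bound state)."""

    s: np.ndarray
    F: np.ndarray                # kcal/mol
    stderr: np.ndarray           # kcal/mol per node

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        F = np.asarray(self.F, dtype=float)
        err = np.asarray(self.stderr, dtype=float)
        if not (len(s) == len(F) == len(err)):
            raise ValueError("s, F, stderr must have equal length")
        if len(F) and F[0] != 0.0:
            raise ValueError("profile must be anchored at F[0] = 0")
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "stderr", err)


@dataclass(frozen=True)
class EstimateDiagnostics:
    """Mean and dissipated work of one direction: W_diss = ⟨W⟩ − ΔF̂ ≥ 0."""

    mean_work: float
    dF: float
    dissipated: float


def segment_works(
    traces: Sequence[WorkTrace],
    path_or_nodes: ReferencePath | np.ndarray,
    direction: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Work increments at node crossings of the schedule coordinate.

    For each trace the times at which the moving restraint Ŝ crosses each
    node are found (the schedule, not the instantaneous S, indexes the
    crossing — the restraint is what the work is measured against) and the
    accumulated work is interpolated linearly in time at those instants.
    Returns (node_s, increments) with increments of shape
    (n_segments, n_replicas); for ``direction="backward"`` the increments are
    sign-flipped into the forward convention.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    if isinstance(path_or_nodes, ReferencePath):
        nodes = path_or_nodes.physical_node_s()
    else:
        nodes = np.asarray(path_or_nodes, dtype=float)
    if np.any(np.diff(nodes) <= 0):
        raise ValueError("node_s must be strictly increasing")

    cols = []
    for r, tr in enumerate(traces):
        s_hat = np.asarray(tr.s_hat, dtype=float)
        lo, hi = min(s_hat[0], s_hat[-1]), max(s_hat[0], s_hat[-1])
        tol = 1e-9
        if nodes[0] < lo - tol or nodes[-1] > hi + tol:
            raise ValueError(
                f"replica {r}: schedule spans [{lo:.4g}, {hi:.4g}] and does "
                f"not cover nodes [{nodes[0]:.4g}, {nodes[-1]:.4g}]"
            )
        if s_hat[-1] >= s_hat[0]:
            t_cross = np.interp(nodes, s_hat, tr.times)
        else:
            t_cross = np.interp(nodes, s_hat[::-1], tr.times[::-1])
        w_cross = np.interp(t_cross, tr.times, tr.w_accum)
        # diff along increasing nodes; for a high→low schedule this is the
        # negated reverse-process increment, i.e. the forward convention
        cols.append(np.diff(w_cross))
    inc = np.stack(cols, axis=1)
    return nodes, inc


def build_segment_work_set(
    forward_traces: Sequence[WorkTrace],
    backward_traces: Sequence[WorkTrace],
    path_or_nodes: ReferencePath | np.ndarray,
) -> SegmentWorkSet:
    """Segment both directions and assemble a :class:`SegmentWorkSet`."""
    nodes, wf = segment_works(forward_traces, path_or_nodes, "forward")
    _, wb = segment_works(backward_traces, path_or_nodes, "backward")
    return SegmentWorkSet(node_s=nodes, w_forward=wf, w_backward=wb)


def bennett_solve(
    w_f: np.ndarray,
    w_b: np.ndarray,
    thermo: ThermoContext,
    xtol: float = 1e-12,
) -> float:
    """ΔF (kcal/mol) from the self-consistent CFT/Bennett equation.

    Unique root of
    ⟨expit(−β(w_f − ΔF))⟩ − ⟨expit(β(w_b − ΔF))⟩ = 0, found by bracketed
    root-finding; the bracket starts at [min − 10RT, max + 10RT] of all work
    values and is expanded if needed.
    """
    w_f = np.asarray(w_f, dtype=float).ravel()
    w_b = np.asarray(w_b, dtype=float).ravel()
    if len(w_f) < 1 or len(w_f) != len(w_b):
        raise ValueError(
            "equal, non-empty forward and backward work samples required "
            f"(got {len(w_f)} vs {len(w_b)})"
        )
    beta = thermo.beta

    def g(dF: float) -> float:
        return float(
            np.mean(expit(-beta * (w_f - dF))) - np.mean(expit(beta * (w_b - dF)))
        )

    allw = np.concatenate([w_f, w_b])
    span = 10.0 * thermo.RT
    lo, hi = float(allw.min()) - span, float(allw.max()) + span
    for _ in range(60):
        if g(lo) < 0 < g(hi):
            break
        lo -= span
        hi += span
    else:
        raise RuntimeError(
            f"no sign change in Bennett bracket; residual g({lo})={g(lo):.3g}, "
            f"g({hi})={g(hi):.3g}"
        )
    return float(brentq(g, lo, hi, xtol=xtol))


def cft_profile(
    segments: SegmentWorkSet,
    thermo: ThermoContext,
    n_boot: int = 0,
    seed: int | None = None,
) -> FESProfile:
    """Piecewise CFT free energy profile: F[i+1] = F[i] + ΔF̂(segment i).

    With ``n_boot`` > 0 the per-node standard errors are estimated by
    paired-replica bootstrap (the same replica resample is used across all
    segments; errors are cumulative along the profile).
    """
    dFs = np.array(
        [
            bennett_solve(segments.w_forward[i], segments.w_backward[i], thermo)
            for i in range(segments.n_segments)
        ]
    )
    F = np.concatenate([[0.0], np.cumsum(dFs)])
    if n_boot > 0:
        err = _bootstrap_profile_stderr(segments, thermo, n_boot, seed)
    else:
        err = np.zeros_like(F)
    return FESProfile(s=segments.node_s, F=F, stderr=err)


def _bootstrap_profile_stderr(
    segments: SegmentWorkSet,
    thermo: ThermoContext,
    n_boot: int,
    seed: int | None,
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n_rep = segments.n_replicas
    profiles = np.empty((n_boot, segments.n_segments + 1))
    for b in range(n_boot):
        idx = rng.integers(0, n_rep, size=n_rep)
        dFs = [
            bennett_solve(
                segments.w_forward[i, idx], segments.w_backward[i, idx], thermo
            )
            for i in range(segments.n_segments)
        ]
        profiles[b] = np.concatenate([[0.0], np.cumsum(dFs)])
    return profiles.std(axis=0, ddof=1)


def jarzynski_estimate(
    w_f: np.ndarray,
    thermo: ThermoContext,
) -> tuple[float, EstimateDiagnostics]:
    """ΔF = −β⁻¹ ln⟨e^{−βW}⟩ with log-sum-exp stabilization.

    Also returns the mean and dissipated work; by Jensen's inequality the
    estimate never exceeds the sample mean.
    """
    w = np.asarray(w_f, dtype=float).ravel()
    if len(w) == 0:
        raise ValueError("empty work sample")
    dF = float(-thermo.RT * (logsumexp(-thermo.beta * w) - np.log(len(w))))
    mean = float(w.mean())
    return dF, EstimateDiagnostics(mean_work=mean, dF=dF, dissipated=mean - dF)


def generate_crooks_works(
    dF: float,
    sigma: float,
    n: int,
    thermo: ThermoContext,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic work pair satisfying the Crooks fluctuation theorem exactly.

    w_f ~ N(ΔF + βσ²/2, σ²) and w_b ~ N(ΔF − βσ²/2, σ²) (forward sign
    convention): the log-density ratio ln[P_f(W)/P_b(W)] equals β(W − ΔF)
    identically, and dissipation is symmetric between directions.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    diss = thermo.beta * sigma * sigma / 2.0
    w_f = rng.normal(dF + diss, sigma, size=n)
    w_b = rng.normal(dF - diss, sigma, size=n)
    return w_f, w_b


@dataclass(frozen=True)
class BootstrapResult:
    estimate: float
    stderr: float
    ci_low: float
    ci_high: float
    n_boot: int


def bootstrap_error(
    data,
    estimator: Callable,
    n_boot: int = 1000,
    seed: int | None = None,
    ci: float = 0.95,
    blocks: int | None = None,
) -> BootstrapResult:
    """Bootstrap standard error and percentile CI of a scalar estimator.

    ``data`` is either a :class:`SegmentWorkSet` (replicas are resampled with
    replacement, paired across segments and directions) or an array whose
    first axis indexes replicas/samples.  With ``blocks`` set, contiguous
    blocks are resampled instead of individual samples (block bootstrap, as
    used for metadynamics time series: 10 blocks, 400 iterations).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)

    if isinstance(data, SegmentWorkSet):
        n = data.n_replicas
        if n < 2:
            raise ValueError("need at least 2 replicas to bootstrap")

        def resample():
            idx = rng.integers(0, n, size=n)
            return SegmentWorkSet(
                node_s=data.node_s,
                w_forward=data.w_forward[:, idx],
                w_backward=data.w_backward[:, idx],
            )

        point = float(estimator(data))
    else:
        arr = np.asarray(data)
        n = arr.shape[0]
        if n < 2:
            raise ValueError("need at least 2 samples to bootstrap")
        if blocks is not None:
            bounds = np.linspace(0, n, blocks + 1).astype(int)
            chunks = [arr[bounds[i]: bounds[i + 1]] for i in range(blocks)]

            def resample():
                pick = rng.integers(0, blocks, size=blocks)
                return np.concatenate([chunks[j] for j in pick], axis=0)

        else:

            def resample():
                return arr[rng.integers(0, n, size=n)]

        point = float(estimator(arr))

    stats = np.array([float(estimator(resample())) for _ in range(n_boot)])
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return BootstrapResult(
        estimate=point,
        stderr=float(stats.std(ddof=1)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
    )
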