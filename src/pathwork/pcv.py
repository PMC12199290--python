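"""Path collective variables S(x) and Z(x).

Given a reference path of p waypoints x₁…x_p and a smoothness parameter λ,

    S(x) = Σᵢ i e^{−λ‖x−xᵢ‖²} / Σⱼ e^{−λ‖x−xⱼ‖²}
    Z(x) = −λ⁻¹ ln Σᵢ e^{−λ‖x−xᵢ‖²}

with ‖x−xᵢ‖² the optimal-alignment MSD in Cartesian space.  S measures
progression along the path (≈ i when x ≈ xᵢ) and Z the orthogonal deviation
(a soft minimum of the MSDs; it can dip slightly below zero for closely
spaced frames).  Both are evaluated with log-sum-exp stabilization so large
λ·MSD products cannot underflow.

S is reported both raw (in [1, p]) and normalized to [0, 1] over the
*physical* waypoints, so fictitious padding frames do not shift the bound
(S = 0) and unbound (S = 1) states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .path_model import Conformation, ReferencePath, Trajectory, msd


@dataclass(frozen=True)
class PCVValue:
    """S/Z evaluation of one conformation against a reference path."""

    s_raw: float          # in [1, p] up to softmax leakage
    s_norm: float         # clamped to [0, 1]
    s_norm_raw: float     # unclamped normalized value
    z: float              # Å²
    nearest_index: int    # 0-based waypoint index (lower index on ties)


def _msd_vector(x: Conformation, path: ReferencePath) -> np.ndarray:
    return np.array(
        [msd(x, w, path.align_selection, path.path_selection) for w in path.waypoints]
    )


def eval_pcv(
    x: Conformation,
    path: ReferencePath,
    include_padded_in_norm: bool = False,
) -> PCVValue:
    """Evaluate S(x) and Z(x) for a single conformation."""
    if path.lambda_ is None or not path.lambda_ > 0:
        raise ValueError("path.lambda_ must be set and positive; "
                         "call ReferencePath.with_lambda() first")
    d = _msd_vector(x, path)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite MSD encountered in PCV evaluation")
    return pcv_from_msds(
        d,
        path.lambda_,
        n_padded_head=0 if include_padded_in_norm else path.n_padded_head,
        n_padded_tail=0 if include_padded_in_norm else path.n_padded_tail,
    )


def pcv_from_msds(
    d: np.ndarray,
    lambda_: float,
    n_padded_head: int = 0,
    n_padded_tail: int = 0,
) -> PCVValue:
    """S/Z from a precomputed vector of MSDs to every waypoint (Å²)."""
    d = np.asarray(d, dtype=float)
    p = d.shape[0]
    a = -lambda_ * d
    m = a.max()
    w = np.exp(a - m)
    wsum = w.sum()
    idx = np.arange(1, p + 1, dtype=float)
    s_raw = float((idx * w).sum() / wsum)
    z = float(-(m + np.log(wsum)) / lambda_)
    n_phys = p - n_padded_head - n_padded_tail
    s_norm_raw = (s_raw - 1.0 - n_padded_head) / (n_phys - 1.0)
    return PCVValue(
        s_raw=s_raw,
        s_norm=float(np.clip(s_norm_raw, 0.0, 1.0)),
        s_norm_raw=float(s_norm_raw),
        z=z,
        nearest_index=int(np.argmin(d)),
    )


def eval_pcv_trajectory(
    traj: Trajectory,
    path: ReferencePath,
    include_padded_in_norm: bool = False,
) -> list[PCVValue]:
    """Element-wise :func:`eval_pcv` over a trajectory, order preserved."""
    return [eval_pcv(f, path, include_padded_in_norm) for f in traj.frames]
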