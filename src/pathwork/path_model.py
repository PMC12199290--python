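"""Reference-path geometry for path collective variables.

A reference path is an ordered set of molecular configurations (waypoints)
connecting a bound and an unbound state.  Progression along it is later
measured by the path collective variables (:mod:`pathwork.pcv`), which
require the waypoints to be equidistant in mean-square deviation (MSD) and a
smoothness parameter λ calibrated to the inter-waypoint spacing.

This module provides optimal superposition (Kabsch), the MSD metric,
λ calibration, equidistant-waypoint reparametrization, RMSF-based selection
of alignment atoms, and endpoint padding with fictitious configurations.
All coordinates are in Å, MSDs in Å², λ in Å⁻².
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation


class SelectionError(ValueError):
    """A requested atom selection is empty or absent from a conformation."""


class DegenerateAlignmentError(ValueError):
    """Fewer than 3 non-collinear atoms: the optimal rotation is not unique."""


@dataclass(frozen=True)
class Conformation:
    """A labelled set of 3D coordinates (Å).

    ``atom_labels`` fixes atom identity and order; all conformations of one
    system must share it.  ``weights`` are optional per-atom alignment
    weights (uniform if omitted).
    """

    atom_labels: tuple[str, ...]
    coords: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {coords.shape}")
        if coords.shape[0] != len(self.atom_labels):
            raise ValueError("coords and atom_labels length mismatch")
        if coords.shape[0] < 1:
            raise ValueError("need at least one atom")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords must be finite")
        if len(set(self.atom_labels)) != len(self.atom_labels):
            raise ValueError("atom labels must be unique")
        object.__setattr__(self, "atom_labels", tuple(self.atom_labels))
        object.__setattr__(self, "coords", coords)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (coords.shape[0],):
                raise ValueError("weights must be one scalar per atom")
            object.__setattr__(self, "weights", w)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def indices(self, selection: Sequence[str] | None) -> np.ndarray:
        """Indices of ``selection`` labels (all atoms if None)."""
        if selection is None:
            return np.arange(self.n_atoms)
        if len(selection) == 0:
            raise SelectionError("empty atom selection")
        lookup = {lab: i for i, lab in enumerate(self.atom_labels)}
        missing = [s for s in selection if s not in lookup]
        if missing:
            raise SelectionError(f"selection atoms not present: {missing}")
        return np.array([lookup[s] for s in selection], dtype=int)

    def subset(self, selection: Sequence[str]) -> "Conformation":
        idx = self.indices(selection)
        w = None if self.weights is None else self.weights[idx]
        return Conformation(tuple(self.atom_labels[i] for i in idx), self.coords[idx], w)


@dataclass(frozen=True)
class Trajectory:
    """Ordered conformations with strictly increasing times (ps)."""

    frames: tuple[Conformation, ...]
    times: np.ndarray

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        times = np.asarray(self.times, dtype=float)
        if len(frames) != len(times):
            raise ValueError("len(times) must equal len(frames)")
        if len(frames) and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        labels = {f.atom_labels for f in frames}
        if len(labels) > 1:
            raise ValueError("all frames must share atom_labels")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return len(self.frames)

    def coords_array(self) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_atoms, 3)."""
        return np.stack([f.coords for f in self.frames])


@dataclass(frozen=True)
class SuperposeResult:
    rotation: np.ndarray       # (3, 3), proper (det = +1)
    translation: np.ndarray    # (3,), applied after rotation
    conformation: Conformation
    rmsd: float                # Å, over the alignment selection


def superpose(
    mobile: Conformation,
    reference: Conformation,
    selection: Sequence[str] | None = None,
) -> SuperposeResult:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    The proper rotation and translation minimizing the weighted RMSD over
    ``selection`` (Kabsch) are found and applied to *all* atoms of
    ``mobile``.  Transformed coordinates are ``R @ (x - com_mob) + com_ref``.
    """
    idx_m = mobile.indices(selection)
    idx_r = reference.indices(selection)
    a = mobile.coords[idx_m]
    b = reference.coords[idx_r]
    if a.shape[0] != b.shape[0]:
        raise SelectionError("selection sizes differ between conformations")
    w = mobile.weights[idx_m] if mobile.weights is not None else np.ones(len(idx_m))
    w = w / w.sum()

    com_a = w @ a
    com_b = w @ b
    ac, bc = a - com_a, b - com_b
    # rank < 2 after centering ⇒ collinear (or single/duplicate) points
    if len(idx_m) < 3 or np.linalg.matrix_rank(ac, tol=1e-8) < 2:
        raise DegenerateAlignmentError(
            "need at least 3 non-collinear atoms for a unique rotation"
        )
    rot, _ = Rotation.align_vectors(bc, ac, weights=w)
    R = rot.as_matrix()
    aligned = (mobile.coords - com_a) @ R.T + com_b
    rmsd = float(np.sqrt(np.sum(w[:, None] * (aligned[idx_m] - b) ** 2)))
    out = Conformation(mobile.atom_labels, aligned, mobile.weights)
    return SuperposeResult(R, com_b - R @ com_a, out, rmsd)


def msd(
    a: Conformation,
    b: Conformation,
    align_selection: Sequence[str] | None = None,
    path_selection: Sequence[str] | None = None,
) -> float:
    """Mean-square deviation (Å²) of ``a`` from ``b`` over ``path_selection``.

    If ``align_selection`` is given, ``a`` is first optimally superposed onto
    ``b`` on those atoms; pass None to compare raw coordinates.
    """
    if path_selection is not None and len(path_selection) == 0:
        raise SelectionError("empty path_selection")
    if align_selection is not None:
        a = superpose(a, b, align_selection).conformation
    ia = a.indices(path_selection)
    ib = b.indices(path_selection)
    d = a.coords[ia] - b.coords[ib]
    return float(np.mean(np.sum(d * d, axis=1)))


@dataclass(frozen=True)
class ReferencePath:
    """Ordered waypoints with selections, λ and padding bookkeeping.

    ``align_selection`` (possibly None for toy systems whose frames cannot be
    superposed) is used to superpose an instantaneous conformation onto each
    waypoint; ``path_selection`` (None = all atoms) enters the MSD.
    ``n_padded_head``/``n_padded_tail`` count fictitious endpoint frames that
    are excluded from the S-normalization by default.
    """

    waypoints: tuple[Conformation, ...]
    align_selection: tuple[str, ...] | None = None
    path_selection: tuple[str, ...] | None = None
    lambda_: float | None = None
    n_padded_head: int = 0
    n_padded_tail: int = 0

    def __post_init__(self) -> None:
        wp = tuple(self.waypoints)
        if len(wp) < 2:
            raise ValueError("a reference path needs at least 2 waypoints")
        labels = {f.atom_labels for f in wp}
        if len(labels) > 1:
            raise ValueError("all waypoints must share atom_labels")
        if self.lambda_ is not None and not self.lambda_ > 0:
            raise ValueError("lambda_ must be positive")
        if self.n_padded_head < 0 or self.n_padded_tail < 0:
            raise ValueError("padding counts must be non-negative")
        if self.n_padded_head + self.n_padded_tail > len(wp) - 2:
            raise ValueError("padding exceeds number of waypoints")
        object.__setattr__(self, "waypoints", wp)
        if self.align_selection is not None:
            object.__setattr__(self, "align_selection", tuple(self.align_selection))
        if self.path_selection is not None:
            object.__setattr__(self, "path_selection", tuple(self.path_selection))

    @property
    def p(self) -> int:
        """Total number of waypoints, padded frames included."""
        return len(self.waypoints)

    @property
    def n_physical(self) -> int:
        return self.p - self.n_padded_head - self.n_padded_tail

    def physical_node_s(self) -> np.ndarray:
        """Normalized S of the physical waypoints: 0 (bound) … 1 (unbound)."""
        return np.linspace(0.0, 1.0, self.n_physical)

    def consecutive_msds(self, aligned: bool = True) -> np.ndarray:
        """MSD between each pair of consecutive waypoints (Å²)."""
        sel = self.align_selection if aligned else None
        return np.array(
            [
                msd(self.waypoints[i], self.waypoints[i + 1], sel, self.path_selection)
                for i in range(self.p - 1)
            ]
        )

    def with_lambda(self, convention: str = "printed") -> "ReferencePath":
        return replace(self, lambda_=compute_lambda(self, convention))


def compute_lambda(path: ReferencePath, convention: str = "printed") -> float:
    """Calibrate the PCV smoothness parameter λ (Å⁻²) from waypoint spacing.

    ``printed`` convention: λ = 2.3 p / Σᵢ MSD(xᵢ, xᵢ₊₁) over the p−1 gaps.
    ``mean-gap`` convention: λ = 2.3 / ⟨MSD⟩ = 2.3 (p−1) / Σ MSD, the common
    choice in the path-CV literature.  Both place λ·gap ≈ 2.3 so that
    neighbouring waypoints overlap but remain distinguishable.
    """
    gaps = path.consecutive_msds()
    if np.any(gaps <= 0):
        bad = int(np.argmin(gaps))
        raise ValueError(f"zero consecutive MSD at waypoint {bad} (duplicate?)")
    total = float(gaps.sum())
    if convention == "printed":
        return 2.3 * path.p / total
    if convention == "mean-gap":
        return 2.3 / float(gaps.mean())
    raise ValueError(f"unknown lambda convention {convention!r}")


def _align_chain(path: ReferencePath) -> list[np.ndarray]:
    """Waypoint coordinates after aligning each frame onto its predecessor."""
    if path.align_selection is None:
        return [w.coords.copy() for w in path.waypoints]
    out = [path.waypoints[0].coords.copy()]
    prev = path.waypoints[0]
    for w in path.waypoints[1:]:
        res = superpose(w, prev, path.align_selection)
        out.append(res.conformation.coords)
        prev = res.conformation
    return out


def reparametrize_equidistant(
    path: ReferencePath,
    n_out: int,
    tol: float = 0.01,
    max_iter: int = 200,
) -> ReferencePath:
    """Resample a path to ``n_out`` waypoints equidistant in MSD.

    Waypoints are placed on the piecewise-linear interpolant of the input in
    aligned coordinate space, with RMS distance (√MSD over the path
    selection) as the arc-length metric.  The common chord length is found
    by bisection over an exact equal-chord walk along the polyline, so the
    result has equal consecutive MSDs up to the bisection tolerance;
    endpoints are preserved exactly.  ``max_iter`` bounds the bisection.
    """
    if n_out < 2:
        raise ValueError("n_out must be at least 2")
    if not tol > 0:
        raise ValueError("tol must be positive")
    template = path.waypoints[0]
    aligned = _align_chain(path)
    sel_idx = template.indices(path.path_selection)
    n_sel = len(sel_idx)

    full = np.stack([c.reshape(-1) for c in aligned])           # (p, 3N)
    metric = np.stack([c[sel_idx].reshape(-1) for c in aligned]) / np.sqrt(n_sel)

    seg = np.linalg.norm(np.diff(metric, axis=0), axis=1)
    if np.any(seg <= 0):
        raise ValueError("duplicate consecutive waypoints in input path")
    arc = np.concatenate([[0.0], np.cumsum(seg)])               # RMS arc length
    total = float(arc[-1])

    # bisect the chord length: longer chords finish the walk further along
    lo, hi = total / (n_out - 1) / 4.0, total
    t = np.linspace(0.0, total, n_out)
    for _ in range(max_iter):
        c = 0.5 * (lo + hi)
        params = _chord_walk(metric, arc, c, n_out - 1)
        if params is None:          # ran off the end: chord too long
            hi = c
            continue
        if params[-1] < total:      # stopped short: chord too short
            lo, t = c, params
        else:
            hi, t = c, params
        if (hi - lo) / total < 1e-14:
            break
    t[0], t[-1] = 0.0, total

    def cv_of(tt: np.ndarray) -> float:
        pts = _interp_rows(tt, arc, metric)
        m = np.sum(np.diff(pts, axis=0) ** 2, axis=1)
        return float(np.std(m) / np.mean(m))

    cv = cv_of(t)
    if cv > tol:
        # strong curvature makes the greedy walk discontinuous in the chord
        # length; polish the arc positions by least squares on the chord MSDs
        # (walk result and equal-arc positions as starts, keep the best)
        candidates = [
            _polish_equal_msd(t, arc, metric),
            _polish_equal_msd(np.linspace(0.0, total, n_out), arc, metric),
        ]
        t = min(candidates, key=cv_of)
        cv = cv_of(t)
    if cv > tol:
        raise RuntimeError(
            f"equidistant reparametrization did not reach CV ≤ {tol} "
            f"(achieved CV = {cv:.3g})"
        )

    new_full = _interp_rows(t, arc, full)
    new_full[0] = full[0]
    new_full[-1] = full[-1]
    waypoints = tuple(
        Conformation(template.atom_labels, row.reshape(-1, 3), template.weights)
        for row in new_full
    )
    return ReferencePath(
        waypoints,
        align_selection=path.align_selection,
        path_selection=path.path_selection,
        lambda_=None,
        n_padded_head=0,
        n_padded_tail=0,
    )


def _chord_walk(
    metric: np.ndarray,
    arc: np.ndarray,
    c: float,
    n_chords: int,
) -> np.ndarray | None:
    """Arc parameters after walking ``n_chords`` chords of length ``c``.

    Starting at the first vertex, each step moves to the first point further
    along the polyline at Euclidean distance ``c`` from the current point
    (sphere–segment intersection, smallest forward root).  Returns None if
    the polyline ends before all chords are placed.
    """
    n_seg = len(metric) - 1
    params = np.empty(n_chords + 1)
    params[0] = 0.0
    t = 0.0
    k = 0
    P = metric[0].copy()
    for step in range(n_chords):
        placed = False
        kk = k
        while kk < n_seg:
            A, B = metric[kk], metric[kk + 1]
            d = B - A
            seg_len = arc[kk + 1] - arc[kk]
            u0 = (t - arc[kk]) / seg_len if kk == k else 0.0
            f = A - P
            a2 = float(d @ d)
            b2 = 2.0 * float(f @ d)
            c2 = float(f @ f) - c * c
            disc = b2 * b2 - 4.0 * a2 * c2
            if disc >= 0.0 and a2 > 0.0:
                sq = np.sqrt(disc)
                roots = [(-b2 - sq) / (2 * a2), (-b2 + sq) / (2 * a2)]
                valid = [u for u in roots if u0 - 1e-12 <= u <= 1.0 + 1e-12]
                if valid:
                    u = float(np.clip(min(valid), u0, 1.0))
                    t = arc[kk] + u * seg_len
                    P = A + u * d
                    k = kk
                    params[step + 1] = t
                    placed = True
                    break
            kk += 1
        if not placed:
            return None
    return params


def _polish_equal_msd(t: np.ndarray, arc: np.ndarray, metric: np.ndarray) -> np.ndarray:
    """Equalize chord MSDs by least squares over monotone arc positions.

    Arc increments are parametrized as a softmax of free variables, which
    keeps the positions ordered and the endpoints pinned; residuals are the
    relative deviations of the chord MSDs from their mean.
    """
    from scipy.optimize import least_squares

    total = float(arc[-1])
    inc = np.clip(np.diff(t), 1e-12 * total, None)
    theta0 = np.log(inc)

    def to_t(theta: np.ndarray) -> np.ndarray:
        w = np.exp(theta - theta.max())
        return np.concatenate([[0.0], np.cumsum(w)]) / w.sum() * total

    def resid(theta: np.ndarray) -> np.ndarray:
        pts = _interp_rows(to_t(theta), arc, metric)
        m = np.sum(np.diff(pts, axis=0) ** 2, axis=1)
        return (m - m.mean()) / m.mean()

    sol = least_squares(resid, theta0, xtol=1e-14, ftol=1e-14, gtol=1e-14,
                        max_nfev=500 * len(theta0))
    return to_t(sol.x)


def _interp_rows(t: np.ndarray, x: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Linear interpolation of each column of ``rows`` (shape (len(x), d))."""
    idx = np.clip(np.searchsorted(x, t, side="right") - 1, 0, len(x) - 2)
    x0, x1 = x[idx], x[idx + 1]
    frac = np.where(x1 > x0, (t - x0) / np.where(x1 > x0, x1 - x0, 1.0), 0.0)
    return rows[idx] + frac[:, None] * (rows[idx + 1] - rows[idx])


def rmsf(
    traj: Trajectory,
    grouping: Mapping[str, Sequence[str]] | None = None,
    align_selection: Sequence[str] | None = None,
    max_iter: int = 10,
    align_tol: float = 1e-8,
) -> dict[str, float]:
    """Root-mean-square fluctuation per atom group (Å).

    Frames are iteratively superposed onto their evolving mean structure on
    ``align_selection`` (skip superposition with None, e.g. for toy frames).
    The RMSF of a group is the RMS deviation from the mean position over all
    its atoms and frames.  ``grouping`` maps group name → atom labels
    (default: one group per atom).
    """
    if len(traj) < 2:
        raise ValueError("RMSF needs at least 2 frames")
    template = traj.frames[0]
    coords = traj.coords_array().copy()

    if align_selection is not None:
        for _ in range(max_iter):
            mean = coords.mean(axis=0)
            ref = Conformation(template.atom_labels, mean)
            new = np.empty_like(coords)
            for i in range(coords.shape[0]):
                mob = Conformation(template.atom_labels, coords[i])
                new[i] = superpose(mob, ref, align_selection).conformation.coords
            shift = float(np.max(np.abs(new - coords)))
            coords = new
            if shift < align_tol:
                break

    mean = coords.mean(axis=0)
    sq = np.sum((coords - mean) ** 2, axis=2)       # (frames, atoms)
    if grouping is None:
        grouping = {lab: [lab] for lab in template.atom_labels}
    out: dict[str, float] = {}
    for name, labels in grouping.items():
        idx = template.indices(labels)
        out[name] = float(np.sqrt(np.mean(sq[:, idx])))
    return out


def rmsf_select(
    traj: Trajectory,
    threshold: float,
    grouping: Mapping[str, Sequence[str]] | None = None,
    align_selection: Sequence[str] | None = None,
) -> list[str]:
    """Groups whose RMSF is strictly below ``threshold`` (Å).

    Mirrors the selection of rigid residues (e.g. RMSF < 1.8 Å) used to
    choose alignment atoms for flexible receptors.
    """
    values = rmsf(traj, grouping=grouping, align_selection=align_selection)
    return [name for name, v in values.items() if v < threshold]


def pad_endpoints(
    path: ReferencePath,
    n_extra: int,
    step_scale: float = 1.0,
) -> ReferencePath:
    """Add fictitious configurations at both path ends by linear extrapolation.

    Each added head frame steps by ``step_scale × (w₀ − w₁)`` beyond the
    first waypoint (and symmetrically at the tail), so the terminal gap MSD
    scales as ``step_scale²`` times the original.  Padded frames are counted
    in ``n_padded_head/tail`` and excluded from S-normalization by default:
    the physical endpoints keep S = 0 and S = 1, the padding only improves
    sampling of the true bound and unbound states.
    """
    if n_extra < 0:
        raise ValueError("n_extra must be non-negative")
    if n_extra == 0:
        return path
    wp = list(path.waypoints)
    labels = wp[0].atom_labels
    head_step = (wp[0].coords - wp[1].coords) * step_scale
    tail_step = (wp[-1].coords - wp[-2].coords) * step_scale
    head = [
        Conformation(labels, wp[0].coords + k * head_step, wp[0].weights)
        for k in range(n_extra, 0, -1)
    ]
    tail = [
        Conformation(labels, wp[-1].coords + k * tail_step, wp[-1].weights)
        for k in range(1, n_extra + 1)
    ]
    return replace(
        path,
        waypoints=tuple(head + wp + tail),
        lambda_=None,
        n_padded_head=path.n_padded_head + n_extra,
        n_padded_tail=path.n_padded_tail + n_extra,
    )
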