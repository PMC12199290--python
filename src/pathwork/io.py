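"""File formats: COLVAR-style tables, hills/FES tables, multi-frame XYZ and
multi-model PDB.

All table writers emit a format-version line (``# pathwork <kind> 1``)
followed by a ``#! FIELDS ...`` header naming the columns; readers accept
only declared versions and resolve columns by name, so column order is
free.  Multi-frame XYZ is the lossless carrier for toy and path frames
(arbitrary atom labels live in the symbol column); multi-model PDB
(MODEL/ENDMDL) is supported for interchange with structure tools via
biotite.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .path_model import Conformation, ReferencePath, Trajectory

FORMAT_VERSION = 1
_KINDS = ("colvar", "hills", "fes")


class FormatError(ValueError):
    """A file does not conform to a declared pathwork format."""


# ---------------------------------------------------------------------------
# whitespace tables

def write_table(
    path: str | Path,
    columns: Mapping[str, np.ndarray],
    kind: str = "colvar",
) -> None:
    """Write named columns as a whitespace table with version header."""
    if kind not in _KINDS:
        raise ValueError(f"unknown table kind {kind!r}")
    names = list(columns)
    arrs = [np.asarray(columns[n], dtype=float) for n in names]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("all columns must have equal length")
    with open(path, "w") as fh:
        fh.write(f"# pathwork {kind} {FORMAT_VERSION}\n")
        fh.write("#! FIELDS " + " ".join(names) + "\n")
        for i in range(n):
            fh.write(" ".join(format(a[i], ".17g") for a in arrs) + "\n")


def read_table(
    path: str | Path,
    kind: str = "colvar",
    required: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read a pathwork table; columns resolved by header name."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    head = lines[0].strip().split()
    if head[:2] != ["#", "pathwork"] or len(head) != 4:
        raise FormatError(f"{path}:1: missing '# pathwork <kind> <version>' line")
    if head[2] != kind:
        raise FormatError(f"{path}:1: expected kind {kind!r}, found {head[2]!r}")
    if head[3] != str(FORMAT_VERSION):
        raise FormatError(f"{path}:1: unsupported format version {head[3]}")
    fields_line = lines[1].strip()
    if not fields_line.startswith("#! FIELDS"):
        raise FormatError(f"{path}:2: missing '#! FIELDS' header")
    names = fields_line.split()[2:]
    if not names:
        raise FormatError(f"{path}:2: no column names in FIELDS header")
    data_lines = []
    for lineno, line in enumerate(lines[2:], start=3):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        vals = s.split()
        if len(vals) != len(names):
            raise FormatError(
                f"{path}:{lineno}: expected {len(names)} values, got {len(vals)}"
            )
        data_lines.append((lineno, [float(v) for v in vals]))
    df = pd.DataFrame([v for _, v in data_lines], columns=names)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
    if "time" in df.columns and len(df) > 1:
        dt = np.diff(df["time"].to_numpy())
        bad = np.nonzero(dt <= 0)[0]
        if len(bad):
            lineno = data_lines[int(bad[0]) + 1][0]
            raise FormatError(
                f"{path}:{lineno}: time not strictly increasing"
            )
    return df


def write_colvar(path: str | Path, columns: Mapping[str, np.ndarray]) -> None:
    """COLVAR-style table (time plus CV/work columns)."""
    if "time" not in columns:
        raise ValueError("a colvar table needs a 'time' column")
    write_table(path, columns, kind="colvar")


def read_colvar(path: str | Path, required: Sequence[str] | None = None) -> pd.DataFrame:
    req = list(required) if required else []
    if "time" not in req:
        req = ["time", *req]
    return read_table(path, kind="colvar", required=req)


def write_fes(path: str | Path, s, F, stderr) -> None:
    write_table(path, {"s": s, "F": F, "stderr": stderr}, kind="fes")


def read_fes(path: str | Path) -> pd.DataFrame:
    return read_table(path, kind="fes", required=["s", "F", "stderr"])


def write_hills(path: str | Path, hills) -> None:
    """Hills table: time, center_s, center_z, sigma_s, sigma_z, height."""
    n = len(hills.times)
    write_table(
        path,
        {
            "time": hills.times,
            "center_s": hills.centers_s,
            "center_z": hills.centers_z,
            "sigma_s": np.full(n, hills.sigma_s),
            "sigma_z": np.full(n, hills.sigma_z),
            "height": hills.heights,
        },
        kind="hills",
    )


# ---------------------------------------------------------------------------
# multi-frame XYZ

def write_xyz(path: str | Path, frames: Sequence[Conformation], times=None) -> None:
    """Multi-frame XYZ; atom labels are written in the symbol column."""
    with open(path, "w") as fh:
        for i, frame in enumerate(frames):
            fh.write(f"{frame.n_atoms}\n")
            comment = f"pathwork xyz {FORMAT_VERSION} frame {i}"
            if times is not None:
                comment += f" time {times[i]:.17g}"
            fh.write(comment + "\n")
            for lab, (x, y, z) in zip(frame.atom_labels, frame.coords):
                fh.write(f"{lab} {x:.10f} {y:.10f} {z:.10f}\n")


def read_xyz(path: str | Path) -> tuple[list[Conformation], list[float] | None]:
    path = Path(path)
    frames: list[Conformation] = []
    times: list[float] = []
    have_times = True
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"{path}:{i + 1}: expected atom count") from None
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        toks = comment.split()
        if "time" in toks:
            times.append(float(toks[toks.index("time") + 1]))
        else:
            have_times = False
        labels, coords = [], []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{i + 3 + j}: malformed atom line")
            labels.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        frames.append(Conformation(tuple(labels), np.array(coords)))
        i += 2 + n
    if not frames:
        raise FormatError(f"{path}: no frames found")
    return frames, (times if have_times and len(times) == len(frames) else None)


# ---------------------------------------------------------------------------
# multi-model PDB

def _pdb_labels(names: Sequence[str], res_ids: Sequence[int]) -> tuple[str, ...]:
    labels = [f"{n}_{r}" for n, r in zip(names, res_ids)]
    if len(set(labels)) != len(labels):
        labels = [f"{lab}_{i}" for i, lab in enumerate(labels)]
    return tuple(labels)


def read_pdb_frames(path: str | Path) -> list[Conformation]:
    """All models of a PDB file, validated for identical atom order."""
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    ref_names = None
    ref_res = None
    frames = []
    for m in range(1, n_models + 1):
        atoms = pdb.get_structure(model=m)
        names = list(atoms.atom_name)
        res_ids = list(atoms.res_id)
        if m == 1:
            ref_names, ref_res = names, res_ids
            labels = _pdb_labels(names, res_ids)
        elif names != ref_names or res_ids != ref_res:
            raise FormatError(
                f"{path}: model {m} has different atom count or order "
                f"than model 1"
            )
        frames.append(Conformation(labels, np.asarray(atoms.coord, dtype=float)))
    return frames


def write_pdb_frames(path: str | Path, frames: Sequence[Conformation]) -> None:
    """Write conformations as a multi-model PDB (labels → atom names)."""
    template = frames[0]
    n = template.n_atoms
    arrays = []
    for frame in frames:
        atoms = bst.AtomArray(n)
        atoms.coord = np.asarray(frame.coords, dtype=np.float32)
        atoms.atom_name = np.array(
            [lab.split("_")[0][:4] for lab in template.atom_labels]
        )
        atoms.res_name = np.full(n, "PTH")
        atoms.res_id = np.arange(1, n + 1)
        atoms.chain_id = np.full(n, "A")
        atoms.element = np.array(
            [lab[0].upper() if lab[0].isalpha() else "C" for lab in template.atom_labels]
        )
        arrays.append(atoms)
    stack = bst.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# frame containers

def read_path_frames(
    path: str | Path,
    kind: str = "path",
    align_selection: Sequence[str] | None = None,
    path_selection: Sequence[str] | None = None,
) -> ReferencePath | Trajectory:
    """Load a multi-model PDB or multi-frame XYZ as a path or trajectory."""
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        frames, times = read_pdb_frames(path), None
    else:
        frames, times = read_xyz(path)
    if kind == "path":
        return ReferencePath(
            tuple(frames),
            align_selection=tuple(align_selection) if align_selection else None,
            path_selection=tuple(path_selection) if path_selection else None,
        )
    if kind == "trajectory":
        if len(frames) == 1:
            warnings.warn(f"{path}: single-model file loaded as 1-frame trajectory")
        t = np.asarray(times, dtype=float) if times else np.arange(len(frames), dtype=float)
        return Trajectory(tuple(frames), t)
    raise ValueError("kind must be 'path' or 'trajectory'")


def write_path_frames(path: str | Path, frames: Sequence[Conformation], times=None) -> None:
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        write_pdb_frames(path, frames)
    else:
        write_xyz(path, frames, times=times)
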