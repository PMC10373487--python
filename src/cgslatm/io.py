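"""Trajectory ingestion, local-environment extraction and frame selection.

Coordinates are stored internally in Angstrom.  Standard MD formats
(GRO/PDB topologies with XTC/TRR/DCD frames) are read through MDAnalysis,
which already reports positions in Angstrom.  A self-contained multi-frame
extended-XYZ dialect is supported for fixtures and synthetic data; its
header line must carry an explicit ``unit=`` flag plus the solute index
ranges, e.g.::

    5
    unit=angstrom solute=0-1,4 box=30.0,30.0,30.0
    T1 0.0 0.0 0.0
    ...

Periodic boundaries follow the minimum-image convention for orthorhombic
boxes; configurations without a box use open boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .registry import BeadTypeRegistry

__all__ = [
    "Configuration",
    "TrajectoryEnsemble",
    "load_trajectory",
    "read_xyz",
    "write_xyz",
    "extract_local_environment",
    "select_frames",
    "depth_scores",
]

DEFAULT_SHELL_RADIUS = 11.0  # Angstrom; 1.1 nm local-environment truncation


@dataclass
class Configuration:
    """A single frame: bead positions (Angstrom), types and solute flags."""

    positions: np.ndarray
    types: np.ndarray
    solute_flags: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.types = np.asarray(self.types, dtype=object)
        self.solute_flags = np.asarray(self.solute_flags, dtype=bool)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        n = len(self.positions)
        if len(self.types) != n or len(self.solute_flags) != n:
            raise ValueError("positions/types/solute_flags length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if not np.all(self.box > 0):
                raise ValueError("box lengths must be positive")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def solute_indices(self) -> np.ndarray:
        return np.flatnonzero(self.solute_flags)


@dataclass
class TrajectoryEnsemble:
    """Ordered frames sharing bead count and types."""

    frames: list[Configuration]
    frame_indices: np.ndarray = field(default=None)  # type: ignore[assignment]
    length_unit_source: str = "angstrom"

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory has no frames")
        if self.frame_indices is None:
            self.frame_indices = np.arange(len(self.frames))
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if len(self.frame_indices) != len(self.frames):
            raise ValueError("frame_indices length mismatch")
        # the solute must be the same beads in every frame; the environment
        # may differ per frame (truncated shells, i.i.d. ensembles)
        first = self.frames[0]
        ref = tuple(first.types[first.solute_indices])
        for f in self.frames[1:]:
            if tuple(f.types[f.solute_indices]) != ref:
                raise ValueError("solute beads differ across frames")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# Extended-XYZ dialect
# ---------------------------------------------------------------------------


def _parse_ranges(spec: str) -> list[int]:
    out: list[int] = []
    for part in spec.split(","):
        if "-" in part:
            lo, hi = part.split("-")
            out.extend(range(int(lo), int(hi) + 1))
        else:
            out.append(int(part))
    return out


def _format_ranges(indices: np.ndarray) -> str:
    idx = sorted(int(i) for i in indices)
    parts = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i == prev + 1:
            prev = i
            continue
        parts.append(f"{start}-{prev}" if prev > start else f"{start}")
        start = prev = i
    parts.append(f"{start}-{prev}" if prev > start else f"{start}")
    return ",".join(parts)


def read_xyz(path, name_map: dict[str, str] | None = None) -> TrajectoryEnsemble:
    """Read the multi-frame extended-XYZ dialect.

    Header comment line tokens: ``unit=nm|angstrom`` (required),
    ``solute=<index ranges>`` (required), ``box=Lx,Ly,Lz`` (optional, in the
    declared unit).
    """
    frames: list[Configuration] = []
    unit = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos].strip())
        header = lines[pos + 1].strip()
        tokens = dict(
            tok.split("=", 1) for tok in header.split() if "=" in tok
        )
        if "unit" not in tokens:
            raise ValueError(
                f"{path}: header line lacks the required unit= flag"
            )
        unit = tokens["unit"].lower()
        if unit not in ("nm", "angstrom", "a", "ang"):
            raise ValueError(f"{path}: unknown unit {unit!r}")
        scale = 10.0 if unit == "nm" else 1.0
        if "solute" not in tokens:
            raise ValueError(f"{path}: header line lacks solute= ranges")
        solute = _parse_ranges(tokens["solute"])
        box = None
        if "box" in tokens:
            box = np.array([float(x) for x in tokens["box"].split(",")]) * scale
        types = []
        coords = np.empty((n, 3))
        for i in range(n):
            cols = lines[pos + 2 + i].split()
            name = cols[0]
            types.append(name_map.get(name, name) if name_map else name)
            coords[i] = [float(c) for c in cols[1:4]]
        flags = np.zeros(n, dtype=bool)
        flags[solute] = True
        frames.append(
            Configuration(coords * scale, np.array(types, dtype=object), flags, box)
        )
        pos += 2 + n
    source = "nm" if unit == "nm" else "angstrom"
    return TrajectoryEnsemble(frames, length_unit_source=source)


def write_xyz(path, traj: TrajectoryEnsemble | Configuration) -> None:
    """Write frames in the extended-XYZ dialect (always in Angstrom)."""
    frames = traj.frames if isinstance(traj, TrajectoryEnsemble) else [traj]
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{frame.n_beads}\n")
            header = f"unit=angstrom solute={_format_ranges(frame.solute_indices)}"
            if frame.box is not None:
                header += " box=" + ",".join(f"{b:.10g}" for b in frame.box)
            fh.write(header + "\n")
            for t, p in zip(frame.types, frame.positions):
                fh.write(f"{t} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}\n")


# ---------------------------------------------------------------------------
# MD formats via MDAnalysis
# ---------------------------------------------------------------------------


def load_trajectory(
    topology_path,
    trajectory_path=None,
    registry: BeadTypeRegistry | None = None,
    name_map: dict[str, str] | None = None,
    solute_selection=None,
) -> TrajectoryEnsemble:
    """Load a trajectory into an in-memory ensemble (coordinates in Angstrom).

    ``topology_path`` may be a GRO/PDB file (frames then come from
    ``trajectory_path``: XTC/TRR/DCD, or the topology's own coordinates) or
    an extended-XYZ dialect file (self-contained; ``trajectory_path`` must
    then be None).  Bead names are mapped to registered types through
    ``name_map`` (identity by default); unmapped names raise with the list
    of offenders.  ``solute_selection`` is an MDAnalysis selection string or
    an explicit index list; the XYZ dialect carries its own solute flags.
    """
    top = str(topology_path)
    if top.endswith(".xyz"):
        if trajectory_path is not None:
            raise ValueError("extended-XYZ files are self-contained")
        traj = read_xyz(top, name_map=name_map)
        _check_types_registered(traj.frames[0].types, registry)
        return traj

    import MDAnalysis as mda

    if trajectory_path is None:
        u = mda.Universe(top)
    else:
        u = mda.Universe(top, str(trajectory_path))
    names = [a.name for a in u.atoms]
    name_map = name_map or {}
    types = np.array([name_map.get(n, n) for n in names], dtype=object)
    _check_types_registered(types, registry, raw_names=names, name_map=name_map)

    if solute_selection is None:
        raise ValueError("solute_selection is required for MD formats")
    if isinstance(solute_selection, str):
        sol_idx = u.select_atoms(solute_selection).indices
    else:
        sol_idx = np.asarray(list(solute_selection), dtype=int)
    if len(sol_idx) == 0:
        raise ValueError("solute selection matched no beads")
    flags = np.zeros(len(u.atoms), dtype=bool)
    flags[sol_idx] = True

    frames = []
    for ts in u.trajectory:
        box = None
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            angles = ts.dimensions[3:]
            if not np.allclose(angles, 90.0, atol=1e-3):
                raise ValueError("only orthorhombic boxes are supported")
            box = np.array(ts.dimensions[:3], dtype=float)
        frames.append(
            Configuration(ts.positions.astype(float).copy(), types, flags, box)
        )
    return TrajectoryEnsemble(frames, length_unit_source="angstrom")


def _check_types_registered(types, registry, raw_names=None, name_map=None):
    if registry is None:
        return
    missing = sorted({t for t in types if t not in registry})
    if missing:
        raise ValueError(
            f"bead names map to unregistered types: {missing}; "
            "extend the registry or the name map"
        )


# ---------------------------------------------------------------------------
# Local environment and frame selection
# ---------------------------------------------------------------------------


def _min_image(disp: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return disp
    return disp - box * np.round(disp / box)


def extract_local_environment(
    frame: Configuration, radius: float = DEFAULT_SHELL_RADIUS
) -> Configuration:
    """Recenter on the solute centroid and truncate to a radial shell.

    The solute is first made whole under the minimum-image convention (when
    a box is present), coordinates are recentered on its centroid, and every
    non-solute bead whose minimum-image distance to the nearest solute bead
    exceeds ``radius`` is discarded (inclusive boundary).  The returned
    configuration is boxless: with the default 11 A shell far below typical
    box lengths, periodic images are irrelevant after truncation.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    sol = frame.solute_indices
    if len(sol) == 0:
        raise ValueError("frame has no solute beads")
    pos = frame.positions
    box = frame.box

    # unwrap the solute relative to its first bead, then recenter everything
    anchor = pos[sol[0]]
    sol_rel = _min_image(pos[sol] - anchor, box)
    centroid = anchor + sol_rel.mean(axis=0)
    rel = _min_image(pos - centroid, box)
    sol_pos = rel[sol]

    # minimum-image distance from every bead to its nearest solute bead
    d = rel[:, None, :] - sol_pos[None, :, :]
    d = _min_image(d, box)
    dmin = np.sqrt((d**2).sum(axis=2)).min(axis=1)

    keep = frame.solute_flags | (dmin <= radius)
    return Configuration(
        rel[keep], frame.types[keep], frame.solute_flags[keep], box=None
    )


def select_frames(
    traj: TrajectoryEnsemble, frame_scores, k: int
) -> TrajectoryEnsemble:
    """Keep the ``k`` frames with the smallest score.

    Scores are caller-supplied (e.g. distance of the solute to a target
    insertion depth).  Ties break toward the earlier frame index and the
    original frame order is preserved among kept frames.
    """
    scores = np.asarray(frame_scores, dtype=float)
    if len(scores) != traj.n_frames:
        raise ValueError("one score per frame required")
    if not 0 < k <= traj.n_frames:
        raise ValueError(f"k={k} outside 1..{traj.n_frames}")
    order = np.argsort(scores, kind="stable")[:k]
    kept = np.sort(order)
    return TrajectoryEnsemble(
        [traj.frames[i] for i in kept],
        frame_indices=traj.frame_indices[kept],
        length_unit_source=traj.length_unit_source,
    )


def depth_scores(traj: TrajectoryEnsemble, plane_z: float) -> np.ndarray:
    """|z-distance of the solute centroid to a reference plane| per frame.

    Convenience score for :func:`select_frames` when frames should cluster
    around a target insertion depth.
    """
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        sol = frame.solute_indices
        if len(sol) == 0:
            raise ValueError("frame has no solute beads")
        out[i] = abs(frame.positions[sol, 2].mean() - plane_z)
    return out
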