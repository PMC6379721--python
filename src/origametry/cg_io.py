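"""Core data model and readers/writers for oxDNA-style text files.

Files store lengths in oxDNA simulation units; everything in memory is in
nanometres.  The conversion constant (0.8518 nm per unit) is applied only
here, on read and write.

Topology files follow the classic convention::

    N_nucleotides N_strands
    strand base 3'-neighbour 5'-neighbour      (one line per nucleotide, -1 = none)

Configuration/trajectory files hold one or more frames::

    t = <time>
    b = Lx Ly Lz
    E = Etot U K
    rx ry rz  a1x a1y a1z  a3x a3y a3z  vx vy vz  Lx Ly Lz   (per nucleotide)

Both header orders (``t``/``b``/``E`` in any order before the first
nucleotide line) are tolerated on read; writing uses the classic order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParseError, ValidationError
from .geometry import BASE_SITE_OFFSET_NM, OXDNA_LENGTH_UNIT_NM

__all__ = [
    "Topology",
    "Frame",
    "Trajectory",
    "BasePairMap",
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory",
    "detect_base_pairs",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class Topology:
    """Strand membership, base identity and backbone connectivity.

    Indices are 0-based and follow file order.  ``strand_ids`` are 1-based
    as in the file format.  Neighbour arrays hold -1 for "no neighbour".
    """

    strand_ids: np.ndarray
    bases: np.ndarray
    neighbor_3p: np.ndarray
    neighbor_5p: np.ndarray
    circular_strands: frozenset = frozenset()

    def __post_init__(self):
        self.strand_ids = np.asarray(self.strand_ids, dtype=int)
        self.bases = np.asarray(self.bases, dtype="<U1")
        self.neighbor_3p = np.asarray(self.neighbor_3p, dtype=int)
        self.neighbor_5p = np.asarray(self.neighbor_5p, dtype=int)

    @property
    def n_nucleotides(self) -> int:
        return int(self.strand_ids.size)

    @property
    def n_strands(self) -> int:
        return int(np.unique(self.strand_ids).size)

    def validate(self) -> None:
        """Check mutual consistency of the neighbour links."""
        n = self.n_nucleotides
        for arr, name in ((self.neighbor_3p, "3'"), (self.neighbor_5p, "5'")):
            bad = (arr < -1) | (arr >= n)
            if np.any(bad):
                raise ValidationError(
                    f"{name} neighbour index out of range at nucleotides "
                    f"{np.nonzero(bad)[0].tolist()}"
                )
        for i in range(n):
            j = self.neighbor_3p[i]
            if j >= 0 and self.neighbor_5p[j] != i:
                raise ValidationError(
                    f"inconsistent neighbour links: {i}'s 3' neighbour is {j} "
                    f"but {j}'s 5' neighbour is {self.neighbor_5p[j]}"
                )
            j = self.neighbor_5p[i]
            if j >= 0 and self.neighbor_3p[j] != i:
                raise ValidationError(
                    f"inconsistent neighbour links: {i}'s 5' neighbour is {j} "
                    f"but {j}'s 3' neighbour is {self.neighbor_3p[j]}"
                )
            for j in (self.neighbor_3p[i], self.neighbor_5p[i]):
                if j >= 0 and self.strand_ids[j] != self.strand_ids[i]:
                    raise ValidationError(
                        f"neighbour link crosses strands at nucleotide {i}"
                    )

    def strand_nucleotides(self, strand_id: int) -> np.ndarray:
        """Indices belonging to one strand, in file order."""
        return np.nonzero(self.strand_ids == strand_id)[0]


@dataclass
class Frame:
    """One configuration: positions (nm) plus orientation versors.

    ``a1`` points from the backbone toward the base face; ``a3`` is the
    stacking/helix-normal direction.  Velocities are carried through I/O
    but never interpreted by the analyses.
    """

    time: float
    box: np.ndarray
    positions: np.ndarray
    a1: np.ndarray
    a3: np.ndarray
    velocities: np.ndarray | None = None
    angular_velocities: np.ndarray | None = None
    energy: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.a1 = np.asarray(self.a1, dtype=float)
        self.a3 = np.asarray(self.a3, dtype=float)
        if self.velocities is None:
            self.velocities = np.zeros_like(self.positions)
        if self.angular_velocities is None:
            self.angular_velocities = np.zeros_like(self.positions)

    @property
    def n_nucleotides(self) -> int:
        return int(self.positions.shape[0])

    def base_sites(self) -> np.ndarray:
        """Base interaction sites: position + offset along a1 (nm)."""
        return self.positions + BASE_SITE_OFFSET_NM * self.a1

    def validate(self, atol_unit: float = 1e-6, atol_ortho: float = 1e-3) -> None:
        if np.any(self.box <= 0):
            raise ValidationError("box components must be positive")
        for name, v in (("a1", self.a1), ("a3", self.a3)):
            norms = np.linalg.norm(v, axis=1)
            if np.any(np.abs(norms - 1.0) > atol_unit):
                raise ValidationError(f"{name} versors are not unit length")
        dots = np.abs(np.einsum("ij,ij->i", self.a1, self.a3))
        if np.any(dots > atol_ortho):
            warnings.warn(
                f"a1·a3 orthogonality violated (max |dot| = {dots.max():.2e})",
                stacklevel=2,
            )

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Frame":
        """Return a rigidly moved copy (rotation applied before translation)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return Frame(
            time=self.time,
            box=self.box.copy(),
            positions=self.positions @ R.T + t,
            a1=self.a1 @ R.T,
            a3=self.a3 @ R.T,
            velocities=self.velocities @ R.T,
            angular_velocities=self.angular_velocities @ R.T,
            energy=self.energy,
        )


@dataclass
class Trajectory:
    """Ordered frames sharing one topology."""

    topology: Topology
    frames: list

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


@dataclass
class BasePairMap:
    """Detected or design-derived base pairs, each index in at most one pair."""

    pairs: list
    provenance: str = "geometry-derived"

    def __post_init__(self):
        norm = []
        seen = set()
        for i, j in self.pairs:
            i, j = (int(i), int(j)) if i < j else (int(j), int(i))
            if i in seen or j in seen:
                raise ValidationError(f"nucleotide appears in two pairs: ({i},{j})")
            seen.add(i)
            seen.add(j)
            norm.append((i, j))
        self.pairs = norm

    def __len__(self):
        return len(self.pairs)

    def partner_of(self, i: int) -> int | None:
        for a, b in self.pairs:
            if a == i:
                return b
            if b == i:
                return a
        return None

    def as_dict(self) -> dict:
        d = {}
        for a, b in self.pairs:
            d[a] = b
            d[b] = a
        return d


# ---------------------------------------------------------------------------
# topology I/O


def read_topology(path) -> Topology:
    path = Path(path)
    lines = path.read_text().splitlines()
    content = [(k, ln) for k, ln in enumerate(lines, start=1) if ln.strip()]
    if not content:
        raise ParseError(f"{path}: empty topology file")
    first_no, first = content[0]
    parts = first.split()
    if len(parts) != 2:
        raise ParseError(f"{path}:{first_no}: expected 'N_nucleotides N_strands'")
    try:
        n_nucl, n_strands = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise ParseError(f"{path}:{first_no}: non-integer counts") from exc

    records = content[1:]
    if len(records) != n_nucl:
        raise ParseError(
            f"{path}: header declares {n_nucl} nucleotides but file has "
            f"{len(records)} record lines"
        )
    strand_ids = np.empty(n_nucl, dtype=int)
    bases = np.empty(n_nucl, dtype="<U1")
    n3 = np.empty(n_nucl, dtype=int)
    n5 = np.empty(n_nucl, dtype=int)
    for i, (lineno, ln) in enumerate(records):
        f = ln.split()
        if len(f) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(f)}")
        try:
            strand_ids[i] = int(f[0])
            n3[i] = int(f[2])
            n5[i] = int(f[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric field") from exc
        bases[i] = f[1].upper()

    # a strand is circular when following 5' links returns to the start
    circular = set()
    for sid in np.unique(strand_ids):
        members = np.nonzero(strand_ids == sid)[0]
        if members.size and np.all(n3[members] >= 0) and np.all(n5[members] >= 0):
            circular.add(int(sid))

    topo = Topology(strand_ids, bases, n3, n5, frozenset(circular))
    if np.unique(strand_ids).size != n_strands:
        raise ParseError(
            f"{path}: header declares {n_strands} strands but records define "
            f"{np.unique(strand_ids).size}"
        )
    topo.validate()
    return topo


def write_topology(path, topology: Topology) -> None:
    topology.validate()
    lines = [f"{topology.n_nucleotides} {topology.n_strands}"]
    for i in range(topology.n_nucleotides):
        lines.append(
            f"{topology.strand_ids[i]} {topology.bases[i]} "
            f"{topology.neighbor_3p[i]} {topology.neighbor_5p[i]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# trajectory I/O


def _parse_frame(header_lines, nucl_lines, n_nucl, frame_index, path):
    time = 0.0
    box = None
    energy = (0.0, 0.0, 0.0)
    for key, rest in header_lines:
        try:
            if key == "t":
                time = float(rest[0])
            elif key == "b":
                box = np.array([float(x) for x in rest[:3]])
            elif key == "E":
                energy = tuple(float(x) for x in rest[:3])
        except (ValueError, IndexError) as exc:
            raise ParseError(
                f"{path}: frame {frame_index}: malformed '{key} =' header"
            ) from exc
    if box is None:
        raise ParseError(f"{path}: frame {frame_index}: missing 'b =' header")
    if len(nucl_lines) != n_nucl:
        raise ParseError(
            f"{path}: frame {frame_index} has {len(nucl_lines)} nucleotide "
            f"lines, expected {n_nucl}"
        )
    data = np.empty((n_nucl, 15))
    for i, ln in enumerate(nucl_lines):
        f = ln.split()
        if len(f) < 15:
            raise ParseError(
                f"{path}: frame {frame_index}, nucleotide {i}: expected 15 "
                f"numbers, got {len(f)}"
            )
        try:
            data[i] = [float(x) for x in f[:15]]
        except ValueError as exc:
            raise ParseError(
                f"{path}: frame {frame_index}, nucleotide {i}: non-numeric token"
            ) from exc
    u = OXDNA_LENGTH_UNIT_NM
    return Frame(
        time=time,
        box=box * u,
        positions=data[:, 0:3] * u,
        a1=data[:, 3:6],
        a3=data[:, 6:9],
        velocities=data[:, 9:12] * u,
        angular_velocities=data[:, 12:15],
        energy=energy,
    )


def read_trajectory(path, topology: Topology) -> Trajectory:
    path = Path(path)
    n_nucl = topology.n_nucleotides
    frames = []
    header: list = []
    nucl: list = []
    started = False

    def flush():
        nonlocal header, nucl
        if not started:
            return
        frames.append(_parse_frame(header, nucl, n_nucl, len(frames), path))
        header, nucl = [], []

    with path.open() as fh:
        for ln in fh:
            s = ln.strip()
            if not s:
                continue
            if "=" in s and s.split("=")[0].strip() in ("t", "b", "E"):
                key = s.split("=")[0].strip()
                rest = s.split("=", 1)[1].split()
                # a header line after nucleotide lines starts a new frame;
                # header order within a frame is otherwise free (classic
                # and updated dialects order t/b/E differently)
                if nucl:
                    flush()
                header.append((key, rest))
                started = True
            else:
                if not started:
                    raise ParseError(f"{path}: nucleotide line before any frame header")
                nucl.append(s)
    flush()
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return Trajectory(topology=topology, frames=frames)


def write_trajectory(path, trajectory: Trajectory | Iterable[Frame]) -> None:
    frames = trajectory.frames if isinstance(trajectory, Trajectory) else list(trajectory)
    u = OXDNA_LENGTH_UNIT_NM
    with Path(path).open("w") as fh:
        for fr in frames:
            fh.write(f"t = {fr.time:.6g}\n")
            b = fr.box / u
            fh.write(f"b = {b[0]:.8g} {b[1]:.8g} {b[2]:.8g}\n")
            e = fr.energy
            fh.write(f"E = {e[0]:.8g} {e[1]:.8g} {e[2]:.8g}\n")
            block = np.hstack(
                [
                    fr.positions / u,
                    fr.a1,
                    fr.a3,
                    fr.velocities / u,
                    fr.angular_velocities,
                ]
            )
            for row in block:
                fh.write(" ".join(f"{x:.10g}" for x in row) + "\n")


def write_configuration(path, frame: Frame) -> None:
    """Write a single frame as an oxDNA configuration file."""
    write_trajectory(path, [frame])


# ---------------------------------------------------------------------------
# geometric base-pair detection


def detect_base_pairs(
    frame: Frame,
    topology: Topology,
    cutoff: float = 0.45,
    antiparallel_threshold: float = 0.7,
    require_complementarity: bool = True,
) -> BasePairMap:
    """Geometric proxy for hydrogen-bonded base pairing.

    A candidate pair (i, j) must: sit on different strands or more than 3
    bases apart along one strand; have base interaction sites closer than
    ``cutoff`` (nm); have anti-aligned stacking versors
    (a3_i . a3_j < -antiparallel_threshold); face each other
    (a1_i . (r_j - r_i) > 0 and vice versa); and, when base identities are
    informative, be Watson-Crick complementary.  Candidates are assigned
    greedily by ascending site distance (ties: lowest index pair), each
    nucleotide used at most once.
    """
    sites = frame.base_sites()
    tree = cKDTree(sites)
    candidates = []
    for i, j in sorted(tree.query_pairs(cutoff)):
        same_strand = topology.strand_ids[i] == topology.strand_ids[j]
        if same_strand and abs(i - j) <= 3:
            continue
        if float(np.dot(frame.a3[i], frame.a3[j])) >= -antiparallel_threshold:
            continue
        rij = frame.positions[j] - frame.positions[i]
        if float(np.dot(frame.a1[i], rij)) <= 0 or float(np.dot(frame.a1[j], -rij)) <= 0:
            continue
        bi, bj = topology.bases[i], topology.bases[j]
        if require_complementarity and bi in _COMPLEMENT and bj in _COMPLEMENT:
            if _COMPLEMENT[bi] != bj:
                continue
        d = float(np.linalg.norm(sites[j] - sites[i]))
        candidates.append((d, i, j))

    candidates.sort()
    used: set = set()
    pairs = []
    for _, i, j in candidates:
        if i in used or j in used:
            continue
        used.add(i)
        used.add(j)
        pairs.append((i, j))
    pairs.sort()
    return BasePairMap(pairs=pairs, provenance="geometry-derived")
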