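"""caDNAno v2 design import: parsing, crossover detection, initial
configuration construction and surrogate relaxation.

A caDNAno design stores virtual helices ("vstrands") on a lattice, each
with per-position scaffold and staple slots (4-tuples pointing at the 5'
and 3' neighbours), skips (deleted base pairs) and loops (insertions).
``build_initial`` places every nucleotide at its ideal B-form position on
the design lattice; crossovers then connect helices per the routing.  The
resulting geometry can be locally pathological (stretched crossover
bonds, coincident insertion nucleotides), so ``relax`` runs a
capped-displacement steepest descent on a simple surrogate energy —
harmonic backbone springs plus a soft excluded-volume repulsion — to
remove the worst clashes before any downstream use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .cg_io import Frame, Topology
from .errors import ParseError, UnsupportedFormatError, ValidationError
from .geometry import DEFAULT_GEOMETRY, GeometryParams, unit

__all__ = [
    "VStrand",
    "Design",
    "Crossover",
    "CrossoverSet",
    "parse_cadnano",
    "detect_crossovers",
    "build_initial",
    "relax",
    "RelaxParams",
]

_NONE_SLOT = (-1, -1, -1, -1)


@dataclass
class VStrand:
    num: int
    row: int
    col: int
    scaf: list
    stap: list
    skip: list
    loop: list

    @property
    def length(self) -> int:
        return len(self.scaf)


@dataclass
class Design:
    lattice: str  # "honeycomb" | "square"
    vstrands: list

    def vstrand_by_num(self, num: int) -> VStrand:
        for v in self.vstrands:
            if v.num == num:
                return v
        raise KeyError(f"no virtual helix numbered {num}")

    def occupied(self, channel: str):
        """Iterate (helix_num, position) of non-empty slots on one channel."""
        for v in self.vstrands:
            slots = v.scaf if channel == "scaf" else v.stap
            for i, slot in enumerate(slots):
                if tuple(slot) != _NONE_SLOT:
                    yield v.num, i


@dataclass(frozen=True)
class Crossover:
    helix_a: int
    helix_b: int
    position: int
    kind: str  # "staple" | "scaffold-seam"
    paired_with: int | None = None


@dataclass
class CrossoverSet:
    crossovers: list

    def __len__(self):
        return len(self.crossovers)

    def double_crossovers(self) -> list:
        """Indices of crossovers paired into double crossovers."""
        return [k for k, c in enumerate(self.crossovers) if c.paired_with is not None]


def parse_cadnano(path) -> Design:
    """Parse a caDNAno v2 JSON design and validate its cross-references."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "vstrands" not in doc:
        if isinstance(doc, dict) and str(doc.get("format", "")).startswith("3"):
            raise UnsupportedFormatError(f"{path}: caDNAno v3 files are not supported")
        raise UnsupportedFormatError(
            f"{path}: no 'vstrands' key; not a caDNAno v2 design"
        )
    raw = doc["vstrands"]
    if not raw:
        raise ValidationError(f"{path}: empty vstrands array")

    vstrands = []
    for v in raw:
        try:
            vs = VStrand(
                num=int(v["num"]),
                row=int(v["row"]),
                col=int(v["col"]),
                scaf=[tuple(map(int, s)) for s in v["scaf"]],
                stap=[tuple(map(int, s)) for s in v["stap"]],
                skip=[int(x) for x in v.get("skip", [0] * len(v["scaf"]))],
                loop=[int(x) for x in v.get("loop", [0] * len(v["scaf"]))],
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: malformed vstrand entry ({exc})") from exc
        vstrands.append(vs)

    nums = {v.num for v in vstrands}
    lengths = {v.num: v.length for v in vstrands}
    dangling = []
    for v in vstrands:
        for channel in ("scaf", "stap"):
            for i, slot in enumerate(getattr(v, channel)):
                for h, p in ((slot[0], slot[1]), (slot[2], slot[3])):
                    if h == -1:
                        continue
                    if h not in nums or not (0 <= p < lengths[h]):
                        dangling.append((v.num, channel, i, h, p))
    if dangling:
        raise ValidationError(
            "dangling slot references: "
            + ", ".join(
                f"helix {n} {ch}[{i}] -> ({h},{p})" for n, ch, i, h, p in dangling[:10]
            )
        )

    lattice = doc.get("lattice")
    if lattice not in ("square", "honeycomb"):
        lattice = _infer_lattice(vstrands)
    return Design(lattice=lattice, vstrands=vstrands)


def _infer_lattice(vstrands) -> str:
    """Honeycomb designs obey an (row+col) parity convention; default square.

    caDNAno files do not always declare their lattice; when any helix
    violates the honeycomb parity rule the design is taken to be square.
    """
    for v in vstrands:
        if (v.row + v.col) % 2 != v.num % 2:
            return "square"
    return "honeycomb"


def detect_crossovers(design: Design) -> CrossoverSet:
    """Every slot whose neighbour lives on another helix yields a crossover.

    Crossovers are deduplicated to one record per inter-helix link,
    labelled ``scaffold-seam`` when the scaffold strand exchanges and
    ``staple`` otherwise, and paired into double crossovers when two
    crossovers join the same helix pair at adjacent positions (within 2
    bp).
    """
    seen = set()
    found = []
    for v in design.vstrands:
        for channel in ("scaf", "stap"):
            for i, slot in enumerate(getattr(v, channel)):
                if tuple(slot) == _NONE_SLOT:
                    continue
                for h, p in ((slot[0], slot[1]), (slot[2], slot[3])):
                    if h == -1 or h == v.num:
                        continue
                    key = (channel, frozenset({(v.num, i), (h, p)}))
                    if key in seen:
                        continue
                    seen.add(key)
                    a, b = sorted((v.num, h))
                    found.append(
                        {
                            "helix_a": a,
                            "helix_b": b,
                            "position": min(i, p),
                            "kind": "scaffold-seam" if channel == "scaf" else "staple",
                        }
                    )
    found.sort(key=lambda c: (c["helix_a"], c["helix_b"], c["position"]))
    paired = [None] * len(found)
    for i in range(len(found)):
        if paired[i] is not None:
            continue
        for j in range(i + 1, len(found)):
            if paired[j] is not None:
                continue
            ci, cj = found[i], found[j]
            if (
                ci["helix_a"] == cj["helix_a"]
                and ci["helix_b"] == cj["helix_b"]
                and ci["kind"] == cj["kind"]
                and abs(ci["position"] - cj["position"]) <= 2
            ):
                paired[i], paired[j] = j, i
                break
    crossovers = [
        Crossover(paired_with=paired[k], **found[k]) for k in range(len(found))
    ]
    return CrossoverSet(crossovers=crossovers)


# ---------------------------------------------------------------------------
# initial configuration


_BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _walk_paths(design: Design, channel: str):
    """Strand paths as ordered (helix_num, position) lists, 5' to 3'."""
    slots = {}
    for v in design.vstrands:
        arr = v.scaf if channel == "scaf" else v.stap
        for i, slot in enumerate(arr):
            if tuple(slot) != _NONE_SLOT:
                slots[(v.num, i)] = slot

    def nxt(node):
        h, p = slots[node][2], slots[node][3]
        return (h, p) if h != -1 else None

    def prv(node):
        h, p = slots[node][0], slots[node][1]
        return (h, p) if h != -1 else None

    starts = [n for n in slots if prv(n) is None]
    paths = []
    visited = set()
    for s in starts:
        path = []
        node = s
        while node is not None:
            if node in visited:
                raise ValidationError(
                    f"{channel} path branches or merges at helix {node[0]} "
                    f"position {node[1]}"
                )
            visited.add(node)
            path.append(node)
            node = nxt(node)
        paths.append(path)
    # remaining nodes belong to cycles (circular strands)
    remaining = [n for n in slots if n not in visited]
    while remaining:
        start = min(remaining)
        path = [start]
        visited.add(start)
        node = nxt(start)
        while node is not None and node != start:
            if node in visited:
                raise ValidationError(f"{channel} routing is inconsistent at {node}")
            visited.add(node)
            path.append(node)
            node = nxt(node)
        paths.append(path)
        remaining = [n for n in slots if n not in visited]
    return paths


def _helix_frame(design: Design, geom: GeometryParams):
    """Lattice coordinates (nm) of each helix axis."""
    S = geom.inter_helix_spacing
    coords = {}
    for v in design.vstrands:
        if design.lattice == "honeycomb":
            # honeycomb rows pack at sqrt(3)/2 spacing with a parity offset
            y = v.col * S
            z = -(v.row * S * np.sqrt(3) / 2 + (((v.row + v.col) % 2) * S / 4))
        else:
            y = v.col * S
            z = -v.row * S
        coords[v.num] = np.array([0.0, y, z])
    return coords


def build_initial(
    design: Design,
    scaffold_sequence: str | None = None,
    geom: GeometryParams = DEFAULT_GEOMETRY,
    seed: int = 0,
) -> tuple:
    """Place the design's nucleotides on the lattice -> (Topology, Frame).

    Helices sit at their lattice coordinates with ideal B-form placement
    along the axis (rise/pitch/radius from ``geom``); connectivity follows
    the scaffold and staple routing, skips omit nucleotides and loops
    insert extras at their design position.  The scaffold sequence is
    taken from ``scaffold_sequence`` or drawn deterministically from
    ``seed``; staple bases complement the scaffold wherever paired.
    """
    rng = np.random.default_rng(seed)
    coords = _helix_frame(design, geom)
    vs_by_num = {v.num: v for v in design.vstrands}

    scaf_paths = _walk_paths(design, "scaf")
    stap_paths = _walk_paths(design, "stap")

    def slot_multiplicity(h, p):
        v = vs_by_num[h]
        if v.skip[p] == -1:
            return 0
        return 1 + max(0, v.loop[p])

    # scaffold bases per (helix, position, copy)
    scaf_nodes = [
        (h, p, k) for path in scaf_paths for (h, p) in path
        for k in range(slot_multiplicity(h, p))
    ]
    if scaffold_sequence is not None:
        seq = list(scaffold_sequence.upper())
        if len(seq) < len(scaf_nodes):
            raise ValidationError(
                f"scaffold sequence length {len(seq)} < scaffold length "
                f"{len(scaf_nodes)}"
            )
    else:
        seq = list(_BASES[rng.integers(0, 4, size=len(scaf_nodes))])
    scaf_base = {node: seq[i] for i, node in enumerate(scaf_nodes)}

    records = []  # (strand_id, base, helix, pos, copy, channel)
    index_of = {}
    n3 = []
    n5 = []
    strand_ids = []
    bases = []
    sid = 0
    for channel, paths in (("scaf", scaf_paths), ("stap", stap_paths)):
        for path in paths:
            nodes = [
                (h, p, k) for (h, p) in path for k in range(slot_multiplicity(h, p))
            ]
            if not nodes:
                continue
            sid += 1
            prev = None
            for node in nodes:
                i = len(records)
                h, p, k = node
                if channel == "scaf":
                    b = scaf_base[node]
                else:
                    b = _COMPLEMENT.get(scaf_base.get(node, ""), None)
                    if b is None:
                        b = str(_BASES[rng.integers(0, 4)])
                records.append((sid, b, h, p, k, channel))
                index_of[(channel,) + node] = i
                strand_ids.append(sid)
                bases.append(b)
                n3.append(prev if prev is not None else -1)
                n5.append(-1)
                if prev is not None:
                    n5[prev] = i
                prev = i

    topo = Topology(
        np.array(strand_ids), np.array(bases, dtype="<U1"),
        np.array(n3), np.array(n5),
    )

    # geometry: scaffold on even-numbered helices runs 5'->3' with
    # increasing position (caDNAno convention); phase advances with index
    positions = np.empty((len(records), 3))
    a1 = np.empty((len(records), 3))
    a3 = np.empty((len(records), 3))
    xhat = np.array([1.0, 0.0, 0.0])
    pr = geom.position_radius
    for i, (s, b, h, p, k, channel) in enumerate(records):
        axis_origin = coords[h]
        frac = k / (1.0 + vs_by_num[h].loop[p]) if vs_by_num[h].loop[p] > 0 else 0.0
        x = (p + frac) * geom.rise
        ang = p * geom.twist_per_bp + (np.pi if channel == "stap" else 0.0)
        radial = np.array([0.0, np.cos(ang), np.sin(ang)])
        center = axis_origin + x * xhat
        positions[i] = center + pr * radial
        a1[i] = -radial
        scaffold_forward = h % 2 == 0
        forward = scaffold_forward if channel == "scaf" else not scaffold_forward
        a3[i] = xhat if forward else -xhat

    frame = Frame(
        time=0.0,
        box=np.maximum(positions.max(axis=0) - positions.min(axis=0) + 20.0, 50.0),
        positions=positions,
        a1=a1,
        a3=a3,
    )
    return topo, frame


# ---------------------------------------------------------------------------
# relaxation


@dataclass
class RelaxParams:
    """Surrogate-energy relaxation parameters.

    Backbone springs act between bonded neighbours at ``rest_length`` (by
    default the ideal B-form backbone spacing implied by the geometry);
    non-bonded nucleotides closer than ``ev_cutoff`` feel a soft quadratic
    repulsion.  Per-step displacements are capped at ``cap_nm``.
    """

    cap_nm: float = 0.05
    tol: float = 0.1
    max_iters: int = 5000
    spring_k: float = 10.0
    ev_k: float = 10.0
    ev_cutoff: float = 0.6
    rest_length: float | None = None

    def resolved_rest_length(self, geom: GeometryParams = DEFAULT_GEOMETRY) -> float:
        if self.rest_length is not None:
            return self.rest_length
        chord = 2 * geom.position_radius * np.sin(geom.twist_per_bp / 2)
        return float(np.hypot(chord, geom.rise))


def _surrogate_energy_grad(pos, bonds, r0, params: RelaxParams):
    E = 0.0
    grad = np.zeros_like(pos)
    d = pos[bonds[:, 1]] - pos[bonds[:, 0]]
    r = np.linalg.norm(d, axis=1)
    r = np.where(r == 0, 1e-12, r)
    dr = r - r0
    E += 0.5 * params.spring_k * np.sum(dr**2)
    f = (params.spring_k * dr / r)[:, None] * d
    np.add.at(grad, bonds[:, 0], -f)
    np.add.at(grad, bonds[:, 1], f)

    tree = cKDTree(pos)
    bonded = {tuple(sorted(b)) for b in bonds.tolist()}
    close = [
        (i, j) for i, j in tree.query_pairs(params.ev_cutoff)
        if tuple(sorted((i, j))) not in bonded
    ]
    if close:
        pairs = np.array(close)
        d2 = pos[pairs[:, 1]] - pos[pairs[:, 0]]
        r2 = np.linalg.norm(d2, axis=1)
        r2 = np.where(r2 == 0, 1e-12, r2)
        over = params.ev_cutoff - r2
        E += 0.5 * params.ev_k * np.sum(over**2)
        f2 = (-params.ev_k * over / r2)[:, None] * d2
        np.add.at(grad, pairs[:, 0], -f2)
        np.add.at(grad, pairs[:, 1], f2)
    if not np.isfinite(E):
        raise ValidationError("non-finite surrogate energy during relaxation")
    return E, grad


def relax(
    frame: Frame,
    topology: Topology,
    params: RelaxParams | None = None,
    geom: GeometryParams = DEFAULT_GEOMETRY,
    return_trace: bool = False,
):
    """Capped-displacement steepest descent on the surrogate energy.

    Stops when the largest backbone-length deviation falls below
    ``params.tol`` or after ``params.max_iters`` iterations.  Steps that
    would increase the energy are retried with a halved step; the energy
    trace is therefore monotone non-increasing.  Returns the relaxed
    Frame (and the energy trace when requested).
    """
    params = params or RelaxParams()
    r0 = params.resolved_rest_length(geom)
    bonds = np.array(
        [
            [i, int(topology.neighbor_5p[i])]
            for i in range(topology.n_nucleotides)
            if topology.neighbor_5p[i] >= 0
        ],
        dtype=int,
    )
    pos = frame.positions.copy()
    bonds = bonds.reshape(-1, 2)

    E, grad = _surrogate_energy_grad(pos, bonds, r0, params)
    trace = [E]
    step = params.cap_nm
    for _ in range(params.max_iters):
        if bonds.shape[0]:
            r = np.linalg.norm(pos[bonds[:, 1]] - pos[bonds[:, 0]], axis=1)
            if np.max(np.abs(r - r0)) < params.tol:
                break
        elif E < 1e-12:  # no backbone: descend the excluded-volume term out
            break
        gnorm = np.linalg.norm(grad, axis=1, keepdims=True)
        gmax = float(gnorm.max())
        if gmax == 0:
            break
        move = -grad * (step / gmax)
        # per-nucleotide displacement cap
        mnorm = np.linalg.norm(move, axis=1, keepdims=True)
        over = mnorm > params.cap_nm
        move = np.where(over, move * (params.cap_nm / np.where(mnorm == 0, 1, mnorm)), move)
        new_pos = pos + move
        E_new, grad_new = _surrogate_energy_grad(new_pos, bonds, r0, params)
        if E_new <= E:
            pos, E, grad = new_pos, E_new, grad_new
            trace.append(E)
            step = min(step * 1.2, params.cap_nm)
        else:
            step *= 0.5
            if step < 1e-6:
                break
    out = Frame(frame.time, frame.box.copy(), pos, frame.a1.copy(), frame.a3.copy())
    return (out, trace) if return_trace else out
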