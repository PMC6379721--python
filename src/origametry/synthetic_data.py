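"""Seeded generators for coarse-grained test ensembles.

These generators construct configurations with the statistical structure
the analysis modules assume — ideal duplexes, stacked four-way junction
ensembles drawn from a stated Boltzmann density over (phi, theta), 2D
tiles with a triangular-wave weave and optional out-of-plane corrugation,
and square-lattice 3D bundles with staggered junctions.  Every generator
records its construction (centerlines, crossover positions, drawn angles)
in a :class:`GroundTruth` so analyses can be validated without re-deriving
the geometry.  Outputs are deterministic functions of the seed.

The noise model is deliberately simple: iid isotropic Gaussian
displacements applied per base pair and frame (both nucleotides of a pair
move together, so the helix-axis points carry the full noise sigma while
base pairing is unaffected).  Versors are noise-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .cg_io import BasePairMap, Frame, Topology, Trajectory
from .errors import AnalysisError
from .geometry import (
    DEFAULT_GEOMETRY,
    GeometryParams,
    rotation_about_axis,
    unit,
    wrap_360,
)
from .junction_analysis import AngleSample, Arm, BiasWindow, JunctionSpec, bias_energy

__all__ = [
    "GeneratorSpec",
    "GroundTruth",
    "TileJunction",
    "GaussianAngleDensity",
    "make_duplex",
    "construct_junction",
    "make_junction_ensemble",
    "sample_angles",
    "make_tile",
    "make_bundle",
]

_BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class GeneratorSpec:
    """What was generated and with which parameters (serialized as metadata)."""

    kind: str
    geometry: GeometryParams
    params: dict
    noise_sigma: float
    n_frames: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "geometry": {
                "rise": self.geometry.rise,
                "pitch": self.geometry.pitch,
                "backbone_radius": self.geometry.backbone_radius,
                "inter_helix_spacing": self.geometry.inter_helix_spacing,
            },
            "params": _jsonable(self.params),
            "noise_sigma": self.noise_sigma,
            "n_frames": self.n_frames,
            "seed": self.seed,
        }


@dataclass
class TileJunction:
    """One crossover (junction) between an adjacent helix pair of a tile."""

    pair: tuple
    index: int
    group: int
    edge: bool = False
    seam: bool = False
    seam_adjacent: bool = False

    @property
    def canonical(self) -> bool:
        return not (self.edge or self.seam or self.seam_adjacent)


@dataclass
class GroundTruth:
    """Constructed quantities sufficient to verify every analysis output."""

    spec: GeneratorSpec
    centerlines: dict | None = None
    helix_pairs: dict | None = None
    crossovers: dict | None = None
    junctions: list | None = None
    groups: dict | None = None
    angles: list | None = None
    junction_spec: JunctionSpec | None = None
    extras: dict = field(default_factory=dict)

    def base_pair_map(self) -> BasePairMap:
        pairs = []
        for plist in (self.helix_pairs or {}).values():
            pairs.extend(plist)
        return BasePairMap(pairs=pairs, provenance="design-derived")

    def to_dict(self) -> dict:
        return _jsonable(
            {
                "spec": self.spec.to_dict(),
                "centerlines": self.centerlines,
                "helix_pairs": self.helix_pairs,
                "crossovers": self.crossovers,
                "junctions": [vars(j) for j in self.junctions] if self.junctions else None,
                "groups": self.groups,
                "angles": [vars(a) for a in self.angles] if self.angles else None,
                "junction_spec": self.junction_spec.to_dict() if self.junction_spec else None,
                "extras": self.extras,
            }
        )

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# low-level duplex placement


def _perp_frame(tangent: np.ndarray, ref: np.ndarray | None = None):
    t = unit(tangent)
    if ref is None:
        ref = np.array([0.0, 0.0, 1.0])
        if abs(float(np.dot(t, ref))) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
    e1 = unit(ref - np.dot(ref, t) * t)
    e2 = np.cross(t, e1)
    return e1, e2


def _place_duplex(
    centerline: np.ndarray,
    tangents: np.ndarray,
    geom: GeometryParams,
    phase0: float = 0.0,
):
    """Nucleotide positions/versors for the two strands of one duplex.

    Strand "a" runs with the centerline parametrization (a3 = +tangent),
    strand "b" against it.  The midpoint of each pair is exactly the
    centerline point.  Returns (pos_a, a1_a, a3_a, pos_b, a1_b, a3_b).
    """
    n = centerline.shape[0]
    pr = geom.position_radius
    twist = geom.twist_per_bp
    mean_t = unit(tangents.sum(axis=0))
    e1, e2 = _perp_frame(mean_t)
    t = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
    ang = phase0 + np.arange(n) * twist
    radial = np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2
    radial -= np.einsum("ij,ij->i", radial, t)[:, None] * t
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    pos_a = centerline + pr * radial
    pos_b = centerline - pr * radial
    return pos_a, -radial, t, pos_b, radial, -t


def _random_sequence(n: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _complement(seq) -> np.ndarray:
    return np.array([_COMPLEMENT[b] for b in seq], dtype="<U1")


def _duplex_topology(seq_a: np.ndarray, strand_offset: int = 0) -> tuple:
    """Topology arrays for one duplex; strand b listed 3'-distal first.

    Nucleotide ``k`` of strand a is bp ``k``; nucleotide ``n + k`` of
    strand b is bp ``n - 1 - k``, so bp ``i`` pairs (i, 2n - 1 - i).
    """
    n = seq_a.size
    seq_b = _complement(seq_a)[::-1]
    strand_ids = np.concatenate(
        [np.full(n, strand_offset + 1), np.full(n, strand_offset + 2)]
    )
    bases = np.concatenate([seq_a, seq_b])
    n3 = np.concatenate([np.arange(-1, n - 1), np.arange(n - 1, 2 * n - 1)])
    n3[n] = -1
    n5 = np.concatenate([np.arange(1, n + 1), np.arange(n + 1, 2 * n + 1)])
    n5[n - 1] = -1
    n5[2 * n - 1] = -1
    return strand_ids, bases, n3, n5


def _default_box(positions: np.ndarray) -> np.ndarray:
    span = positions.max(axis=0) - positions.min(axis=0)
    return np.maximum(span * 2 + 20.0, 50.0)


# ---------------------------------------------------------------------------
# duplex


def make_duplex(
    n_bp: int,
    geom: GeometryParams = DEFAULT_GEOMETRY,
    origin=(0.0, 0.0, 0.0),
    direction=(1.0, 0.0, 0.0),
    seed: int = 0,
    sequence: Sequence[str] | None = None,
) -> tuple:
    """Ideal straight B-form duplex -> (Topology, Frame, GroundTruth)."""
    if n_bp < 2:
        raise ValueError("n_bp must be >= 2")
    rng = np.random.default_rng(seed)
    d = unit(np.asarray(direction, float))
    centerline = np.asarray(origin, float) + np.outer(np.arange(n_bp) * geom.rise, d)
    tangents = np.tile(d, (n_bp, 1))
    pos_a, a1_a, a3_a, pos_b, a1_b, a3_b = _place_duplex(centerline, tangents, geom)
    seq_a = np.asarray(sequence, dtype="<U1") if sequence is not None else _random_sequence(n_bp, rng)
    strand_ids, bases, n3, n5 = _duplex_topology(seq_a)
    topo = Topology(strand_ids, bases, n3, n5)

    positions = np.vstack([pos_a, pos_b[::-1]])
    a1 = np.vstack([a1_a, a1_b[::-1]])
    a3 = np.vstack([a3_a, a3_b[::-1]])
    frame = Frame(time=0.0, box=_default_box(positions), positions=positions, a1=a1, a3=a3)

    spec = GeneratorSpec(
        kind="duplex",
        geometry=geom,
        params={"n_bp": n_bp, "origin": list(origin), "direction": d.tolist()},
        noise_sigma=0.0,
        n_frames=1,
        seed=seed,
    )
    gt = GroundTruth(
        spec=spec,
        centerlines={"0": centerline},
        helix_pairs={"0": [(i, 2 * n_bp - 1 - i) for i in range(n_bp)]},
        extras={"axis": d.tolist()},
    )
    return topo, frame, gt


# ---------------------------------------------------------------------------
# junction


def construct_junction(
    phi_deg: float,
    theta_deg: float,
    arm_bp: int = 16,
    geom: GeometryParams = DEFAULT_GEOMETRY,
    gap: float = 2.0,
    bases_by_arm: list | None = None,
    rng: np.random.Generator | None = None,
) -> tuple:
    """Stacked four-way junction realizing exactly (phi, theta).

    Duplex 1 (arms A, B) and duplex 2 (arms C, D) are separated by ``gap``
    along z.  The duplex directions make a right-handed angle ``phi``
    about z (duplex 1 at -phi/2, duplex 2 at +phi/2 in the xy-plane) and
    each arm is tilted by ``theta`` away from the partner duplex.
    Returns (Topology, Frame, JunctionSpec, bases_by_arm).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    phi_r = np.radians(phi_deg)
    th_r = np.radians(theta_deg)
    z = np.array([0.0, 0.0, 1.0])
    s1 = np.array([np.cos(-phi_r / 2), np.sin(-phi_r / 2), 0.0])
    s2 = np.array([np.cos(phi_r / 2), np.sin(phi_r / 2), 0.0])
    apex1 = -0.5 * gap * z
    apex2 = 0.5 * gap * z

    def tilted(d, away):
        # rotate arm direction by theta toward `away` (normal component)
        return unit(d * np.cos(th_r) + away * np.sin(th_r))

    dirs = {
        "A": tilted(-s1, -z),
        "B": tilted(s1, -z),
        "C": tilted(-s2, z),
        "D": tilted(s2, z),
    }
    apexes = {"A": apex1, "B": apex1, "C": apex2, "D": apex2}

    if bases_by_arm is None:
        bases_by_arm = [_random_sequence(arm_bp, rng) for _ in range(4)]

    # per-arm duplexes; side0 carries the continuing strand, side1 the
    # exchanging strand
    arm_data = {}
    for k, label in enumerate("ABCD"):
        d = dirs[label]
        start = apexes[label] + geom.rise * d
        centerline = start + np.outer(np.arange(arm_bp) * geom.rise, d)
        tangents = np.tile(d, (arm_bp, 1))
        pos_a, a1_a, a3_a, pos_b, a1_b, a3_b = _place_duplex(centerline, tangents, geom)
        arm_data[label] = {
            "pos": (pos_a, pos_b),
            "a1": (a1_a, a1_b),
            "a3": (a3_a, a3_b),
            "bases": (bases_by_arm[k], _complement(bases_by_arm[k])),
        }

    # travel direction of each side's strand within the arm, relative to the
    # junction-outward parametrization used by _place_duplex (side0 = "a").
    # Continuing strands: c1 = A(in) + B(out), c2 = C(in) + D(out).
    # Exchanging strands: e1 = B(in) + C(out), e2 = D(in) + A(out).
    inbound_side0 = {"A": True, "B": False, "C": True, "D": False}

    def side_entry(label, side, k):
        d = arm_data[label]
        i = 0 if side == 0 else 1
        pos = d["pos"][i][k]
        a1 = d["a1"][i][k]
        base = d["bases"][i][k]
        # side0 travels inbound on A/C (against outward parametrization)
        if side == 0:
            travel = -dirs[label] if inbound_side0[label] else dirs[label]
        else:
            travel = dirs[label] if inbound_side0[label] else -dirs[label]
        return {"pos": pos, "a1": a1, "a3": travel, "base": base, "key": (label, side, k)}

    def arm_path(label, side, toward_junction: bool):
        ks = range(arm_bp - 1, -1, -1) if toward_junction else range(arm_bp)
        return [side_entry(label, side, k) for k in ks]

    strands = [
        arm_path("A", 0, True) + arm_path("B", 0, False),   # c1
        arm_path("C", 0, True) + arm_path("D", 0, False),   # c2
        arm_path("B", 1, True) + arm_path("C", 1, False),   # e1
        arm_path("D", 1, True) + arm_path("A", 1, False),   # e2
    ]

    index_of = {}
    records = []
    for sid, path in enumerate(strands, start=1):
        for entry in path:
            index_of[entry["key"]] = len(records)
            records.append((sid, entry))

    n = len(records)
    strand_ids = np.array([sid for sid, _ in records])
    bases = np.array([e["base"] for _, e in records], dtype="<U1")
    n3 = np.full(n, -1)
    n5 = np.full(n, -1)
    for sid, path in enumerate(strands, start=1):
        idx = [index_of[e["key"]] for e in path]
        for a, b in zip(idx[:-1], idx[1:]):
            n5[a] = b
            n3[b] = a
    topo = Topology(strand_ids, bases, n3, n5)

    positions = np.array([e["pos"] for _, e in records])
    a1 = np.array([e["a1"] for _, e in records])
    a3 = np.array([unit(e["a3"]) for _, e in records])
    frame = Frame(time=0.0, box=_default_box(positions), positions=positions, a1=a1, a3=a3)

    arms = []
    for label in "ABCD":
        pairs = tuple(
            (index_of[(label, 0, k)], index_of[(label, 1, k)]) for k in range(arm_bp)
        )
        arms.append(Arm(label=label, pairs=pairs))
    mid = (
        index_of[("B", 1, 0)],
        index_of[("C", 1, 0)],
        index_of[("D", 1, 0)],
        index_of[("A", 1, 0)],
    )
    spec = JunctionSpec(
        arms=tuple(arms),
        exchanging_strands=(3, 4),
        continuing_strands=(1, 2),
        midpoint_nucleotides=mid,
    )
    return topo, frame, spec, bases_by_arm


class GaussianAngleDensity:
    """Separable Gaussian density over (phi, theta), phi treated circularly."""

    def __init__(self, phi_mean=120.0, phi_sigma=15.0, theta_mean=0.0, theta_sigma=5.0):
        self.phi_mean = float(phi_mean)
        self.phi_sigma = float(phi_sigma)
        self.theta_mean = float(theta_mean)
        self.theta_sigma = float(theta_sigma)

    def log_phi(self, phi):
        from .geometry import circular_difference_deg

        d = circular_difference_deg(phi, self.phi_mean)
        return -0.5 * np.square(d) / self.phi_sigma**2

    def log_theta(self, th):
        return -0.5 * np.square(np.asarray(th, float) - self.theta_mean) / self.theta_sigma**2

    def logpdf(self, phi, th):
        return self.log_phi(phi) + self.log_theta(th)

    def sample(self, n, rng: np.random.Generator):
        phi = wrap_360(rng.normal(self.phi_mean, self.phi_sigma, size=n))
        th = np.clip(rng.normal(self.theta_mean, self.theta_sigma, size=n), -90.0, 90.0)
        return phi, th

    def analytic_free_energy(self, phi, th):
        """-log density in kT, up to a constant."""
        return -self.logpdf(phi, th)


def sample_angles(
    density,
    windows: Sequence[BiasWindow] | None,
    n_samples: int,
    rng: np.random.Generator,
) -> list:
    """Draw AngleSamples from ``density`` (times window bias reweighting).

    For a :class:`GaussianAngleDensity` the biased phi marginal is sampled
    by inverse transform on a fine grid (the harmonic phi bias leaves
    theta untouched); a generic callable ``density(phi, theta) -> pdf`` is
    sampled by rejection.
    """
    samples: list = []
    if windows is None or len(windows) == 0:
        if isinstance(density, GaussianAngleDensity):
            ph, th = density.sample(n_samples, rng)
        else:
            ph, th = _rejection_sample(density, None, n_samples, rng)
        for p, t in zip(ph, th):
            samples.append(_bare_sample(p, t, None))
        return samples

    counts = np.full(len(windows), n_samples // len(windows))
    counts[: n_samples % len(windows)] += 1
    for w, m in zip(windows, counts):
        if m == 0:
            continue
        if isinstance(density, GaussianAngleDensity):
            grid = np.arange(0.0, 360.0, 0.02)
            logw = density.log_phi(grid) - bias_energy(grid, w)
            pw = np.exp(logw - logw.max())
            cdf = np.cumsum(pw)
            cdf /= cdf[-1]
            u = rng.random(m)
            ph = np.interp(u, cdf, grid)
            th = np.clip(
                rng.normal(density.theta_mean, density.theta_sigma, size=m), -90.0, 90.0
            )
        else:
            ph, th = _rejection_sample(density, w, m, rng)
        for p, t in zip(ph, th):
            samples.append(_bare_sample(p, t, w.window_id))
    return samples


def _bare_sample(p, t, wid):
    return AngleSample(
        phi=float(p), theta=float(t), phi1=float(p), phi2=float(p),
        theta1=float(t), theta2=float(t), window_id=wid,
    )


def _rejection_sample(density, window, n, rng, max_batches=10000):
    gp = np.linspace(0.0, 360.0, 361)
    gt = np.linspace(-90.0, 90.0, 181)
    PP, TT = np.meshgrid(gp, gt, indexing="ij")
    vals = np.asarray(density(PP, TT), float)
    if window is not None:
        vals = vals * np.exp(-bias_energy(PP, window))
    M = float(vals.max())
    if not np.isfinite(M) or M <= 0:
        raise AnalysisError("density is not normalizable over the angle domain")
    out_p, out_t = [], []
    remaining = n
    for _ in range(max_batches):
        if remaining <= 0:
            break
        m = max(remaining * 4, 256)
        ph = rng.uniform(0.0, 360.0, size=m)
        th = rng.uniform(-90.0, 90.0, size=m)
        f = np.asarray(density(ph, th), float)
        if window is not None:
            f = f * np.exp(-bias_energy(ph, window))
        keep = rng.random(m) * M * 1.05 < f
        out_p.extend(ph[keep][:remaining])
        out_t.extend(th[keep][:remaining])
        remaining = n - len(out_p)
    if remaining > 0:
        raise AnalysisError("rejection sampling failed to converge")
    return np.array(out_p), np.array(out_t)


def make_junction_ensemble(
    arm_bp: int = 16,
    density=None,
    windows: Sequence[BiasWindow] | None = None,
    n_samples: int = 100,
    seed: int = 0,
    geom: GeometryParams = DEFAULT_GEOMETRY,
    gap: float = 2.0,
) -> tuple:
    """Stacked-junction ensemble drawn from a (phi, theta) density.

    Each sampled angle pair is realized exactly by the forward junction
    construction.  Returns (Topology, Trajectory, GroundTruth); the ground
    truth records the drawn angles (as AngleSamples) and the JunctionSpec.
    """
    if density is None:
        density = GaussianAngleDensity()
    rng = np.random.default_rng(seed)
    drawn = sample_angles(density, windows, n_samples, rng)

    topo, frame0, jspec, bases = construct_junction(
        drawn[0].phi, drawn[0].theta, arm_bp=arm_bp, geom=geom, gap=gap, rng=rng
    )
    frames = [frame0]
    for s in drawn[1:]:
        _, fr, _, _ = construct_junction(
            s.phi, s.theta, arm_bp=arm_bp, geom=geom, gap=gap, bases_by_arm=bases
        )
        frames.append(fr)
    for k, (fr, s) in enumerate(zip(frames, drawn)):
        fr.time = float(k)
        s.frame_index = k

    spec = GeneratorSpec(
        kind="junction_ensemble",
        geometry=geom,
        params={
            "arm_bp": arm_bp,
            "gap": gap,
            "n_windows": 0 if windows is None else len(windows),
        },
        noise_sigma=0.0,
        n_frames=len(frames),
        seed=seed,
    )
    gt = GroundTruth(spec=spec, angles=drawn, junction_spec=jspec)
    return topo, Trajectory(topology=topo, frames=frames), gt


# ---------------------------------------------------------------------------
# 2D tile


def _triangle_wave(i, period):
    """Periodic triangular wave: +1 at i = 0 (mod period), -1 at half period."""
    m = np.mod(np.asarray(i, float), period)
    return 1.0 - 4.0 * np.minimum(m, period - m) / period


def make_tile(
    n_helices: int = 8,
    bp_per_helix: int = 96,
    junction_spacing: int = 32,
    weave_amplitude: float = 1.5,
    corrugation_twist: float = 0.0,
    seam: bool = False,
    noise_sigma: float = 0.0,
    n_frames: int = 1,
    seed: int = 0,
    geom: GeometryParams = DEFAULT_GEOMETRY,
) -> tuple:
    """2D tile of parallel helices with triangular weave and corrugation.

    Adjacent helix pairs alternate between two crossover groups offset by
    half a junction period, so the inter-helix distance follows a
    triangular wave of full amplitude ``weave_amplitude`` with minima at
    the crossovers.  ``corrugation_twist`` (= 2 delta) rotates each pair's
    inter-helix vector by -delta on one side of a junction and +delta on
    the other, zero at the junction itself and at the midpoint between
    junctions.  ``seam=True`` removes the central group-0 crossover,
    doubling that group's junction-free section in the middle of the tile.
    Returns (Topology, Trajectory, GroundTruth).
    """
    P = int(junction_spacing)
    if P < 4:
        raise ValueError("junction_spacing must be >= 4")
    L = int(bp_per_helix)
    S = geom.inter_helix_spacing
    A = float(weave_amplitude)
    delta = np.radians(corrugation_twist / 2.0)
    rng = np.random.default_rng(seed)

    idx = np.arange(L)
    # crossover positions per group; group 0 pairs (even h) at i = 0 mod P,
    # group 1 pairs at i = P/2 mod P
    cross0 = [int(i) for i in idx if i % P == 0]
    cross1 = [int(i) for i in idx if i % P == P // 2]
    seam_index = None
    if seam:
        mids = [c for c in cross0 if 0 < c < L - 1]
        seam_index = mids[len(mids) // 2]
        cross0 = [c for c in cross0 if c != seam_index]

    def dist_to_nearest(i, crossings):
        if not crossings:
            return np.full_like(np.asarray(i, float), np.inf)
        arr = np.asarray(crossings, float)
        return np.min(np.abs(np.asarray(i, float)[:, None] - arr[None, :]), axis=1)

    # weave displacement waveform w(i): group-0 pair distance = S - w,
    # group-1 distance = S + w
    if seam:
        d0 = np.minimum(dist_to_nearest(idx, cross0), 1.5 * P / 2.0)
        w = A / 2.0 - A * d0 / (P / 2.0)
    else:
        w = (A / 2.0) * _triangle_wave(idx, P)

    # corrugation: z-offset waveform, zero at every crossover, extremes at
    # quarter period; sized so the measured pair angle peaks at +-delta
    zeta = (S * np.tan(delta) / 2.0) * _triangle_wave(idx - P / 4.0, P) if delta else np.zeros(L)

    # helix displacements: u_h = (-1)^h w/2 makes the group-0 pair distance
    # S - w and the group-1 distance S + w (full peak-to-peak amplitude A);
    # z_h = (-1)^h zeta realizes the corrugation twist
    x = idx * geom.rise
    centerlines = {}
    for h in range(n_helices):
        u = ((-1) ** h) * w / 2.0
        z = ((-1) ** h) * zeta
        centerlines[str(h)] = np.column_stack([x, h * S + u, z])

    # build duplexes
    topo_parts = []
    helix_pairs = {}
    offset = 0
    strand_off = 0
    seqs = []
    for h in range(n_helices):
        seq = _random_sequence(L, rng)
        seqs.append(seq)
        sids, bases, n3, n5 = _duplex_topology(seq, strand_offset=strand_off)
        n3 = np.where(n3 >= 0, n3 + offset, -1)
        n5 = np.where(n5 >= 0, n5 + offset, -1)
        topo_parts.append((sids, bases, n3, n5))
        helix_pairs[str(h)] = [(offset + i, offset + 2 * L - 1 - i) for i in range(L)]
        offset += 2 * L
        strand_off += 2
    topo = Topology(
        np.concatenate([p[0] for p in topo_parts]),
        np.concatenate([p[1] for p in topo_parts]),
        np.concatenate([p[2] for p in topo_parts]),
        np.concatenate([p[3] for p in topo_parts]),
    )

    # nucleotide placement (noise added per frame, shared within a base pair)
    def build_frame(k):
        pos_all = np.empty((offset, 3))
        a1_all = np.empty((offset, 3))
        a3_all = np.empty((offset, 3))
        for h in range(n_helices):
            pts = centerlines[str(h)]
            if noise_sigma > 0:
                pts = pts + rng.normal(0.0, noise_sigma, size=pts.shape)
            tangents = np.gradient(pts, axis=0)
            pos_a, a1_a, a3_a, pos_b, a1_b, a3_b = _place_duplex(pts, tangents, geom)
            base = 2 * L * h
            pos_all[base : base + L] = pos_a
            a1_all[base : base + L] = a1_a
            a3_all[base : base + L] = a3_a
            pos_all[base + L : base + 2 * L] = pos_b[::-1]
            a1_all[base + L : base + 2 * L] = a1_b[::-1]
            a3_all[base + L : base + 2 * L] = a3_b[::-1]
        return Frame(
            time=float(k),
            box=_default_box(pos_all),
            positions=pos_all,
            a1=a1_all,
            a3=a3_all,
        )

    frames = [build_frame(k) for k in range(n_frames)]

    junctions = []
    for h in range(n_helices - 1):
        group = h % 2
        crossings = cross0 if group == 0 else cross1
        for c in crossings:
            edge = h == 0 or h == n_helices - 2 or c < P // 2 or c > L - 1 - P // 2
            seam_adj = bool(
                seam_index is not None and group == 1 and abs(c - seam_index) <= P
            )
            junctions.append(
                TileJunction(pair=(h, h + 1), index=c, group=group, edge=edge,
                             seam_adjacent=seam_adj)
            )
        if seam_index is not None and group == 0:
            junctions.append(
                TileJunction(pair=(h, h + 1), index=seam_index, group=group,
                             edge=(h == 0 or h == n_helices - 2), seam=True)
            )

    spec = GeneratorSpec(
        kind="tile",
        geometry=geom,
        params={
            "n_helices": n_helices,
            "bp_per_helix": L,
            "junction_spacing": P,
            "weave_amplitude": A,
            "corrugation_twist": corrugation_twist,
            "seam": seam,
            "seam_index": seam_index,
        },
        noise_sigma=noise_sigma,
        n_frames=n_frames,
        seed=seed,
    )
    gt = GroundTruth(
        spec=spec,
        centerlines=centerlines,
        helix_pairs=helix_pairs,
        crossovers={"0": cross0, "1": cross1},
        junctions=junctions,
        groups={str(h): h % 2 for h in range(n_helices - 1)},
    )
    return topo, Trajectory(topology=topo, frames=frames), gt


# ---------------------------------------------------------------------------
# 3D bundle


def _periodic_hat(i, period):
    """Triangular hat of unit height at 0 (mod period), support half a period."""
    m = np.mod(np.asarray(i, float), period)
    m = np.minimum(m, period - m)
    return np.clip(1.0 - m / (period / 4.0), 0.0, None)


def make_bundle(
    rows: int = 4,
    cols: int = 4,
    bp_per_helix: int = 128,
    junction_spacing: int = 32,
    weave_amplitude: float = 1.0,
    stagger: int = +1,
    noise_sigma: float = 0.0,
    n_frames: int = 1,
    seed: int = 0,
    geom: GeometryParams = DEFAULT_GEOMETRY,
) -> tuple:
    """Square-lattice bundle whose helices trace weak helical paths.

    Each helix is drawn toward its four lattice neighbours in turn, at
    junction positions staggered by a quarter period, so interior helix
    centerlines wind once per ``junction_spacing`` base pairs.
    ``stagger=+1`` orders the deflections to produce a left-handed path;
    ``stagger=-1`` a right-handed one.  Returns (Topology, Trajectory,
    GroundTruth); interior helix labels are listed in
    ``ground_truth.extras['interior']``.
    """
    if rows < 2 or cols < 2:
        raise ValueError("rows and cols must be >= 2")
    P = int(junction_spacing)
    L = int(bp_per_helix)
    S = geom.inter_helix_spacing
    A = float(weave_amplitude)
    rng = np.random.default_rng(seed)
    idx = np.arange(L)

    # deflection directions in the (y, z) lattice plane, visited in an
    # order whose rotation sense sets the handedness of the residual path
    plus_y, minus_y = np.array([0.0, 1.0, 0.0]), np.array([0.0, -1.0, 0.0])
    plus_z, minus_z = np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0])
    if stagger >= 0:  # left-handed: y -> -z -> -y -> +z
        order = [plus_y, minus_z, minus_y, plus_z]
    else:  # right-handed: y -> +z -> -y -> -z
        order = [plus_y, plus_z, minus_y, minus_z]

    centerlines = {}
    interior = []
    for r in range(rows):
        for c in range(cols):
            label = f"{r},{c}"
            neigh_present = [c + 1 < cols, r + 1 < rows, c - 1 >= 0, r - 1 >= 0]
            # direction k deflects toward: +y neighbour = next column, etc.
            u = np.zeros((L, 3))
            for k, (d, present) in enumerate(zip(order, neigh_present)):
                if not present:
                    continue
                u += (A / 2.0) * _periodic_hat(idx - k * P / 4.0, P)[:, None] * d[None, :]
            pts = np.column_stack([idx * geom.rise, np.full(L, c * S), np.full(L, r * S)])
            pts = pts + u
            centerlines[label] = pts
            if 0 < r < rows - 1 and 0 < c < cols - 1:
                interior.append(label)

    topo_parts = []
    helix_pairs = {}
    offset = 0
    strand_off = 0
    order_labels = list(centerlines)
    for label in order_labels:
        seq = _random_sequence(L, rng)
        sids, bases, n3, n5 = _duplex_topology(seq, strand_offset=strand_off)
        n3 = np.where(n3 >= 0, n3 + offset, -1)
        n5 = np.where(n5 >= 0, n5 + offset, -1)
        topo_parts.append((sids, bases, n3, n5))
        helix_pairs[label] = [(offset + i, offset + 2 * L - 1 - i) for i in range(L)]
        offset += 2 * L
        strand_off += 2
    topo = Topology(
        np.concatenate([p[0] for p in topo_parts]),
        np.concatenate([p[1] for p in topo_parts]),
        np.concatenate([p[2] for p in topo_parts]),
        np.concatenate([p[3] for p in topo_parts]),
    )

    def build_frame(k):
        pos_all = np.empty((offset, 3))
        a1_all = np.empty((offset, 3))
        a3_all = np.empty((offset, 3))
        base = 0
        for label in order_labels:
            pts = centerlines[label]
            if noise_sigma > 0:
                pts = pts + rng.normal(0.0, noise_sigma, size=pts.shape)
            tangents = np.gradient(pts, axis=0)
            pos_a, a1_a, a3_a, pos_b, a1_b, a3_b = _place_duplex(pts, tangents, geom)
            pos_all[base : base + L] = pos_a
            a1_all[base : base + L] = a1_a
            a3_all[base : base + L] = a3_a
            pos_all[base + L : base + 2 * L] = pos_b[::-1]
            a1_all[base + L : base + 2 * L] = a1_b[::-1]
            a3_all[base + L : base + 2 * L] = a3_b[::-1]
            base += 2 * L
        return Frame(
            time=float(k), box=_default_box(pos_all), positions=pos_all,
            a1=a1_all, a3=a3_all,
        )

    frames = [build_frame(k) for k in range(n_frames)]

    spec = GeneratorSpec(
        kind="bundle",
        geometry=geom,
        params={
            "rows": rows,
            "cols": cols,
            "bp_per_helix": L,
            "junction_spacing": P,
            "weave_amplitude": A,
            "stagger": int(np.sign(stagger) or 1),
        },
        noise_sigma=noise_sigma,
        n_frames=n_frames,
        seed=seed,
    )
    gt = GroundTruth(
        spec=spec,
        centerlines=centerlines,
        helix_pairs=helix_pairs,
        extras={
            "interior": interior,
            "expected_handedness": "left" if stagger >= 0 else "right",
            "expected_period": P,
        },
    )
    return topo, Trajectory(topology=topo, frames=frames), gt
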