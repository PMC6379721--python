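"""Four-way (Holliday) junction geometry and free-energy landscapes.

A stacked four-way junction consists of two quasi-continuous duplexes
("stacks"), each made of two coaxially stacked arms, joined by two strands
that cross from one duplex to the other.  Two angles summarize its shape:

``phi``
    the chiral twist between the two stacked duplexes, measured about the
    axis connecting them.  ``phi = 0`` for a parallel junction (the two
    non-crossing strands run the same way), ``phi = 180`` for an
    anti-parallel junction; values below 180 are left-handed.
``theta``
    the splay of the arms out of the junction plane (the mid-plane that
    separates the two duplexes).  Positive ``theta`` means the arms of each
    duplex bend away from the other duplex, the motif that produces the
    weave pattern in origami sheets.

Angle conventions in detail (these are this package's declared
realizations of the printed anchors):

* Each arm axis is a least-squares line through its base-pair midpoints,
  skipping the ``exclusion`` pairs nearest the junction, oriented to point
  away from the junction.
* The junction plane passes through the midpoints of the exchanging
  strands with its normal along the axis from duplex 1's junction end to
  duplex 2's junction end.
* ``phi1`` is the signed angle (right-hand rule about that normal) from
  the outgoing arm of continuing strand 1 to the outgoing arm of
  continuing strand 2; ``phi2`` is the same for the incoming travel
  directions; ``phi`` is their circular mean mapped to [0, 360).
* ``theta_k`` is the elevation of arm k above the junction plane, signed
  positive away from the partner duplex; ``theta1``/``theta2`` average the
  two arms of each duplex and ``theta = (theta1 + theta2) / 2``.

Free-energy landscapes over (phi, theta) are assembled from harmonically
biased sampling windows in phi with a standard self-consistent
histogram-reweighting (WHAM) iteration; energies are in units of kT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .cg_io import Frame, Trajectory
from .errors import AnalysisError
from .geometry import (
    circular_difference_deg,
    circular_mean_deg,
    signed_angle_deg,
    unit,
    wrap_360,
)

__all__ = [
    "Arm",
    "JunctionSpec",
    "AngleSample",
    "BiasWindow",
    "FreeEnergyLandscape",
    "arm_axis",
    "junction_plane",
    "phi",
    "theta",
    "junction_angles",
    "classify_isomer",
    "bias_energy",
    "wham",
    "marginal_profile",
    "compute_angle_samples",
    "samples_to_dataframe",
]


@dataclass(frozen=True)
class Arm:
    """One duplex arm: ordered base pairs from the junction outward."""

    label: str
    pairs: tuple

    def __post_init__(self):
        object.__setattr__(self, "pairs", tuple((int(i), int(j)) for i, j in self.pairs))

    def midpoints(self, frame: Frame) -> np.ndarray:
        idx = np.array(self.pairs, dtype=int)
        return 0.5 * (frame.positions[idx[:, 0]] + frame.positions[idx[:, 1]])


@dataclass(frozen=True)
class JunctionSpec:
    """The four arms and strand roles defining one junction.

    ``arms`` are ordered (A, B, C, D): A and B are the two arms of duplex 1
    (continuing strand 1 travels A -> B), C and D those of duplex 2.  The
    exchanging strands cross B -> C and D -> A.  ``midpoint_nucleotides``
    are the crossover-flanking nucleotides on the exchanging strands.
    """

    arms: tuple
    exchanging_strands: tuple
    continuing_strands: tuple
    midpoint_nucleotides: tuple

    def to_dict(self) -> dict:
        return {
            "arms": [{"label": a.label, "pairs": list(map(list, a.pairs))} for a in self.arms],
            "exchanging_strands": list(self.exchanging_strands),
            "continuing_strands": list(self.continuing_strands),
            "midpoint_nucleotides": list(self.midpoint_nucleotides),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "JunctionSpec":
        return cls(
            arms=tuple(Arm(a["label"], tuple(map(tuple, a["pairs"]))) for a in d["arms"]),
            exchanging_strands=tuple(d["exchanging_strands"]),
            continuing_strands=tuple(d["continuing_strands"]),
            midpoint_nucleotides=tuple(d["midpoint_nucleotides"]),
        )


@dataclass
class AngleSample:
    phi: float
    theta: float
    phi1: float
    phi2: float
    theta1: float
    theta2: float
    window_id: int | None = None
    frame_index: int = 0
    isomer: str = "I"


@dataclass(frozen=True)
class BiasWindow:
    """Harmonic umbrella window in phi: E = 1/2 k d(phi, center)^2 (kT)."""

    center: float
    stiffness: float
    window_id: int

    def __post_init__(self):
        if self.stiffness < 0:
            raise ValueError("window stiffness must be >= 0")


# ---------------------------------------------------------------------------
# geometry


def arm_axis(
    frame: Frame,
    arm: Arm,
    fit_length: int = 8,
    exclusion: int = 2,
) -> np.ndarray:
    """Unit axis of one arm, oriented away from the junction.

    Least-squares line through the base-pair midpoints of pairs
    ``exclusion .. exclusion + fit_length - 1`` (junction-proximal pairs
    skipped to avoid junction distortion).
    """
    if len(arm.pairs) < fit_length + exclusion:
        raise AnalysisError(
            f"arm {arm.label!r} has {len(arm.pairs)} pairs, needs at least "
            f"{fit_length + exclusion}"
        )
    mids = arm.midpoints(frame)
    sel = mids[exclusion : exclusion + fit_length]
    centred = sel - sel.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    d = vt[0]
    outward = mids[-1] - mids[0]
    if float(np.dot(d, outward)) < 0:
        d = -d
    return d / np.linalg.norm(d)


def _junction_geometry(frame: Frame, spec: JunctionSpec, fit_length: int, exclusion: int):
    """Arm axes, duplex stack directions and the inter-duplex axis."""
    aA, aB, aC, aD = (arm_axis(frame, a, fit_length, exclusion) for a in spec.arms)
    centers = []
    for arms in ((spec.arms[0], spec.arms[1]), (spec.arms[2], spec.arms[3])):
        pts = np.vstack([a.midpoints(frame)[: max(exclusion, 1) + 1] for a in arms])
        centers.append(pts.mean(axis=0))
    sep = centers[1] - centers[0]
    norm = np.linalg.norm(sep)
    if norm < 0.1:
        raise AnalysisError(
            "degenerate junction: duplex stacks coincide (arms collinear?)"
        )
    c = sep / norm
    s1 = unit(aB - aA)
    s2 = unit(aD - aC)
    return {"axes": (aA, aB, aC, aD), "centers": centers, "c": c, "s1": s1, "s2": s2}


def junction_plane(
    frame: Frame,
    spec: JunctionSpec,
    fit_length: int = 8,
    exclusion: int = 2,
) -> tuple:
    """(point, unit normal) of the junction plane.

    The plane passes through the midpoints of the exchanging strands and
    separates the two stacked duplexes; the normal points from duplex 1
    (arms A, B) toward duplex 2 (arms C, D).
    """
    geo = _junction_geometry(frame, spec, fit_length, exclusion)
    point = frame.positions[list(spec.midpoint_nucleotides)].mean(axis=0)
    return point, geo["c"]


def junction_angles(
    frame: Frame,
    spec: JunctionSpec,
    fit_length: int = 8,
    exclusion: int = 2,
) -> AngleSample:
    """Compute (phi1, phi2, phi, theta1, theta2, theta) for one frame."""
    geo = _junction_geometry(frame, spec, fit_length, exclusion)
    aA, aB, aC, aD = geo["axes"]
    c = geo["c"]
    phi1 = wrap_360(signed_angle_deg(aB, aD, c))
    phi2 = wrap_360(signed_angle_deg(-aA, -aC, c))
    phi_val = circular_mean_deg([phi1, phi2])
    thA = -np.degrees(np.arcsin(np.clip(np.dot(aA, c), -1, 1)))
    thB = -np.degrees(np.arcsin(np.clip(np.dot(aB, c), -1, 1)))
    thC = np.degrees(np.arcsin(np.clip(np.dot(aC, c), -1, 1)))
    thD = np.degrees(np.arcsin(np.clip(np.dot(aD, c), -1, 1)))
    th1 = 0.5 * (thA + thB)
    th2 = 0.5 * (thC + thD)
    return AngleSample(
        phi=float(phi_val),
        theta=float(0.5 * (th1 + th2)),
        phi1=float(phi1),
        phi2=float(phi2),
        theta1=float(th1),
        theta2=float(th2),
        isomer=classify_isomer(frame, spec, fit_length=fit_length, exclusion=exclusion),
    )


def phi(frame: Frame, spec: JunctionSpec, fit_length: int = 8, exclusion: int = 2) -> float:
    """Junction twist angle in degrees, in [0, 360)."""
    return junction_angles(frame, spec, fit_length, exclusion).phi


def theta(frame: Frame, spec: JunctionSpec, fit_length: int = 8, exclusion: int = 2) -> float:
    """Junction splay angle in degrees (positive = arms splay apart)."""
    return junction_angles(frame, spec, fit_length, exclusion).theta


def classify_isomer(
    frame: Frame,
    spec: JunctionSpec,
    stacking_threshold: float = -0.8,
    fit_length: int = 8,
    exclusion: int = 2,
) -> str:
    """Label the stacking isomer: 'I' (A-B and C-D coaxial), 'II', or 'open'.

    Two arms are coaxially stacked when their outward axes are anti-aligned
    beyond the threshold (dot < stacking_threshold).
    """
    aA, aB, aC, aD = (arm_axis(frame, a, fit_length, exclusion) for a in spec.arms)

    def stacked(u, v):
        return float(np.dot(u, v)) < stacking_threshold

    if stacked(aA, aB) and stacked(aC, aD):
        return "I"
    if (stacked(aA, aC) and stacked(aB, aD)) or (stacked(aA, aD) and stacked(aB, aC)):
        return "II"
    return "open"


def compute_angle_samples(
    trajectory: Trajectory,
    spec: JunctionSpec,
    window_ids: Sequence[int] | None = None,
    fit_length: int = 8,
    exclusion: int = 2,
) -> list:
    """Angle samples for every frame of a trajectory.

    ``window_ids`` optionally assigns each frame to a bias window.
    """
    out = []
    for k, frame in enumerate(trajectory.frames):
        s = junction_angles(frame, spec, fit_length, exclusion)
        s.frame_index = k
        s.window_id = None if window_ids is None else int(window_ids[k])
        out.append(s)
    return out


def branch_migration_mask(
    trajectory: Trajectory,
    spec: JunctionSpec,
    pair_maps: Sequence,
) -> np.ndarray:
    """True where the junction midpoint pairing matches the design.

    Frames where any midpoint base pair has changed identity (branch
    migration) are flagged False and should be excluded from landscape
    accumulation.
    """
    design_partner = {}
    for arm in spec.arms:
        i, j = arm.pairs[0]
        design_partner[i] = j
        design_partner[j] = i
    ok = np.ones(trajectory.n_frames, dtype=bool)
    for k, pm in enumerate(pair_maps):
        d = pm.as_dict()
        for i, j in design_partner.items():
            if d.get(i) != j:
                ok[k] = False
                break
    return ok


# ---------------------------------------------------------------------------
# biasing and WHAM


def bias_energy(phi_value, window: BiasWindow):
    """Harmonic umbrella energy in kT; the phi difference is circular."""
    d = circular_difference_deg(phi_value, window.center)
    return 0.5 * window.stiffness * np.square(d)


@dataclass
class FreeEnergyLandscape:
    """Binned F(phi, theta) in kT, minimum shifted to zero.

    ``norm_offset`` is the constant such that
    ``sum(exp(-(F + norm_offset)))`` over occupied bins equals 1.
    Unoccupied bins hold ``inf`` and are excluded from every statistic.
    """

    phi_edges: np.ndarray
    theta_edges: np.ndarray
    F: np.ndarray
    counts: np.ndarray
    temperature: float = 296.15
    norm_offset: float = 0.0
    disconnected: bool = False

    @property
    def phi_centers(self) -> np.ndarray:
        return 0.5 * (self.phi_edges[:-1] + self.phi_edges[1:])

    @property
    def theta_centers(self) -> np.ndarray:
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def probability(self) -> np.ndarray:
        p = np.zeros_like(self.F)
        occ = self.occupied
        p[occ] = np.exp(-(self.F[occ] + self.norm_offset))
        return p

    def minimum(self, refine: bool = False) -> tuple:
        """(phi, theta) location of the free-energy minimum.

        With ``refine=False`` the centre of the lowest occupied bin is
        returned.  With ``refine=True`` a count-weighted quadratic surface
        is fit to the bins around the raw minimum and its stationary point
        returned — near a smooth minimum the bin-to-bin statistical noise
        exceeds the sub-kT curvature, so the raw argmin wanders while the
        quadratic fit does not.  Bins with fewer than 5 samples are never
        candidates: a lone tail sample reweighted out of a strongly biased
        window can carry a spuriously low F.
        """
        masked = np.where(self.counts >= min(5, self.counts.max()), self.F, np.inf)
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        raw = (float(self.phi_centers[i]), float(self.theta_centers[j]))
        if not refine:
            return raw
        dphi = self.phi_edges[1] - self.phi_edges[0]
        dth = self.theta_edges[1] - self.theta_edges[0]
        pc, tc = self.phi_centers, self.theta_centers
        sel_i = np.abs(pc - raw[0]) <= 8 * dphi
        sel_j = np.abs(tc - raw[1]) <= 8 * dth
        PP, TT = np.meshgrid(pc[sel_i], tc[sel_j], indexing="ij")
        Fs = self.F[np.ix_(sel_i, sel_j)]
        Ws = self.counts[np.ix_(sel_i, sel_j)]
        good = (Ws > 0) & np.isfinite(Fs)
        if good.sum() < 8:
            return raw
        x = PP[good] - raw[0]
        y = TT[good] - raw[1]
        A = np.column_stack([np.ones_like(x), x, y, x * y, x * x, y * y])
        w = np.sqrt(Ws[good])
        coef, *_ = np.linalg.lstsq(A * w[:, None], Fs[good] * w, rcond=None)
        _, b1, b2, cxy, cxx, cyy = coef
        H = np.array([[2 * cxx, cxy], [cxy, 2 * cyy]])
        if np.linalg.det(H) <= 0 or H[0, 0] <= 0:
            return raw
        sx, sy = np.linalg.solve(H, [-b1, -b2])
        # stationary point must stay inside the fit window
        if abs(sx) > 8 * dphi or abs(sy) > 8 * dth:
            return raw
        return (float(wrap_360(raw[0] + sx)), float(raw[1] + sy))

    def to_dataframe(self) -> pd.DataFrame:
        pc, tc = np.meshgrid(self.phi_centers, self.theta_centers, indexing="ij")
        return pd.DataFrame(
            {
                "phi": pc.ravel(),
                "theta": tc.ravel(),
                "F_kT": self.F.ravel(),
                "count": self.counts.ravel(),
            }
        )

    def save_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# temperature_K = {self.temperature}\n")
            fh.write(f"# norm_offset = {self.norm_offset!r}\n")
            fh.write(f"# disconnected = {self.disconnected}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)


def _default_phi_edges() -> np.ndarray:
    return np.arange(0.0, 360.0 + 1e-9, 2.0)


def _default_theta_edges() -> np.ndarray:
    return np.arange(-90.0, 90.0 + 1e-9, 1.0)


def wham(
    samples: Sequence[AngleSample],
    windows: Sequence[BiasWindow] | None = None,
    phi_edges: np.ndarray | None = None,
    theta_edges: np.ndarray | None = None,
    temperature: float = 296.15,
    tol: float = 1e-7,
    max_iters: int = 100_000,
) -> FreeEnergyLandscape:
    """Unbias windowed (phi, theta) samples into one free-energy landscape.

    Standard self-consistent histogram reweighting: window free-energy
    offsets are iterated to relative change below ``tol``.  Samples whose
    ``window_id`` is None are treated as an unbiased window.
    """
    if len(samples) == 0:
        raise AnalysisError("wham: no samples")
    phi_edges = _default_phi_edges() if phi_edges is None else np.asarray(phi_edges, float)
    theta_edges = (
        _default_theta_edges() if theta_edges is None else np.asarray(theta_edges, float)
    )
    windows = list(windows) if windows else []
    win_by_id = {w.window_id: w for w in windows}

    groups: dict = {}
    for s in samples:
        groups.setdefault(s.window_id, []).append(s)

    phi_centers = 0.5 * (phi_edges[:-1] + phi_edges[1:])
    n_phi, n_theta = phi_centers.size, theta_edges.size - 1
    W = len(groups)
    hists = np.zeros((W, n_phi, n_theta))
    biases = np.zeros((W, n_phi, n_theta))
    keys = sorted(groups, key=lambda k: (k is None, k))
    for w, key in enumerate(keys):
        grp = groups[key]
        ph = np.array([s.phi for s in grp], float)
        th = np.array([s.theta for s in grp], float)
        hists[w], _, _ = np.histogram2d(ph, th, bins=(phi_edges, theta_edges))
        if key is not None:
            if key not in win_by_id:
                raise AnalysisError(f"wham: samples reference unknown window id {key}")
            # Boltzmann-average the bias over each phi bin (the harmonic
            # bias can vary by >1 kT across a bin far from the window
            # centre; evaluating it only at the centre biases F there)
            sub = np.linspace(-0.5, 0.5, 7)[1:-1]
            dphi_bin = phi_edges[1] - phi_edges[0]
            sub_phi = phi_centers[:, None] + sub[None, :] * dphi_bin
            sub_bias = bias_energy(sub_phi, win_by_id[key])
            biases[w] = -logsumexp(-sub_bias, axis=1, b=1.0 / sub.size)[:, None]

    N_tot = hists.sum(axis=0)
    occ = N_tot > 0
    n_w = hists.reshape(W, -1).sum(axis=1)
    B = n_phi * n_theta
    hists_f = hists.reshape(W, B)
    biases_f = biases.reshape(W, B)
    N_tot_f = N_tot.reshape(B)
    occ_f = occ.reshape(B)

    log_n_w = np.log(n_w)
    f_w = np.zeros(W)
    log_N = np.where(occ_f, np.log(np.where(occ_f, N_tot_f, 1.0)), -np.inf)

    log_p = np.full(B, -np.inf)
    for _ in range(int(max_iters)):
        denom = logsumexp(
            (log_n_w + f_w)[:, None] - biases_f, axis=0
        )
        log_p = log_N - denom
        log_p -= logsumexp(log_p[occ_f])
        f_new = -logsumexp(log_p[None, occ_f] - biases_f[:, occ_f], axis=1)
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f_w)) < tol:
            f_w = f_new
            break
        f_w = f_new

    F_raw = np.full(B, np.inf)
    F_raw[occ_f] = -log_p[occ_f]
    f_min = float(F_raw[occ_f].min())
    F = (F_raw - f_min).reshape(n_phi, n_theta)

    disconnected = _windows_disconnected(hists_f, occ_f) if W > 1 else False
    if disconnected:
        warnings.warn(
            "wham: sampling windows do not overlap; landscape is disconnected",
            stacklevel=2,
        )
    return FreeEnergyLandscape(
        phi_edges=phi_edges,
        theta_edges=theta_edges,
        F=F,
        counts=N_tot,
        temperature=temperature,
        norm_offset=f_min,
        disconnected=disconnected,
    )


def _windows_disconnected(hists_f: np.ndarray, occ_f: np.ndarray) -> bool:
    """True when the graph of windows linked by shared occupied bins splits."""
    W = hists_f.shape[0]
    support = hists_f > 0
    adj = [[False] * W for _ in range(W)]
    for a in range(W):
        for b in range(a + 1, W):
            adj[a][b] = adj[b][a] = bool(np.any(support[a] & support[b]))
    seen = {0}
    stack = [0]
    while stack:
        a = stack.pop()
        for b in range(W):
            if adj[a][b] and b not in seen:
                seen.add(b)
                stack.append(b)
    return len(seen) < W


def marginal_profile(
    landscape: FreeEnergyLandscape,
    axis: str = "theta",
    restrict: tuple | None = None,
) -> tuple:
    """1D free-energy profile along ``axis`` (kT, minimum shifted to zero).

    ``restrict = (lo, hi)`` limits the bins summed over on the *other*
    axis, e.g. the theta profile restricted to 160 <= phi <= 180.
    Returns (bin centres, F).
    """
    if axis not in ("phi", "theta"):
        raise ValueError("axis must be 'phi' or 'theta'")
    F = landscape.F
    occ = landscape.occupied
    if axis == "theta":
        other_centers = landscape.phi_centers
        centers = landscape.theta_centers
        F2, occ2 = F, occ
    else:
        other_centers = landscape.theta_centers
        centers = landscape.phi_centers
        F2, occ2 = F.T, occ.T
    if restrict is not None:
        lo, hi = restrict
        keep = (other_centers >= lo) & (other_centers <= hi)
        if not np.any(keep):
            raise AnalysisError("marginal_profile: empty restriction range")
        F2, occ2 = F2[keep], occ2[keep]
    prof = np.full(centers.size, np.inf)
    for k in range(centers.size):
        col_occ = occ2[:, k]
        if np.any(col_occ):
            prof[k] = -logsumexp(-F2[col_occ, k])
    finite = np.isfinite(prof)
    if not np.any(finite):
        raise AnalysisError("marginal_profile: restriction leaves no occupied bins")
    prof[finite] -= prof[finite].min()
    return centers, prof


def samples_to_dataframe(samples: Sequence[AngleSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": [s.frame_index for s in samples],
            "window": [s.window_id for s in samples],
            "phi1": [s.phi1 for s in samples],
            "phi2": [s.phi2 for s in samples],
            "phi": [s.phi for s in samples],
            "theta1": [s.theta1 for s in samples],
            "theta2": [s.theta2 for s in samples],
            "theta": [s.theta for s in samples],
            "isomer": [s.isomer for s in samples],
        }
    )
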