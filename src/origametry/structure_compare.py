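"""Mean structures, rigid superposition, RMSD and helix-path helicity.

Superposition is least-squares optimal over proper rotations only
(reflections are forbidden: molecular chirality must be preserved).  The
mean structure of a trajectory is computed iteratively: every frame is
aligned to the current mean, positions and orientation versors are
averaged, and the mean versors re-orthonormalized (a3 first, then a1
projected perpendicular and normalized).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cg_io import Frame, Trajectory
from .errors import AnalysisError

__all__ = [
    "SuperpositionResult",
    "MeanStructure",
    "RMSDReport",
    "HelicityResult",
    "superpose",
    "mean_structure",
    "rmsd_to_reference",
    "helix_path_helicity",
]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass
class MeanStructure:
    frame: Frame
    spread: np.ndarray
    n_frames: int
    iterations: int


@dataclass
class RMSDReport:
    rmsd: float
    displacements: np.ndarray
    superposition: SuperpositionResult


def superpose(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Optimal proper rotation + translation mapping P onto Q (Kabsch).

    Minimizes sum |R p + t - q|^2 over rotations with det = +1; the
    returned rmsd is sqrt(mean squared residual).  Degenerate (collinear)
    point sets produce a warning but still return the optimal solution.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 corresponding points")
    cP, cQ = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cP, Q - cQ
    H = Pc.T @ Qc
    U, s, Vt = np.linalg.svd(H)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        warnings.warn("superpose: point set is (nearly) collinear", stacklevel=2)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cQ - R @ cP
    resid = Pc @ R.T - Qc
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def mean_structure(
    trajectory: Trajectory,
    tol: float = 1e-6,
    max_iters: int = 20,
    core_mask: np.ndarray | None = None,
) -> MeanStructure:
    """Iteratively aligned average structure of a trajectory.

    ``core_mask`` optionally restricts the superposition to a subset of
    nucleotides (all positions are still averaged and transformed).
    """
    frames = trajectory.frames
    if len(frames) == 0:
        raise AnalysisError("mean_structure: empty trajectory")
    sel = slice(None) if core_mask is None else np.asarray(core_mask, bool)
    mean_pos = frames[0].positions.copy()
    aligned_pos = None
    aligned_a1 = aligned_a3 = None
    it = 0
    for it in range(1, max_iters + 1):
        aligned_pos = np.empty((len(frames),) + mean_pos.shape)
        aligned_a1 = np.empty_like(aligned_pos)
        aligned_a3 = np.empty_like(aligned_pos)
        for k, fr in enumerate(frames):
            sp = superpose(fr.positions[sel], mean_pos[sel])
            aligned_pos[k] = sp.apply(fr.positions)
            aligned_a1[k] = fr.a1 @ sp.rotation.T
            aligned_a3[k] = fr.a3 @ sp.rotation.T
        new_mean = aligned_pos.mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - mean_pos, axis=1)))
        mean_pos = new_mean
        if shift < tol:
            break

    a3m = aligned_a3.mean(axis=0)
    a3m /= np.linalg.norm(a3m, axis=1, keepdims=True)
    a1m = aligned_a1.mean(axis=0)
    a1m -= np.einsum("ij,ij->i", a1m, a3m)[:, None] * a3m
    a1m /= np.linalg.norm(a1m, axis=1, keepdims=True)
    spread = np.sqrt(
        np.mean(np.sum((aligned_pos - mean_pos) ** 2, axis=2), axis=0)
    )
    fr0 = frames[0]
    mean_frame = Frame(
        time=0.0, box=fr0.box.copy(), positions=mean_pos, a1=a1m, a3=a3m
    )
    return MeanStructure(frame=mean_frame, spread=spread, n_frames=len(frames),
                         iterations=it)


def rmsd_to_reference(
    model_points: np.ndarray,
    reference_points: np.ndarray,
    mapping: np.ndarray | None = None,
) -> RMSDReport:
    """Superpose model points onto a reference and report RMSD.

    ``mapping`` optionally pairs model point ``mapping[k]`` with reference
    point ``k``.  Displacement vectors (aligned model - reference) are
    returned for displacement-field plots.
    """
    model = np.asarray(model_points, float)
    ref = np.asarray(reference_points, float)
    if mapping is not None:
        mapping = np.asarray(mapping, int)
        if mapping.size != ref.shape[0]:
            raise ValueError("mapping size must match the reference point count")
        model = model[mapping]
    if model.shape != ref.shape:
        raise ValueError("model and reference point counts differ")
    sp = superpose(model, ref)
    disp = sp.apply(model) - ref
    return RMSDReport(rmsd=sp.rmsd, displacements=disp, superposition=sp)


@dataclass
class HelicityResult:
    handedness: str  # "left" | "right" | "none"
    period_bp: float
    winding_deg_per_bp: float
    residual_rms: float


def helix_path_helicity(
    points: np.ndarray,
    window: int = 32,
    noise_floor: float = 0.05,
) -> HelicityResult:
    """Handedness and period of the helical residual of an axis polyline.

    The local straight axis is a ``window``-point moving average of the
    polyline; the residual is tracked in a fixed frame perpendicular to
    the mean tangent and its winding angle is unwrapped and fit linearly.
    Positive winding while advancing along the path means a right-handed
    helix (the B-DNA sense); ``none`` is returned when the in-plane
    residual RMS amplitude is below ``noise_floor`` (nm).
    """
    pts = np.asarray(points, float)
    n = pts.shape[0]
    if n < 2 * window:
        raise AnalysisError(
            f"polyline has {n} points; need at least two windows ({2 * window})"
        )
    w = int(window)
    kernel = np.ones(w) / w
    base = np.column_stack([np.convolve(pts[:, k], kernel, mode="same") for k in range(3)])
    lo, hi = w // 2, n - w // 2  # interior, where the moving average is full
    resid = pts[lo:hi] - base[lo:hi]

    tangent = pts[-1] - pts[0]
    tangent = tangent / np.linalg.norm(tangent)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(float(np.dot(tangent, ref))) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, tangent) * tangent
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(tangent, e1)

    u = resid @ e1
    v = resid @ e2
    amp = np.hypot(u, v)
    rms = float(np.sqrt(np.mean(amp**2)))
    if rms < noise_floor:
        return HelicityResult("none", np.nan, 0.0, rms)

    good = amp > 0.3 * rms
    if good.sum() < 4:
        return HelicityResult("none", np.nan, 0.0, rms)
    ang = np.unwrap(np.arctan2(v[good], u[good]))
    i = np.arange(resid.shape[0])[good]
    slope = np.polyfit(i, np.degrees(ang), 1)[0]
    if abs(slope) < 1e-9:
        return HelicityResult("none", np.nan, 0.0, rms)
    period = 360.0 / abs(slope)
    handed = "right" if slope > 0 else "left"
    return HelicityResult(handed, float(period), float(slope), rms)
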