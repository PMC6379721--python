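"""Weave and corrugation metrics for origami sheets.

The helix axis of a double helix is the sequence of midpoints between the
two bases of each base pair.  The *weave* is the periodic opening and
closing of the distance between adjacent helix axes, with minima at the
crossovers; the *corrugation* is the much weaker out-of-plane rotation of
the inter-helix vectors around each junction that results from the
junctions' preference for a chiral twist slightly away from perfectly
anti-parallel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cg_io import BasePairMap, Frame, Trajectory
from .errors import AnalysisError

__all__ = [
    "HelixAxis",
    "WeaveProfile",
    "WaveformStats",
    "CorrugationProfile",
    "helix_axes",
    "trajectory_axes",
    "weave_profile",
    "triangular_theta",
    "weave_waveform_stats",
    "corrugation_profile",
]


@dataclass
class HelixAxis:
    """Axis points (bp midpoints, nm) of one helix; invalid indices masked."""

    label: str
    indices: np.ndarray
    points: np.ndarray
    mask: np.ndarray


@dataclass
class WeaveProfile:
    """Per-index mean and standard deviation of an inter-helix distance."""

    pair: tuple
    indices: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    n_frames: int
    group: int | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair": [f"{self.pair[0]}-{self.pair[1]}"] * self.indices.size,
                "index": self.indices,
                "mean_nm": self.mean,
                "std_nm": self.std,
                "n": self.n_frames,
                "group": self.group,
            }
        )


@dataclass
class WaveformStats:
    amplitude: float
    period_bp: float
    maxima: np.ndarray
    minima: np.ndarray
    aperiodic: bool = False


@dataclass
class CorrugationProfile:
    """Signed inter-helix-vector angles around junctions (degrees)."""

    offsets: np.ndarray
    per_junction: np.ndarray  # (n_junctions, n_offsets), NaN where undefined
    junctions: list
    mean_curve: np.ndarray = field(init=False)

    def __post_init__(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.mean_curve = np.nanmean(self.per_junction, axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for j, curve in zip(self.junctions, self.per_junction):
            for o, ang in zip(self.offsets, curve):
                rows.append(
                    {
                        "pair": f"{j.pair[0]}-{j.pair[1]}",
                        "junction_index": j.index,
                        "offset": int(o),
                        "angle_deg": ang,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# helix axes


def helix_axes(
    frame: Frame,
    helix_pairs: Mapping[str, Sequence],
    pair_map: BasePairMap | None = None,
    min_paired: int = 4,
) -> dict:
    """Axis points for each helix of one frame.

    ``helix_pairs`` maps a helix label to its ordered design base pairs
    ``(i, j)``.  When ``pair_map`` (the frame's detected pairing) is given,
    design pairs absent from it are masked out (frayed/melted positions);
    helices with fewer than ``min_paired`` valid positions are dropped
    with a warning.
    """
    detected = pair_map.as_dict() if pair_map is not None else None
    out = {}
    for label, plist in helix_pairs.items():
        idx = np.arange(len(plist))
        pts = np.empty((len(plist), 3))
        mask = np.ones(len(plist), dtype=bool)
        for k, (i, j) in enumerate(plist):
            pts[k] = 0.5 * (frame.positions[i] + frame.positions[j])
            if detected is not None and detected.get(i) != j:
                mask[k] = False
        if mask.sum() < min_paired:
            warnings.warn(
                f"helix {label!r} has only {int(mask.sum())} paired positions; excluded",
                stacklevel=2,
            )
            continue
        pts[~mask] = np.nan
        out[label] = HelixAxis(label=label, indices=idx, points=pts, mask=mask)
    return out


def trajectory_axes(
    trajectory: Trajectory,
    helix_pairs: Mapping[str, Sequence],
    pair_maps: Sequence[BasePairMap] | None = None,
) -> list:
    """Per-frame helix axes for a whole trajectory."""
    out = []
    for k, frame in enumerate(trajectory.frames):
        pm = pair_maps[k] if pair_maps is not None else None
        out.append(helix_axes(frame, helix_pairs, pm))
    return out


def mean_axis_points(axes_frames: Sequence[dict], label: str) -> tuple:
    """Across-frame mean axis points and the all-frames-valid mask."""
    stack = np.array([fr[label].points for fr in axes_frames if label in fr])
    mask = np.all([fr[label].mask for fr in axes_frames if label in fr], axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    return mean, mask


# ---------------------------------------------------------------------------
# weave


def weave_profile(
    axes_frames: Sequence[dict],
    pairs: Sequence[tuple],
    groups: Mapping | None = None,
) -> list:
    """Inter-helix distance statistics for registered adjacent helix pairs.

    Helix pairs are registered index-to-index in the design frame (axis
    arrays share the design bp index).  Per index the mean and standard
    deviation over frames of the Euclidean axis-point distance are
    reported; indices masked in any helix propagate as NaN gaps.
    """
    profiles = []
    for a, b in pairs:
        dists = []
        for fr in axes_frames:
            if a not in fr or b not in fr:
                continue
            ha, hb = fr[a], fr[b]
            n = min(ha.points.shape[0], hb.points.shape[0])
            if ha.points.shape[0] != hb.points.shape[0]:
                warnings.warn(
                    f"pair ({a},{b}): unregistered indices beyond {n} skipped",
                    stacklevel=2,
                )
            d = np.linalg.norm(ha.points[:n] - hb.points[:n], axis=1)
            d[~(ha.mask[:n] & hb.mask[:n])] = np.nan
            dists.append(d)
        if not dists:
            continue
        arr = np.array(dists)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(arr, axis=0)
            std = np.nanstd(arr, axis=0)
        grp = None
        if groups is not None:
            grp = groups.get((a, b), groups.get(f"{a}", None))
        profiles.append(
            WeaveProfile(
                pair=(a, b),
                indices=np.arange(arr.shape[1]),
                mean=mean,
                std=std,
                n_frames=arr.shape[0],
                group=grp,
            )
        )
    return profiles


def triangular_theta(amplitude: float, half_period: float, rise: float = 0.34) -> float:
    """Junction splay angle implied by a perfectly triangular weave.

    A symmetric triangular waveform whose inter-helix distance differs by
    ``amplitude`` (nm) between a minimum and the adjacent maximum, located
    ``half_period`` base-pair steps apart, corresponds to each helix
    deflecting by amplitude/2 over ``half_period * rise`` nm of contour:

        theta = atan((amplitude / 2) / (half_period * rise))   [degrees]
    """
    if amplitude < 0 or half_period <= 0 or rise <= 0:
        raise ValueError("amplitude must be >= 0 and half_period, rise > 0")
    return float(np.degrees(np.arctan2(amplitude / 2.0, half_period * rise)))


def weave_waveform_stats(values: np.ndarray, smooth: bool = True) -> WaveformStats:
    """Amplitude, dominant period and extrema of a weave profile.

    Extrema are located on a 3-point moving average (to suppress jitter)
    but the amplitude uses the raw profile values at those locations:
    amplitude = mean(maxima) - mean(minima).  The dominant period is the
    lag of the highest circular autocorrelation peak.  Profiles with no
    interior extrema are flagged aperiodic.
    """
    x = np.asarray(values, float)
    finite = np.isfinite(x)
    if finite.sum() < 5:
        raise AnalysisError("profile too short")
    xi = x.copy()
    xi[~finite] = np.interp(np.nonzero(~finite)[0], np.nonzero(finite)[0], x[finite])
    s = np.convolve(xi, np.ones(3) / 3.0, mode="same") if smooth else xi
    s[0], s[-1] = xi[0], xi[-1]

    interior = np.arange(1, s.size - 1)
    maxima = interior[(s[interior] > s[interior - 1]) & (s[interior] > s[interior + 1])]
    minima = interior[(s[interior] < s[interior - 1]) & (s[interior] < s[interior + 1])]
    if maxima.size == 0 or minima.size == 0:
        return WaveformStats(
            amplitude=0.0, period_bp=np.nan, maxima=maxima, minima=minima, aperiodic=True
        )

    amplitude = float(np.mean(xi[maxima]) - np.mean(xi[minima]))

    xc = xi - xi.mean()
    n = xc.size
    ac = np.array([np.dot(xc, np.roll(xc, lag)) for lag in range(n // 2 + 1)])
    if ac.size > 2:
        # smallest lag attaining the peak: a pure wave of period p has
        # equal circular autocorrelation at p, 2p, ...
        peak = ac[2:].max()
        lag = int(np.nonzero(ac[2:] >= peak * (1 - 1e-9))[0][0] + 2)
    else:
        lag = n
    return WaveformStats(
        amplitude=amplitude, period_bp=float(lag), maxima=maxima, minima=minima
    )


# ---------------------------------------------------------------------------
# corrugation


def corrugation_profile(
    axes_frames: Sequence[dict],
    junctions: Sequence,
    max_offset: int = 15,
    canonical_only: bool = True,
) -> CorrugationProfile:
    """Signed twist of inter-helix vectors around each junction.

    For every offset from a junction midpoint, the local inter-helix
    vector and the junction-averaged inter-helix vector are projected onto
    the plane perpendicular to the average helix axis at that junction;
    the reported angle is the signed rotation (right-hand rule about the
    axis, which points along increasing bp index) from the junction vector
    to the local one.  Axis points are averaged over frames first.  With
    ``canonical_only`` the edge, seam and seam-adjacent junctions are
    excluded, keeping only junctions with the canonical pattern of
    neighbours.
    """
    js = [j for j in junctions if (not canonical_only) or _canonical(j)]
    if not js:
        raise AnalysisError("no junctions left after canonical filtering")
    offsets = np.arange(-max_offset, max_offset + 1)
    curves = np.full((len(js), offsets.size), np.nan)

    mean_pts: dict = {}
    masks: dict = {}
    for j in js:
        for lbl in j.pair:
            key = str(lbl)
            if key not in mean_pts:
                mean_pts[key], masks[key] = mean_axis_points(axes_frames, key)

    for row, j in enumerate(js):
        a, b = (str(x) for x in j.pair)
        pa, pb = mean_pts[a], mean_pts[b]
        mask = masks[a] & masks[b]
        L = min(pa.shape[0], pb.shape[0])
        c = int(j.index)
        if c - 1 < 0 or c + 1 >= L or not (mask[c - 1] and mask[c] and mask[c + 1]):
            continue
        # average helix axis at the junction: mean central-difference
        # tangent of both helices, oriented along increasing index
        tan = 0.5 * ((pa[c + 1] - pa[c - 1]) + (pb[c + 1] - pb[c - 1]))
        axis = tan / np.linalg.norm(tan)
        v = pb[:L] - pa[:L]
        v_junc = v[c - 1 : c + 2].mean(axis=0)
        v_junc_p = v_junc - np.dot(v_junc, axis) * axis
        nj = np.linalg.norm(v_junc_p)
        if nj == 0:
            continue
        v_junc_p = v_junc_p / nj
        for k, o in enumerate(offsets):
            i = c + int(o)
            if i < 0 or i >= L or not mask[i]:
                continue
            vp = v[i] - np.dot(v[i], axis) * axis
            nv = np.linalg.norm(vp)
            if nv == 0:
                continue
            vp = vp / nv
            sin_a = float(np.dot(np.cross(v_junc_p, vp), axis))
            cos_a = float(np.dot(v_junc_p, vp))
            curves[row, k] = np.degrees(np.arctan2(sin_a, cos_a))
    return CorrugationProfile(offsets=offsets, per_junction=curves, junctions=js)


def _canonical(j) -> bool:
    if hasattr(j, "canonical"):
        return bool(j.canonical)
    return not (getattr(j, "edge", False) or getattr(j, "seam", False)
                or getattr(j, "seam_adjacent", False))
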