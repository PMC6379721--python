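"""Shared geometric conventions and small vector helpers.

All coordinates inside the package are in nanometres.  The only place the
oxDNA simulation length unit (0.8518 nm) appears is at the file I/O boundary
in :mod:`origametry.cg_io`.

The idealized B-form placement used by the builders puts the two backbone
sites of a base pair on a cylinder of radius ``backbone_radius`` around the
helix axis, diametrically opposed, with the nucleotide centre and the base
interaction site displaced from the backbone toward the axis by
``BASE_SITE_OFFSET_NM``.  With the default radius the two base sites of a
pair end up ~0.16 nm apart, well inside the pairing cutoff used by
geometric base-pair detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: oxDNA simulation length unit expressed in nanometres.
OXDNA_LENGTH_UNIT_NM = 0.8518

#: Distance from a nucleotide's position to its base interaction site,
#: along the base versor a1 (0.4 oxDNA length units).
BASE_SITE_OFFSET_NM = 0.4 * OXDNA_LENGTH_UNIT_NM


@dataclass(frozen=True)
class GeometryParams:
    """Idealized double-helix geometry used by builders and generators.

    rise
        axial rise per base pair, nm.
    pitch
        base pairs per helical turn (untwisted-origami convention, ~10.5).
    backbone_radius
        radius of the backbone-site cylinder, nm.
    inter_helix_spacing
        centre-to-centre distance between neighbouring helices on the
        design lattice, nm.
    """

    rise: float = 0.34
    pitch: float = 10.5
    backbone_radius: float = 0.6
    inter_helix_spacing: float = 2.5

    @property
    def position_radius(self) -> float:
        """Radius of the nucleotide-centre cylinder, nm."""
        return self.backbone_radius - BASE_SITE_OFFSET_NM

    @property
    def twist_per_bp(self) -> float:
        """Helical twist per base-pair step, radians."""
        return 2.0 * np.pi / self.pitch

    def with_(self, **kwargs) -> "GeometryParams":
        return replace(self, **kwargs)


DEFAULT_GEOMETRY = GeometryParams()


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize the last axis of ``v``; raises on zero vectors."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n == 0.0):
        raise ValueError("cannot normalize zero vector")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    a = unit(axis)
    x, y, z = a
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def perpendicular_component(v: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Component of ``v`` perpendicular to the unit vector ``axis``."""
    axis = unit(axis)
    v = np.asarray(v, dtype=float)
    return v - np.outer(np.atleast_2d(v) @ axis, axis).reshape(v.shape)


def signed_angle_deg(u: np.ndarray, v: np.ndarray, axis: np.ndarray) -> float:
    """Signed angle (degrees) from ``u`` to ``v`` about ``axis``, in (-180, 180].

    Both vectors are first projected onto the plane perpendicular to
    ``axis``; the sign follows the right-hand rule about ``axis``.
    """
    axis = unit(axis)
    up = perpendicular_component(np.asarray(u, float), axis)
    vp = perpendicular_component(np.asarray(v, float), axis)
    nu, nv = np.linalg.norm(up), np.linalg.norm(vp)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("vector is parallel to the rotation axis")
    up, vp = up / nu, vp / nv
    s = float(np.dot(np.cross(up, vp), axis))
    c = float(np.dot(up, vp))
    ang = np.degrees(np.arctan2(s, c))
    return 180.0 if ang == -180.0 else ang


def wrap_360(angle_deg) -> np.ndarray | float:
    """Map angles to [0, 360)."""
    return np.mod(angle_deg, 360.0)


def circular_difference_deg(a, b):
    """Minimal signed circular difference a - b, in (-180, 180]."""
    d = np.mod(np.asarray(a, float) - np.asarray(b, float) + 180.0, 360.0) - 180.0
    return np.where(d == -180.0, 180.0, d) if np.ndim(d) else (180.0 if d == -180.0 else float(d))


def circular_mean_deg(angles_deg) -> float:
    """Circular mean of angles in degrees, mapped to [0, 360)."""
    a = np.radians(np.asarray(angles_deg, float))
    m = np.degrees(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a))))
    return float(wrap_360(m))


def fit_line_direction(points: np.ndarray) -> np.ndarray:
    """Least-squares direction of a 3D point cloud (first principal axis).

    The returned unit vector's overall sign is arbitrary.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("need at least two points to fit a line")
    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    return vt[0]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
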