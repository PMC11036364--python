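"""Six-sided crystal template geometry.

A projected faceted crystal (the 2D outline of a needle-like habit such as
beta-L-glutamic acid resting on its largest face) is modelled as the
intersection of three pairs of parallel half-planes.  Each pair shares a
normal direction; the two half-planes of a pair sit at independent distances
from a common centre, so asymmetric growth about the centre is representable
and a face may "grow out" of the outline entirely.

Coordinate convention
---------------------
Pixel centres sit at integer ``(x, y) = (column, row)``; x runs rightward and
y runs downward, as is usual for images.  Angles are measured
counterclockwise in the mathematically oriented frame ``(x, -y)``, so a
reported angle of +90 degrees points toward the top of the image.  The unit
normal for angle ``phi`` is therefore ``(cos phi, -sin phi)`` in (x, y)
components.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "CrystalAngles",
    "HexTemplate",
    "face_directions",
    "recenter",
    "half_turn",
    "render_soft_mask",
    "render_hard_mask",
    "polygon_vertices",
    "polygon_interior_angles",
    "width_to_normal_distance",
]


@dataclass(frozen=True)
class CrystalAngles:
    """Interfacial angles defining a compound's projected hexagon.

    Defaults are those of beta-L-glutamic acid: 108 degrees between the two
    {101} capping faces at the needle tip, 126 degrees between a capping and
    a prismatic face in projection, and 78 degrees between the (021) and
    (02-1) faces in 3D (used for the out-of-plane width correction).

    For a closed mirror-symmetric hexagon the interior angles are
    {tip, cp, cp} repeated twice, so ``2*capping_capping +
    4*capping_prismatic == 720``.
    """

    capping_capping: float = 108.0
    capping_prismatic: float = 126.0
    prismatic_pair_3d: float = 78.0

    def rel_angles(self) -> tuple[float, float]:
        """Angles between the prismatic normal and the two capping normals.

        Adjacent faces with interior angle ``capping_prismatic`` have normals
        separated by ``180 - capping_prismatic`` degrees (54 for the default
        126), one on each side of the prismatic normal.
        """
        a = 180.0 - self.capping_prismatic
        return (a, -a)


@dataclass
class HexTemplate:
    """Parameters of a candidate hexagon.

    Attributes
    ----------
    center : (2,) array
        Centre point in image coordinates (x=col, y=row), pixels.
    theta1 : float
        Orientation (degrees) of the first face-normal direction, measured
        counterclockwise in (x, -y).  By convention direction 1 is the
        prismatic (short-distance) pair.
    rel_angles : (2,) tuple
        Offsets (degrees) added to ``theta1`` to obtain directions 2 and 3.
        Fixed during optimisation.
    dists : (3, 2) array
        Non-negative signed-projection bounds, pixels: ``dists[i, 0]`` along
        +normal i and ``dists[i, 1]`` along -normal i.
    """

    center: np.ndarray
    theta1: float
    dists: np.ndarray
    rel_angles: tuple[float, float] = field(
        default_factory=lambda: CrystalAngles().rel_angles()
    )

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.dists = np.asarray(self.dists, dtype=float).reshape(3, 2)
        if self.center.shape != (2,):
            raise ValueError("center must be a 2-vector")
        if np.any(self.dists < 0):
            raise ValueError("all six distances must be >= 0")

    def copy(self) -> "HexTemplate":
        return replace(
            self, center=self.center.copy(), dists=self.dists.copy()
        )

    @property
    def direction_angles(self) -> np.ndarray:
        """The three normal-direction angles (degrees)."""
        return self.theta1 + np.array([0.0, *self.rel_angles])


def _unit_normal(phi_deg: np.ndarray) -> np.ndarray:
    """Unit normal(s) for angle(s) in degrees, (x, y)=(col, row) components."""
    phi = np.deg2rad(np.asarray(phi_deg, dtype=float))
    return np.stack([np.cos(phi), -np.sin(phi)], axis=-1)


def recenter(t: HexTemplate, new_center: np.ndarray) -> HexTemplate:
    """Equivalent template expressed about a different centre point.

    The centre is a gauge choice: shifting it by ``delta`` while adding
    ``-n_i . delta`` to each +distance and ``+n_i . delta`` to each
    -distance leaves all six face lines (and hence the polygon) unchanged.
    Useful for comparing fits to a ground truth parametrised about another
    centre.  Raises if a resulting distance would go negative (centre
    outside the band of a face pair).
    """
    new_center = np.asarray(new_center, dtype=float)
    delta = new_center - t.center
    n = _unit_normal(t.direction_angles)  # (3, 2)
    shift = n @ delta  # (3,)
    dists = t.dists + np.stack([-shift, shift], axis=1)
    if np.any(dists < 0):
        raise ValueError("new centre lies outside a face-pair band")
    return replace(t.copy(), center=new_center, dists=dists)


def half_turn(t: HexTemplate) -> HexTemplate:
    """Equivalent template with theta1 shifted by 180 degrees.

    Rotating the first normal half a turn negates all six normals, so the
    same hexagon is described with the +/- distances swapped in each pair.
    """
    return replace(
        t.copy(), theta1=t.theta1 - 180.0, dists=t.dists[:, ::-1].copy()
    )


def face_directions(t: HexTemplate) -> np.ndarray:
    """Six unit normals, one per half-plane.

    Returns a (6, 2) array ordered ``[+n1, -n1, +n2, -n2, +n3, -n3]``,
    matching the flattened order of ``t.dists``.
    """
    n = _unit_normal(t.direction_angles)  # (3, 2)
    return np.stack([n, -n], axis=1).reshape(6, 2)


def _signed_margins(t: HexTemplate, points: np.ndarray) -> np.ndarray:
    """Margins ``d_k - n_k . (p - c)`` for each half-plane k.

    ``points`` is (..., 2); returns (..., 6).  Positive margin = inside.
    """
    offsets = np.asarray(points, dtype=float) - t.center
    normals = face_directions(t)  # (6, 2)
    proj = offsets @ normals.T  # (..., 6)
    return t.dists.reshape(6) - proj


def _pixel_grid(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    return np.stack([xs, ys], axis=-1).astype(float)


def render_soft_mask(
    t: HexTemplate, shape: tuple[int, int], sharpness: float
) -> np.ndarray:
    """Differentiable soft rasterisation of the template.

    Each half-plane contributes a logistic factor
    ``sigma(sharpness * (d_k - n_k . (x - c)))``; the mask is the product of
    the six factors (the intersection of the three parallel-line bands).
    Values lie in (0, 1) and are smooth in center, theta1 and dists.
    """
    if sharpness <= 0:
        raise ValueError("sharpness must be positive")
    margins = _signed_margins(t, _pixel_grid(shape))  # (h, w, 6)
    # log-sigmoid product, computed stably
    z = sharpness * margins
    log_f = -np.logaddexp(0.0, -z)
    return np.exp(log_f.sum(axis=-1))


def render_hard_mask(t: HexTemplate, shape: tuple[int, int]) -> np.ndarray:
    """Binary rasterisation: pixel centres inside all six half-planes."""
    margins = _signed_margins(t, _pixel_grid(shape))
    return (margins >= 0).all(axis=-1).astype(np.uint8)


def polygon_vertices(
    t: HexTemplate, tol: float = 1e-9, min_edge: float = 1e-6
) -> np.ndarray:
    """Vertices of the half-plane intersection, counterclockwise.

    Enumerates all pairwise line intersections, keeps those feasible for
    every half-plane, merges vertices closer than ``min_edge`` and orders
    the rest counterclockwise (in the (x, -y) sense) around their mean.
    Faces whose line never touches the feasible region ("grown out")
    contribute no vertex pair, so the result can have fewer than six
    vertices; an empty (0, 2) array is returned for an empty intersection.
    ``min_edge`` in pixels lets callers ignore sub-resolution slivers when
    counting sides of a fitted shape.
    """
    normals = face_directions(t)
    d = t.dists.reshape(6)
    scale = max(1.0, float(d.max()))
    pts = []
    for i in range(6):
        for j in range(i + 1, 6):
            a = np.array([normals[i], normals[j]])
            det = np.linalg.det(a)
            if abs(det) < 1e-12:
                continue  # parallel pair
            v = np.linalg.solve(a, np.array([d[i], d[j]]))
            margins = d - normals @ v
            if margins.min() >= -tol * scale - 1e-12:
                pts.append(t.center + v)
    if not pts:
        return np.empty((0, 2))
    pts_arr = np.array(pts)
    # merge near-coincident intersection points
    uniq: list[np.ndarray] = []
    for p in pts_arr:
        if not any(np.hypot(*(p - q)) < max(min_edge, 1e-9 * scale)
                   for q in uniq):
            uniq.append(p)
    if len(uniq) < 2:
        return np.array(uniq).reshape(-1, 2)
    pts_arr = np.array(uniq)
    c = pts_arr.mean(axis=0)
    # counterclockwise in (x, -y): sort by atan2(-(y-cy), x-cx)
    ang = np.arctan2(-(pts_arr[:, 1] - c[1]), pts_arr[:, 0] - c[0])
    return pts_arr[np.argsort(ang)]


def polygon_interior_angles(vertices: np.ndarray) -> np.ndarray:
    """Interior angles (degrees) of a convex polygon given CCW vertices."""
    v = np.asarray(vertices, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("need at least 3 vertices")
    angles = np.empty(n)
    for k in range(n):
        a = v[(k - 1) % n] - v[k]
        b = v[(k + 1) % n] - v[k]
        cosang = (a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
        angles[k] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return angles


def width_to_normal_distance(
    projected_width: float, interfacial_angle_3d: float
) -> float:
    """Out-of-plane tilt correction for the prismatic face pair.

    When the crystal rests on its {010} face the prismatic faces are tilted
    symmetrically out of the viewing plane by half the 3D interfacial angle
    between them, so the normal distance is the projected width scaled by
    ``sin(angle / 2)``.  This trigonometric construction is our own; it
    reduces to the identity at 180 degrees (faces in-plane).
    """
    if not 0.0 < interfacial_angle_3d <= 180.0:
        raise ValueError("interfacial angle must lie in (0, 180] degrees")
    return projected_width * np.sin(np.deg2rad(interfacial_angle_3d) / 2.0)
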