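"""Equal-area discretization of the frontal hemisphere and rigid rotations.

The localization model treats target direction as a discrete hypothesis
space: the frontal hemisphere is split into ``n_cells`` cells of identical
solid angle, so a uniform posterior over cells carries exactly
``log2(n_cells)`` bits of uncertainty.  Ear movements are modelled as rigid
rotations of a directional gain field, resampled on the same partition.

Coordinate convention: azimuth is the horizontal angle (degrees, positive to
the right), elevation the vertical angle (degrees, positive up);
``(0, 0)`` is straight ahead.  The unit vector of a direction is
``(cos el cos az, cos el sin az, sin el)`` with x forward, y right, z up.
Rotations by ``(d_az, d_el)`` are intrinsic azimuth-then-elevation turns, so
the forward direction maps onto ``(d_az, d_el)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Direction",
    "SpherePartition",
    "partition_hemisphere",
    "angular_distance",
    "rotation_matrix",
    "rotate_field",
]


@dataclass(frozen=True)
class Direction:
    """A direction in the frontal hemisphere (degrees)."""

    azimuth_deg: float
    elevation_deg: float

    def unit_vector(self) -> np.ndarray:
        az = np.deg2rad(self.azimuth_deg)
        el = np.deg2rad(self.elevation_deg)
        return np.array(
            [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
        )

    @staticmethod
    def from_vector(v: np.ndarray) -> "Direction":
        v = np.asarray(v, dtype=float)
        v = v / np.linalg.norm(v)
        el = np.rad2deg(np.arcsin(np.clip(v[2], -1.0, 1.0)))
        az = np.rad2deg(np.arctan2(v[1], v[0]))
        return Direction(float(az), float(el))


@dataclass(frozen=True)
class SpherePartition:
    """Equal-area partition of the frontal hemisphere.

    Attributes
    ----------
    n_cells:
        Number of cells; every cell has solid angle ``2*pi / n_cells``.
    cell_centers:
        ``(n_cells, 2)`` array of (azimuth, elevation) in degrees.
    """

    n_cells: int
    cell_centers: np.ndarray

    @property
    def cell_solid_angle_sr(self) -> float:
        return 2.0 * np.pi / self.n_cells

    @property
    def unit_vectors(self) -> np.ndarray:
        az = np.deg2rad(self.cell_centers[:, 0])
        el = np.deg2rad(self.cell_centers[:, 1])
        return np.column_stack(
            [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
        )

    def nearest_cell(self, vectors: np.ndarray) -> np.ndarray:
        """Index of the cell center closest (great-circle) to each vector."""
        vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
        return np.argmax(vectors @ self.unit_vectors.T, axis=1)

    def __eq__(self, other: object) -> bool:  # array field needs custom eq
        if not isinstance(other, SpherePartition):
            return NotImplemented
        return self.n_cells == other.n_cells and np.array_equal(
            self.cell_centers, other.cell_centers
        )


def partition_hemisphere(n_cells: int) -> SpherePartition:
    """Split the frontal hemisphere into ``n_cells`` equal-area cells.

    A zonal construction: a polar cap around the forward axis, then rings
    (collars) of cells toward the rim, every cell with solid angle
    ``2*pi/n_cells`` exactly.  Deterministic for fixed ``n_cells``.
    """
    if not isinstance(n_cells, (int, np.integer)) or n_cells < 1:
        raise ValueError(f"n_cells must be a positive integer, got {n_cells!r}")
    n_cells = int(n_cells)
    if n_cells == 1:
        return SpherePartition(1, np.array([[0.0, 0.0]]))

    # polar angle theta measured from the forward axis; cap of one cell
    cap_cos = 1.0 - 1.0 / n_cells  # area 2*pi*(1-cos) = 2*pi/n
    theta_cap = np.arccos(cap_cos)
    ideal_width = np.sqrt(2.0 * np.pi / n_cells)
    n_collars = max(1, int(round((np.pi / 2.0 - theta_cap) / ideal_width)))

    # distribute the remaining n-1 cells over collars in proportion to
    # collar area, rounding cumulatively so the total is conserved
    edges = np.linspace(theta_cap, np.pi / 2.0, n_collars + 1)
    areas = 2.0 * np.pi * (np.cos(edges[:-1]) - np.cos(edges[1:]))
    ideal = (n_cells - 1) * areas / areas.sum()
    counts = np.zeros(n_collars, dtype=int)
    carry = 0.0
    for i in range(n_collars):
        want = ideal[i] + carry
        counts[i] = max(1, int(round(want)))
        carry = want - counts[i]
    counts[-1] += (n_cells - 1) - counts.sum()

    centers = [(0.0, 0.0)]
    cum = 0
    cos_prev = cap_cos
    for i, m in enumerate(counts):
        cum += m
        cos_next = 1.0 - (1 + cum) / n_cells  # exact equal-area boundary
        theta_mid = np.arccos(0.5 * (cos_prev + cos_next))
        phi0 = (0.5 * i % 1.0) * 2.0 * np.pi / m  # stagger successive rings
        for j in range(m):
            phi = phi0 + 2.0 * np.pi * j / m
            v = np.array(
                [
                    np.cos(theta_mid),
                    np.sin(theta_mid) * np.cos(phi),
                    np.sin(theta_mid) * np.sin(phi),
                ]
            )
            d = Direction.from_vector(v)
            centers.append((d.azimuth_deg, d.elevation_deg))
        cos_prev = cos_next
    return SpherePartition(n_cells, np.array(centers))


def angular_distance(a: Direction, b: Direction) -> float:
    """Great-circle angle between two directions, degrees in [0, 180]."""
    dot = float(np.dot(a.unit_vector(), b.unit_vector()))
    return float(np.rad2deg(np.arccos(np.clip(dot, -1.0, 1.0))))


def rotation_matrix(d_az_deg: float, d_el_deg: float) -> np.ndarray:
    """Intrinsic azimuth-then-elevation rotation matrix.

    Maps the forward unit vector onto ``Direction(d_az, d_el)``.
    """
    a = np.deg2rad(d_az_deg)
    e = np.deg2rad(d_el_deg)
    rz = np.array(
        [[np.cos(a), -np.sin(a), 0.0], [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]]
    )
    ry = np.array(
        [[np.cos(e), 0.0, -np.sin(e)], [0.0, 1.0, 0.0], [np.sin(e), 0.0, np.cos(e)]]
    )
    return rz @ ry


def rotate_field(field, rot: tuple[float, float], method: str = "nearest"):
    """Rigidly rotate a directional field by ``(d_az, d_el)`` degrees.

    The returned field, sampled at direction ``d``, equals the input field at
    the back-rotated direction.  Directions that rotate out of the frontal
    hemisphere take the field's floor value.

    Parameters
    ----------
    field:
        A :class:`~pinnasonar.fields.DirectionalField`.
    rot:
        ``(d_az, d_el)`` rotation in degrees.
    method:
        ``"nearest"`` (default, deterministic nearest-cell lookup) or
        ``"idw3"`` (inverse-distance weights over the 3 nearest centers).
    """
    part: SpherePartition = field.partition
    rinv = rotation_matrix(*rot).T  # orthonormal: inverse = transpose
    back = part.unit_vectors @ rinv.T
    gain = np.asarray(field.gain_db, dtype=float)
    if method == "nearest":
        idx = part.nearest_cell(back)
        new_gain = gain[idx]
    elif method == "idw3":
        cosines = np.clip(back @ part.unit_vectors.T, -1.0, 1.0)
        order = np.argsort(-cosines, axis=1)[:, :3]
        ang = np.arccos(np.take_along_axis(cosines, order, axis=1))
        w = 1.0 / np.maximum(ang, 1e-12)
        w /= w.sum(axis=1, keepdims=True)
        new_gain = np.sum(gain[order] * w, axis=1)
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    behind = back[:, 0] < 0.0  # rotated out of the frontal hemisphere
    new_gain = np.where(behind, field.floor_db, new_gain)
    return dataclasses.replace(field, gain_db=new_gain)
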