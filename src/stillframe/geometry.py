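"""Laboratory-frame geometry for still-shot diffraction.

Conventions
-----------
Right-handed laboratory frame with the incident beam travelling along -z.
The flat detector lies in the plane z = -distance, with its fast/slow axes
parallel to lab x/y.  Reciprocal space is described by the 3x3 orientation
matrix ``A`` whose columns are the reciprocal cell vectors a*, b*, c* in the
lab frame, so that a reflection with Miller index ``h`` sits at ``q = A h``
(units: inverse angstroms).  The reference (unrotated) setting of the
reciprocal basis is the Busing-Levy convention: a* along lab x, b* in the
x-y plane.  Angles are degrees at every public interface and radians
internally; lengths are angstroms (reciprocal: 1/angstrom) and detector
coordinates millimetres relative to the beam centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Beam",
    "UnitCell",
    "CrystalModel",
    "Detector",
    "SpotObservation",
    "AssignmentResult",
    "build_a_matrix",
    "b_matrix",
    "cell_from_a",
    "q_from_hkl",
    "project_to_detector",
    "project_batch",
    "backproject_to_q",
    "assign_indices",
    "misorientation_angle",
    "point_group_rotations",
    "NonIntersectingRay",
]

_UNIT_TOL = 1e-12


class NonIntersectingRay(ValueError):
    """Raised when a diffracted ray does not hit the detector plane."""


def _as_unit(v: Sequence[float]) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    n = np.linalg.norm(a)
    if abs(n - 1.0) > 1e-9:
        raise ValueError(f"expected a unit vector, got |v| = {n!r}")
    return a / n


@dataclass(frozen=True)
class Beam:
    """Incident beam: unit direction ``s0_hat`` and wavelength (angstroms)."""

    wavelength: float
    s0_hat: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -1.0]))

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        object.__setattr__(self, "s0_hat", _as_unit(self.s0_hat))

    @property
    def s0(self) -> np.ndarray:
        """Incident wavevector s0 = s0_hat / wavelength (1/angstrom)."""
        return self.s0_hat / self.wavelength

    @property
    def k(self) -> float:
        """Ewald sphere radius 1/wavelength."""
        return 1.0 / self.wavelength


@dataclass(frozen=True)
class UnitCell:
    """Direct-space unit cell: lengths in angstroms, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.volume_factor() <= 0:
            raise ValueError("degenerate cell: metric tensor not positive definite")

    def volume_factor(self) -> float:
        """The dimensionless factor V / (a b c)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return math.sqrt(arg) if arg > 0 else arg

    @property
    def volume(self) -> float:
        return self.a * self.b * self.c * self.volume_factor()

    def metric(self) -> np.ndarray:
        """Real-space metric tensor G (angstrom^2)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        a, b, c = self.a, self.b, self.c
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


def b_matrix(cell: UnitCell) -> np.ndarray:
    """Reciprocal basis in the Busing-Levy reference setting.

    Columns are a*, b*, c* (1/angstrom) with a* along lab x and b* in the
    x-y plane.  Any fixed convention would do, since only the product
    A = R B is observable; this one is the crystallographic standard.
    """
    a, b, c = cell.a, cell.b, cell.c
    cos_alpha = math.cos(math.radians(cell.alpha))
    V = cell.volume
    sa, sb, sg = (
        math.sin(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma)
    )
    ca, cb, cg = (
        math.cos(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma)
    )
    a_s = b * c * sa / V
    b_s = a * c * sb / V
    c_s = a * b * sg / V
    cb_s = (ca * cg - cb) / (sa * sg)
    cg_s = (ca * cb - cg) / (sa * sb)
    sb_s = math.sqrt(max(0.0, 1.0 - cb_s * cb_s))
    sg_s = math.sqrt(max(0.0, 1.0 - cg_s * cg_s))
    return np.array(
        [
            [a_s, b_s * cg_s, c_s * cb_s],
            [0.0, b_s * sg_s, -c_s * sb_s * cos_alpha],
            [0.0, 0.0, 1.0 / c],
        ]
    )


def cell_from_a(A: np.ndarray) -> UnitCell:
    """Recover the direct cell from an orientation matrix (columns a*, b*, c*)."""
    A = np.asarray(A, dtype=float)
    g_star = A.T @ A
    g = np.linalg.inv(g_star)
    a, b, c = (math.sqrt(g[i, i]) for i in range(3))
    alpha = math.degrees(math.acos(g[1, 2] / (b * c)))
    beta = math.degrees(math.acos(g[0, 2] / (a * c)))
    gamma = math.degrees(math.acos(g[0, 1] / (a * b)))
    return UnitCell(a, b, c, alpha, beta, gamma)


@dataclass(frozen=True)
class CrystalModel:
    """Reciprocal orientation matrix ``A`` (columns a*, b*, c*) plus symmetry tag."""

    A: np.ndarray
    symmetry_tag: str = "triclinic"

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.shape != (3, 3):
            raise ValueError("A must be a 3x3 matrix")
        if abs(np.linalg.det(A)) < 1e-30:
            raise ValueError("A must be invertible")
        object.__setattr__(self, "A", A)

    @property
    def cell(self) -> UnitCell:
        return cell_from_a(self.A)

    @property
    def orientation(self) -> np.ndarray:
        """Proper rotation R with A = R B, extracted by polar decomposition."""
        B = b_matrix(self.cell)
        M = self.A @ np.linalg.inv(B)
        U, _, Vt = np.linalg.svd(M)
        R = U @ Vt
        if np.linalg.det(R) < 0:
            U[:, -1] *= -1.0
            R = U @ Vt
        return R


def build_a_matrix(cell: UnitCell, orientation) -> CrystalModel:
    """A = R B with B the reference-setting reciprocal basis."""
    if isinstance(orientation, Rotation):
        R = orientation.as_matrix()
    else:
        R = np.asarray(orientation, dtype=float)
    if R.shape != (3, 3) or abs(np.linalg.det(R) - 1.0) > 1e-8:
        raise ValueError("orientation must be a proper rotation matrix")
    return CrystalModel(R @ b_matrix(cell))


@dataclass(frozen=True)
class Detector:
    """Flat detector in the plane z = -distance, axes parallel to lab x/y.

    ``beam_center`` is the (x, y) position of the direct-beam intercept
    measured from the detector's low corner, in millimetres, so a spot at
    detector coordinate (x, y) relative to the beam centre is on the panel
    iff 0 <= x + beam_center[0] <= n_fast * pixel_size (same for slow).
    """

    distance: float
    pixel_size: float
    n_fast: int
    n_slow: int
    beam_center: tuple[float, float]

    def __post_init__(self) -> None:
        if self.distance <= 0 or self.pixel_size <= 0:
            raise ValueError("distance and pixel_size must be positive")

    def contains(self, x_mm: float, y_mm: float) -> bool:
        fx = x_mm + self.beam_center[0]
        fy = y_mm + self.beam_center[1]
        return (
            0.0 <= fx <= self.n_fast * self.pixel_size
            and 0.0 <= fy <= self.n_slow * self.pixel_size
        )

    def contains_batch(self, xy: np.ndarray) -> np.ndarray:
        fx = xy[:, 0] + self.beam_center[0]
        fy = xy[:, 1] + self.beam_center[1]
        return (
            (fx >= 0.0)
            & (fx <= self.n_fast * self.pixel_size)
            & (fy >= 0.0)
            & (fy <= self.n_slow * self.pixel_size)
        )


@dataclass
class SpotObservation:
    """One detected spot centroid: (x, y) in mm relative to the beam centre."""

    position: tuple[float, float]
    intensity: float | None = None
    hkl: tuple[int, int, int] | None = None
    extras: dict = field(default_factory=dict)

    @property
    def assigned(self) -> bool:
        return self.hkl is not None


def q_from_hkl(model: CrystalModel, hkl) -> np.ndarray:
    """Reciprocal-space lab coordinates q = A h (batched over leading axis)."""
    h = np.asarray(hkl, dtype=float)
    if h.ndim == 1:
        return model.A @ h
    return h @ model.A.T


def project_to_detector(s1, beam: Beam, det: Detector) -> tuple[float, float]:
    """Intersect the ray from the sample along ``s1`` with the detector plane.

    Returns (x_mm, y_mm) relative to the beam centre; raises
    :class:`NonIntersectingRay` when the ray points away from the plane.
    """
    s1 = np.asarray(s1, dtype=float)
    if s1[2] >= -1e-14 * np.linalg.norm(s1):
        raise NonIntersectingRay("ray is parallel to or directed away from the detector")
    t = -det.distance / s1[2]
    return (t * s1[0], t * s1[1])


def project_batch(s1: np.ndarray, det: Detector) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised detector projection; returns (xy, valid_mask)."""
    s1 = np.asarray(s1, dtype=float)
    valid = s1[:, 2] < -1e-14 * np.linalg.norm(s1, axis=1)
    t = np.where(valid, -det.distance / np.where(valid, s1[:, 2], -1.0), np.nan)
    xy = np.stack([t * s1[:, 0], t * s1[:, 1]], axis=1)
    return xy, valid


def backproject_to_q(spot: SpotObservation, beam: Beam, det: Detector) -> np.ndarray:
    """Scattering vector q_obs = s1 - s0 with |s1| = 1/lambda (on-sphere)."""
    x, y = spot.position
    direction = np.array([x, y, -det.distance])
    s1 = direction / np.linalg.norm(direction) / beam.wavelength
    return s1 - beam.s0


@dataclass
class AssignmentResult:
    spots: list
    n_assigned: int
    n_unassigned: int

    @property
    def failure_fraction(self) -> float:
        n = len(self.spots)
        return self.n_unassigned / n if n else 0.0


def assign_indices(
    spots: Iterable[SpotObservation],
    model: CrystalModel,
    beam: Beam,
    det: Detector,
    max_frac_dev: float = 0.3,
) -> AssignmentResult:
    """Assign the nearest integer Miller index to each observed centroid.

    ``h = round(A^-1 q_obs)``; a spot stays unassigned when any component of
    the fractional index deviates from its nearest integer by more than
    ``max_frac_dev``.  The model must already be approximately oriented
    (misorientation of order a degree or less).
    """
    spots = list(spots)
    if not spots:
        return AssignmentResult([], 0, 0)
    A_inv = np.linalg.inv(model.A)
    n_ok = 0
    for spot in spots:
        q_obs = backproject_to_q(spot, beam, det)
        h_frac = A_inv @ q_obs
        h = np.rint(h_frac)
        if np.max(np.abs(h_frac - h)) <= max_frac_dev and not np.all(h == 0):
            spot.hkl = (int(h[0]), int(h[1]), int(h[2]))
            n_ok += 1
        else:
            spot.hkl = None
    return AssignmentResult(spots, n_ok, len(spots) - n_ok)


# ---------------------------------------------------------------------------
# lattice point-group rotations and symmetry-reduced misorientation
# ---------------------------------------------------------------------------

#: generators per symmetry tag: (axis selector, rotation order).  Axis
#: selectors refer to the *direct* cell axes of the reference model.
POINT_GROUP_GENERATORS: dict[str, list[tuple[str, int]]] = {
    "triclinic": [],
    "hexagonal_622": [("c", 6), ("a", 2)],
}


def _real_axes(A: np.ndarray) -> dict[str, np.ndarray]:
    """Direct-space basis vectors (rows of A^-1) for an orientation matrix."""
    A_inv = np.linalg.inv(A)
    return {"a": A_inv[0], "b": A_inv[1], "c": A_inv[2]}


def point_group_rotations(symmetry_tag: str, A: np.ndarray) -> list[np.ndarray]:
    """Reference-setting rotation matrices mapping the lattice onto itself.

    The rotations are expressed in the unrotated (reference) crystal frame,
    so an orientation ``R`` has the symmetry-equivalent set ``{R C}``.  Using
    the reference frame for both arguments makes the symmetry-reduced
    misorientation symmetric in its inputs.
    """
    if symmetry_tag not in POINT_GROUP_GENERATORS:
        raise ValueError(f"unknown symmetry tag: {symmetry_tag!r}")
    B = b_matrix(cell_from_a(np.asarray(A, dtype=float)))
    axes = _real_axes(B)
    gens = [np.eye(3)]
    for axis_name, order in POINT_GROUP_GENERATORS[symmetry_tag]:
        axis = axes[axis_name]
        axis = axis / np.linalg.norm(axis)
        gens.append(Rotation.from_rotvec(axis * (2.0 * math.pi / order)).as_matrix())
    # close the group
    group: dict[tuple, np.ndarray] = {}

    def key(m: np.ndarray) -> tuple:
        return tuple(np.round(m, 9).ravel())

    frontier = [np.eye(3)]
    group[key(np.eye(3))] = np.eye(3)
    while frontier:
        nxt = []
        for m in frontier:
            for g in gens:
                prod = g @ m
                k = key(prod)
                if k not in group:
                    group[k] = prod
                    nxt.append(prod)
        frontier = nxt
        if len(group) > 192:  # safety valve for bad generators
            raise RuntimeError("point-group closure did not terminate")
    return list(group.values())


def misorientation_angle(
    A_model: np.ndarray,
    A_true: np.ndarray,
    symmetry_tag: str = "triclinic",
) -> tuple[float, tuple[float, float, float]]:
    """Symmetry-reduced angle (degrees) between two crystal orientations.

    Minimises the relating-rotation angle over the lattice point group of
    ``symmetry_tag`` and returns ``(angle_deg, (Rx, Ry, Rz))`` where the
    second element is the rotation-vector decomposition of the minimal
    relating rotation along the laboratory axes, in degrees.
    """
    A_model = np.asarray(A_model, dtype=float)
    A_true = np.asarray(A_true, dtype=float)
    R_m = CrystalModel(A_model).orientation
    R_t = CrystalModel(A_true).orientation
    best = None
    best_vec = (0.0, 0.0, 0.0)
    for C in point_group_rotations(symmetry_tag, A_true):
        rel = Rotation.from_matrix(R_m @ (R_t @ C).T)
        ang = math.degrees(rel.magnitude())
        if best is None or ang < best:
            best = ang
            vec = np.degrees(rel.as_rotvec())
            best_vec = (float(vec[0]), float(vec[1]), float(vec[2]))
    assert best is not None
    return best, best_vec
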