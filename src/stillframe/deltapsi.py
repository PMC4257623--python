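"""Signed minimal rotation bringing a reciprocal-lattice point onto the Ewald sphere.

For a still exposure, a lattice point Q = q generally sits slightly off the
Ewald sphere of radius 1/lambda centred at E = -s0.  The angle ``delta_psi``
is the smallest rotation of q about an axis through the reciprocal origin O,
perpendicular to the plane EOQ, that lands the point exactly on the sphere.
The sign convention is physical: negative when Q lies outside the sphere,
positive when inside, zero on the sphere.

Geometry.  Work in the plane spanned by q and the beam.  With
``e_a = -s0_hat`` (unit vector from O toward the sphere centre E, scaled) and
``e_b`` the in-plane unit vector perpendicular to ``e_a`` on q's side, every
point at radius |q| that lies on the Ewald sphere satisfies

    r . e_a = |q|^2 * lambda / 2,

i.e. it makes the fixed polar angle theta_r = arccos(|q| lambda / 2) with
``e_a``.  The reflecting position is therefore

    r = |q| (cos(theta_r) e_a + sin(theta_r) e_b),

and ``delta_psi`` is the signed in-plane angle from q to r, evaluated through
an arctangent of projections so the sign and the near-zero behaviour are
exact.  Rotating q by ``delta_psi`` about ``axis_e1 = e_a x e_b`` maps it
onto r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from scipy.spatial.transform import Rotation

from .geometry import Beam, CrystalModel, UnitCell, build_a_matrix

__all__ = [
    "DeltaPsiRecord",
    "DeltaPsiError",
    "BeyondLimitingSphere",
    "OriginReflection",
    "AxisUndefined",
    "compute_delta_psi",
    "reflecting_position",
    "delta_psi_batch",
    "reflecting_position_batch",
    "delta_psi_gradient",
]


class DeltaPsiError(ValueError):
    """Base class for degenerate reflection configurations."""


class BeyondLimitingSphere(DeltaPsiError):
    """|q| >= 2/lambda: no rotation can reach the Ewald sphere."""


class OriginReflection(DeltaPsiError):
    """q = 0: the origin is always on the sphere, the angle is undefined."""


class AxisUndefined(DeltaPsiError):
    """q collinear with the beam: the rotation axis is not defined."""


_COLLINEAR_TOL = 1e-12


@dataclass(frozen=True)
class DeltaPsiRecord:
    """One reflection's fitting datum: index, q, resolution, signed angle, axis."""

    hkl: tuple[int, int, int] | None
    q: np.ndarray
    d: float
    delta_psi: float
    axis_e1: np.ndarray


def _frame(q: np.ndarray, beam: Beam):
    qn = float(np.linalg.norm(q))
    if qn == 0.0:
        raise OriginReflection("q = 0 has no defined rotation")
    if qn >= 2.0 * beam.k:
        raise BeyondLimitingSphere(f"|q| = {qn:.6g} >= 2/lambda = {2 * beam.k:.6g}")
    e_a = -beam.s0_hat
    q_par = float(q @ e_a)
    perp = q - q_par * e_a
    pn = float(np.linalg.norm(perp))
    if pn <= _COLLINEAR_TOL * qn:
        raise AxisUndefined("q is collinear with the beam; rotation axis undefined")
    e_b = perp / pn
    return qn, e_a, e_b


def reflecting_position(q, beam: Beam) -> np.ndarray:
    """The on-sphere image r of q: |r| = |q| and |r + s0| = 1/lambda."""
    q = np.asarray(q, dtype=float)
    qn, e_a, e_b = _frame(q, beam)
    cos_tr = qn * beam.wavelength / 2.0
    sin_tr = math.sqrt(1.0 - cos_tr * cos_tr)
    return qn * (cos_tr * e_a + sin_tr * e_b)


def compute_delta_psi(q, beam: Beam, hkl=None) -> DeltaPsiRecord:
    """Signed minimal on-sphere rotation for one reciprocal-lattice point."""
    q = np.asarray(q, dtype=float)
    qn, e_a, e_b = _frame(q, beam)
    cos_tr = qn * beam.wavelength / 2.0
    sin_tr = math.sqrt(1.0 - cos_tr * cos_tr)
    r = qn * (cos_tr * e_a + sin_tr * e_b)
    e1 = np.cross(e_a, e_b)
    q_hat = q / qn
    e_p = np.cross(e1, q_hat)
    delta_psi = math.atan2(float(r @ e_p), float(r @ q_hat))
    return DeltaPsiRecord(hkl=hkl, q=q, d=1.0 / qn, delta_psi=delta_psi, axis_e1=e1)


def delta_psi_batch(
    q: np.ndarray, beam: Beam, with_r: bool = False
) -> tuple[np.ndarray, np.ndarray] | tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised signed delta-psi for an (N, 3) array of lattice points.

    Returns ``(delta_psi, valid)`` or ``(delta_psi, valid, r)``; entries where
    ``valid`` is False (origin, beyond the limiting sphere, or axis-undefined
    configurations) hold NaN and are excluded from all fits.
    """
    q = np.asarray(q, dtype=float)
    qn = np.linalg.norm(q, axis=1)
    e_a = -beam.s0_hat
    q_par = q @ e_a
    perp = q - q_par[:, None] * e_a
    pn = np.linalg.norm(perp, axis=1)
    valid = (qn > 0.0) & (qn < 2.0 * beam.k) & (pn > _COLLINEAR_TOL * np.maximum(qn, 1e-300))
    qn_safe = np.where(valid, qn, 1.0)
    pn_safe = np.where(valid, pn, 1.0)
    cos_tq = q_par / qn_safe
    sin_tq = pn / qn_safe
    cos_tr = qn * beam.wavelength / 2.0
    sin_tr = np.sqrt(np.clip(1.0 - cos_tr * cos_tr, 0.0, None))
    # delta = theta_r - theta_q through the angle-difference identities
    sin_d = sin_tr * cos_tq - cos_tr * sin_tq
    cos_d = cos_tr * cos_tq + sin_tr * sin_tq
    dpsi = np.where(valid, np.arctan2(sin_d, cos_d), np.nan)
    if not with_r:
        return dpsi, valid
    e_b = perp / pn_safe[:, None]
    r = qn_safe[:, None] * (cos_tr[:, None] * e_a + sin_tr[:, None] * e_b)
    r = np.where(valid[:, None], r, np.nan)
    return dpsi, valid, r


def reflecting_position_batch(q: np.ndarray, beam: Beam) -> tuple[np.ndarray, np.ndarray]:
    dpsi, valid, r = delta_psi_batch(q, beam, with_r=True)
    return r, valid


# ---------------------------------------------------------------------------
# derivatives
# ---------------------------------------------------------------------------

#: parameter names understood by :func:`delta_psi_gradient`
ORIENTATION_PARAMS = ("rx", "ry", "rz")
CELL_PARAMS = ("a", "b", "c", "alpha", "beta", "gamma")

_AXES = {"rx": np.array([1.0, 0, 0]), "ry": np.array([0, 1.0, 0]), "rz": np.array([0, 0, 1.0])}

# central-difference steps in natural units (rad, angstrom, degree, angstrom)
_STEPS = {
    "rx": 1e-6, "ry": 1e-6, "rz": 1e-6,
    "a": 1e-6, "b": 1e-6, "c": 1e-6,
    "alpha": 1e-6, "beta": 1e-6, "gamma": 1e-6,
    "wavelength": 1e-6,
}


def _delta_psi_of(model: CrystalModel, hkl, beam: Beam, param: str, shift: float) -> float:
    h = np.asarray(hkl, dtype=float)
    if param in _AXES:
        R = Rotation.from_rotvec(_AXES[param] * shift).as_matrix()
        q = R @ (model.A @ h)
        return compute_delta_psi(q, beam).delta_psi
    if param == "wavelength":
        beam = Beam(beam.wavelength + shift, beam.s0_hat)
        return compute_delta_psi(model.A @ h, beam).delta_psi
    if param in CELL_PARAMS:
        cell = model.cell
        values = dict(zip(CELL_PARAMS, cell.parameters()))
        values[param] += shift
        new_model = build_a_matrix(UnitCell(**values), model.orientation)
        return compute_delta_psi(new_model.A @ h, beam).delta_psi
    raise ValueError(f"unknown parameter {param!r}")


def delta_psi_gradient(
    model: CrystalModel,
    hkl,
    beam: Beam,
    params=ORIENTATION_PARAMS,
) -> dict[str, float]:
    """Central-difference first derivatives of delta-psi.

    ``params`` may contain the orientation angles ``rx``/``ry``/``rz``
    (rotations about the lab axes, radians), the cell parameters under the
    active constraint set (lengths in angstroms, angles in degrees) and
    ``wavelength`` (angstroms).  Reflections in a degenerate configuration
    raise the corresponding :class:`DeltaPsiError` and are excluded upstream.
    """
    unknown = [p for p in params if p not in _STEPS]
    if unknown:
        raise ValueError(f"unknown parameters: {unknown}")
    grad: dict[str, float] = {}
    for p in params:
        s = _STEPS[p]
        plus = _delta_psi_of(model, hkl, beam, p, +s)
        minus = _delta_psi_of(model, hkl, beam, p, -s)
        grad[p] = (plus - minus) / (2.0 * s)
    return grad
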