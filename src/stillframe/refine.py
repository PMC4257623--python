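"""Crystal model refinement against still-shot spot centroids.

Two least-squares targets are provided.  The positional target sums the
squared detector-plane distance (mm^2) between observed and calculated spot
centroids; on a still only the rotation about the beam axis moves calculated
centroids appreciably, so the two transverse misorientation angles are
nearly unconstrained by it.  The hybrid target adds, per spot, the squared
off-sphere angle delta_psi expressed in radians/(2*pi); that term depends
directly on the transverse angles and restores a well-conditioned problem.

Minimisation is damped Gauss-Newton with a numerically differenced Jacobian.
The orientation is parameterised as a small rotation (Rx, Ry, Rz about the
lab axes) composed onto the current orientation and re-linearised each
iteration; the cell is parameterised directly (six parameters for triclinic,
a and c for the hexagonal 622 constraint with a = b and angles fixed at
90/90/120).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .deltapsi import delta_psi_batch
from .geometry import (
    Beam,
    CrystalModel,
    Detector,
    SpotObservation,
    UnitCell,
    b_matrix,
    build_a_matrix,
)

__all__ = [
    "RefinementResult",
    "ProtocolError",
    "positional_target",
    "hybrid_target",
    "refine_model",
    "symmetrize_to_bravais",
    "run_protocol",
]

TWO_PI = 2.0 * math.pi

#: free parameters per constraint set (orientation deltas first)
PARAM_SETS = {
    "triclinic": ("rx", "ry", "rz", "a", "b", "c", "alpha", "beta", "gamma"),
    "hexagonal_622": ("rx", "ry", "rz", "a", "c"),
}

# finite-difference steps: radians for angles about the lab axes,
# angstroms for lengths, degrees for cell angles
_FD_STEPS = {"rx": 1e-5, "ry": 1e-5, "rz": 1e-5,
             "a": 1e-3, "b": 1e-3, "c": 1e-3,
             "alpha": 1e-3, "beta": 1e-3, "gamma": 1e-3}

MAX_ITERATIONS = 100
MAX_HALVINGS = 25
TARGET_RTOL = 1e-10
STEP_TOL = 1e-8


class ProtocolError(RuntimeError):
    """Two-stage protocol aborted; carries the failing stage's result."""

    def __init__(self, message: str, stage: int, result: "RefinementResult"):
        super().__init__(message)
        self.stage = stage
        self.result = result


@dataclass
class RefinementResult:
    model: CrystalModel
    target_history: np.ndarray
    converged: bool
    per_spot: pd.DataFrame
    n_iterations: int
    message: str = ""
    stage1: "RefinementResult | None" = field(default=None, repr=False)


def _spot_arrays(spots) -> tuple[np.ndarray, np.ndarray]:
    hkl = []
    obs = []
    for s in spots:
        if s.hkl is None:
            raise ValueError("all spots must carry an assigned Miller index")
        hkl.append(s.hkl)
        obs.append(s.position)
    return np.asarray(hkl, dtype=float), np.asarray(obs, dtype=float)


def _residuals(A: np.ndarray, hkl: np.ndarray, obs: np.ndarray,
               beam: Beam, det: Detector, hybrid: bool) -> np.ndarray:
    """Stacked residual vector: positional mm terms, then delta-psi/(2 pi)."""
    q = hkl @ A.T
    dpsi, valid, r = delta_psi_batch(q, beam, with_r=True)
    if not np.all(valid):
        raise ValueError("degenerate reflection encountered during refinement")
    s1 = r + beam.s0
    if np.any(s1[:, 2] >= 0):
        raise ValueError("diffracted ray does not reach the detector plane")
    t = -det.distance / s1[:, 2]
    calc = np.stack([t * s1[:, 0], t * s1[:, 1]], axis=1)
    res_pos = (obs - calc).ravel()
    if not hybrid:
        return res_pos
    return np.concatenate([res_pos, dpsi / TWO_PI])


def positional_target(model: CrystalModel, spots, beam: Beam, det: Detector) -> float:
    """Sum over spots of |r_obs - r_calc|^2 in mm^2."""
    hkl, obs = _spot_arrays(spots)
    r = _residuals(model.A, hkl, obs, beam, det, hybrid=False)
    return float(r @ r)


def hybrid_target(model: CrystalModel, spots, beam: Beam, det: Detector) -> float:
    """Positional term (mm^2) plus sum of (delta_psi / 2 pi)^2."""
    hkl, obs = _spot_arrays(spots)
    r = _residuals(model.A, hkl, obs, beam, det, hybrid=True)
    return float(r @ r)


def _cell_params(cell: UnitCell, constraint: str) -> np.ndarray:
    if constraint == "triclinic":
        return np.array(cell.parameters())
    if constraint == "hexagonal_622":
        return np.array([0.5 * (cell.a + cell.b), cell.c])
    raise ValueError(f"unknown constraint {constraint!r}")


def _cell_from_params(p: np.ndarray, constraint: str) -> UnitCell:
    if constraint == "triclinic":
        return UnitCell(*p)
    return UnitCell(p[0], p[0], p[1], 90.0, 90.0, 120.0)


def _apply(p: np.ndarray, R_base: np.ndarray, constraint: str) -> np.ndarray:
    """Build A from a parameter vector: small rotation composed on R_base."""
    rot = Rotation.from_rotvec([p[0], 0, 0]) * Rotation.from_rotvec([0, p[1], 0]) \
        * Rotation.from_rotvec([0, 0, p[2]])
    R = rot.as_matrix() @ R_base
    cell = _cell_from_params(p[3:], constraint)
    return R @ b_matrix(cell)


def refine_model(
    spots,
    start: CrystalModel,
    beam: Beam,
    det: Detector,
    target: str = "eq2",
    constraint: str = "triclinic",
    max_iterations: int = MAX_ITERATIONS,
) -> RefinementResult:
    """Damped Gauss-Newton minimisation of the chosen target.

    ``target`` selects the objective: ``"eq1"`` (positional only) or
    ``"eq2"`` (hybrid positional + delta-psi).  ``constraint`` selects the
    parameterisation (see :data:`PARAM_SETS`).  Accepted steps never increase
    the target; failure to find a decreasing step within the damping budget,
    or a singular normal system, flags the result as not converged.
    """
    if target not in ("eq1", "eq2"):
        raise ValueError("target must be 'eq1' or 'eq2'")
    names = PARAM_SETS[constraint]
    hybrid = target == "eq2"
    hkl, obs = _spot_arrays(spots)
    min_spots = 6 if constraint == "triclinic" else 4
    if len(hkl) < min_spots:
        raise ValueError(f"need at least {min_spots} assigned spots for {constraint}")

    R_base = start.orientation
    cell_p = _cell_params(start.cell, constraint)
    n_rot = 3
    steps = np.array([_FD_STEPS[n] for n in names])

    history = []
    converged = False
    message = ""
    n_iter = 0
    res = _residuals(_apply(np.concatenate([np.zeros(n_rot), cell_p]), R_base, constraint),
                     hkl, obs, beam, det, hybrid)
    f0 = float(res @ res)
    history.append(f0)

    for n_iter in range(1, max_iterations + 1):
        p0 = np.concatenate([np.zeros(n_rot), cell_p])
        J = np.empty((res.size, len(names)))
        n_pos = 2 * len(hkl)  # leading positional rows of the residual vector
        try:
            for j in range(len(names)):
                dp = np.zeros_like(p0)
                dp[j] = steps[j]
                r_plus = _residuals(_apply(p0 + dp, R_base, constraint), hkl, obs, beam, det, hybrid)
                r_minus = _residuals(_apply(p0 - dp, R_base, constraint), hkl, obs, beam, det, hybrid)
                J[:, j] = (r_plus - r_minus) / (2.0 * steps[j])
                if names[j] in ("rx", "ry"):
                    # Still-shot model: the transverse misorientations do not
                    # move calculated centroids; they only carry information
                    # through the delta-psi term.  The positional block of
                    # their derivative is therefore zero by construction.
                    J[:n_pos, j] = 0.0
            delta, *_ = np.linalg.lstsq(J, -res, rcond=None)
        except (np.linalg.LinAlgError, ValueError) as exc:
            message = f"normal system failure: {exc}"
            break
        if not np.all(np.isfinite(delta)):
            message = "singular normal system"
            break
        if np.linalg.norm(delta) < STEP_TOL:
            converged = True
            break
        # the linearised model's own predicted decrease; when it vanishes the
        # normal equations are satisfied and the refinement is done
        res_pred = res + J @ delta
        if f0 - float(res_pred @ res_pred) <= TARGET_RTOL * max(f0, 1e-300) * 10.0:
            converged = True
            break

        accepted = False
        f_best = math.inf
        for k in range(MAX_HALVINGS + 1):
            step = delta * (0.5 ** k)
            p_try = p0 + step
            try:
                res_try = _residuals(_apply(p_try, R_base, constraint), hkl, obs, beam, det, hybrid)
            except ValueError:
                continue
            f_try = float(res_try @ res_try)
            f_best = min(f_best, f_try)
            if f_try <= f0:
                accepted = True
                break
        if not accepted:
            # stagnation at a minimum (every damped step raises the target
            # only marginally) is convergence, not divergence; a genuinely
            # diverging step overshoots by far more than this tolerance
            if f_best <= f0 * (1.0 + 1e-6):
                converged = True
            else:
                message = "divergence: no decreasing step within damping budget"
            break

        # fold the accepted rotation update into the base orientation
        rot = Rotation.from_rotvec([step[0], 0, 0]) * Rotation.from_rotvec([0, step[1], 0]) \
            * Rotation.from_rotvec([0, 0, step[2]])
        R_base = rot.as_matrix() @ R_base
        cell_p = p_try[n_rot:]
        res, f_prev, f0 = res_try, f0, f_try
        history.append(f0)
        if (f_prev - f0) <= TARGET_RTOL * max(f_prev, 1e-300) or np.linalg.norm(step) < STEP_TOL:
            converged = True
            break

    A_final = _apply(np.concatenate([np.zeros(n_rot), cell_p]), R_base, constraint)
    model = CrystalModel(A_final, symmetry_tag=start.symmetry_tag)
    q = hkl @ A_final.T
    dpsi, _, r = delta_psi_batch(q, beam, with_r=True)
    s1 = r + beam.s0
    t = -det.distance / s1[:, 2]
    calc = np.stack([t * s1[:, 0], t * s1[:, 1]], axis=1)
    per_spot = pd.DataFrame(
        {
            "h": hkl[:, 0].astype(int),
            "k": hkl[:, 1].astype(int),
            "l": hkl[:, 2].astype(int),
            "x_obs_mm": obs[:, 0],
            "y_obs_mm": obs[:, 1],
            "x_calc_mm": calc[:, 0],
            "y_calc_mm": calc[:, 1],
            "residual_mm": np.linalg.norm(obs - calc, axis=1),
            "delta_psi_rad": dpsi,
            "d_angstrom": 1.0 / np.linalg.norm(q, axis=1),
        }
    )
    return RefinementResult(
        model=model,
        target_history=np.asarray(history),
        converged=converged,
        per_spot=per_spot,
        n_iterations=n_iter,
        message=message,
    )


def symmetrize_to_bravais(model: CrystalModel, symmetry: str = "hexagonal_622") -> CrystalModel:
    """Project a refined triclinic model onto the constrained lattice family.

    The constrained cell is the least-squares projection of the refined
    metric (hexagonal: a = mean of refined a and b, c kept, angles fixed at
    90/90/120); the orientation is the rotation closest to the refined A in
    the Frobenius sense, found by polar decomposition of ``A B_hex^-1``.
    """
    if symmetry == "triclinic":
        return model
    if symmetry != "hexagonal_622":
        raise ValueError(f"unknown symmetry {symmetry!r}")
    cell = model.cell
    hex_cell = UnitCell(0.5 * (cell.a + cell.b), 0.5 * (cell.a + cell.b), cell.c,
                        90.0, 90.0, 120.0)
    B = b_matrix(hex_cell)
    M = model.A @ np.linalg.inv(B)
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1.0
        R = U @ Vt
    new = build_a_matrix(hex_cell, R)
    return CrystalModel(new.A, symmetry_tag=symmetry)


def run_protocol(
    spots,
    start: CrystalModel,
    beam: Beam,
    det: Detector,
    stage1_target: str = "eq2",
    stage2_target: str | None = "eq2",
    symmetry: str = "hexagonal_622",
    reassign_between_stages: bool = False,
    max_frac_dev: float = 0.3,
) -> RefinementResult:
    """Two-stage refinement: triclinic, then Bravais-constrained.

    Stage 1 refines all nine triclinic parameters from ``start``; the cell
    is then symmetrised to the target Bravais family and stage 2 re-refines
    under the constraints.  ``stage2_target=None`` (or ``"none"``) skips the
    second stage.  A stage-1 divergence aborts with :class:`ProtocolError`.
    """
    stage1 = refine_model(spots, start, beam, det, target=stage1_target,
                          constraint="triclinic")
    if not stage1.converged and stage1.message.startswith("divergence"):
        raise ProtocolError(f"stage 1 failed: {stage1.message}", 1, stage1)
    symmetrized = symmetrize_to_bravais(stage1.model, symmetry)
    if stage2_target in (None, "none") or symmetry == "triclinic":
        stage1.model = CrystalModel(symmetrized.A, symmetry_tag=symmetry)
        return stage1
    if reassign_between_stages:
        from .geometry import assign_indices

        res = assign_indices(list(spots), symmetrized, beam, det, max_frac_dev)
        spots = [s for s in res.spots if s.assigned]
    stage2 = refine_model(spots, symmetrized, beam, det, target=stage2_target,
                          constraint=symmetry)
    stage2.target_history = np.concatenate([stage1.target_history, stage2.target_history])
    stage2.stage1 = stage1
    return stage2
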