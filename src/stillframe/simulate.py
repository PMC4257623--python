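"""Seeded synthetic still-shot generator.

Emulates the test conditions used throughout the package's recovery suites:
randomly oriented photosystem-I-like hexagonal crystals (a = b = 281,
c = 165.2 angstroms, gamma = 120 degrees) exposed to monochromatic,
zero-divergence 1.32-angstrom radiation, recorded on a flat pixel-array
detector (0.11 mm pixels, 129 mm from the sample), analysed over the
15-3.5 angstrom resolution range.  The ground-truth acceptance rule is the
mosaic envelope itself: a reflection is observed iff
|delta_psi| <= eta/2 + d/D_eff, with the zero-mosaicity default
(eta = 0, D_eff = 4850 angstroms) describing a finite perfect crystallite
of roughly 17 x 17 x 30 cells.  Spot centroids are the detector projections
of the reflecting positions, optionally jittered by Gaussian centroid noise
and/or quantised to pixel centres.  Intensities, solvent background and
fringes are not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .deltapsi import delta_psi_batch
from .geometry import Beam, CrystalModel, Detector, SpotObservation, UnitCell, build_a_matrix
from .mosaic import MosaicEnvelope, envelope_halfwidth
from .predict import candidate_lattice

__all__ = [
    "PSI_CELL",
    "psi_beam",
    "psi_detector",
    "psi_envelope",
    "StillScene",
    "random_orientation",
    "simulate_still",
    "perturb_model",
]

#: hexagonal photosystem-I cell
PSI_CELL = UnitCell(281.0, 281.0, 165.2, 90.0, 90.0, 120.0)

#: default centroid jitter standing in for spotfinding error (~1/4 pixel)
DEFAULT_NOISE_SIGMA_MM = 0.03


def psi_beam() -> Beam:
    return Beam(wavelength=1.32)


def psi_detector() -> Detector:
    """0.11 mm pixels at 129 mm; a 1000x1000 panel comfortably holds the
    3.5-angstrom ring (radius 51.4 mm) with the beam at its centre."""
    return Detector(distance=129.0, pixel_size=0.11, n_fast=1000, n_slow=1000,
                    beam_center=(55.0, 55.0))


def psi_envelope() -> MosaicEnvelope:
    """Zero mosaic spread; block size of a ~17 x 17 x 30 cell crystallite."""
    return MosaicEnvelope(eta=0.0, d_eff=4850.0)


@dataclass
class StillScene:
    """Simulator ground truth plus the observed spot list."""

    truth_model: CrystalModel
    truth_env: MosaicEnvelope
    beam: Beam
    det: Detector
    spots: list[SpotObservation]
    seed: int | None
    noise_sigma_mm: float = 0.0
    pixel_quantize: bool = False
    warning: str | None = None

    @property
    def hkl_set(self) -> set[tuple[int, int, int]]:
        return {s.hkl for s in self.spots}


def random_orientation(rng: np.random.Generator) -> Rotation:
    """Uniform random 3-D orientation via a normalised Gaussian quaternion."""
    quat = rng.normal(size=4)
    return Rotation.from_quat(quat / np.linalg.norm(quat))


# (hkl, d) depend only on the cell and resolution range, not the orientation,
# because |A h| = |B h|; cache them across scenes.
_lattice_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _cached_lattice(cell: UnitCell, d_min: float, d_max: float):
    key = (*np.round(cell.parameters(), 9), round(d_min, 9), round(d_max, 9))
    if key not in _lattice_cache:
        B = build_a_matrix(cell, np.eye(3)).A
        _lattice_cache[key] = candidate_lattice(B, d_min, d_max)
        if len(_lattice_cache) > 8:
            _lattice_cache.pop(next(iter(_lattice_cache)))
    return _lattice_cache[key]


def simulate_still(
    cell: UnitCell = PSI_CELL,
    symmetry: str = "hexagonal_622",
    orientation: Rotation | np.ndarray | None = None,
    env_true: MosaicEnvelope | None = None,
    beam: Beam | None = None,
    det: Detector | None = None,
    d_min: float = 3.5,
    d_max: float = 15.0,
    noise_sigma_mm: float = 0.0,
    pixel_quantize: bool = False,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> StillScene:
    """Generate one still: envelope-accepted reflections of a (random) orientation.

    Observed spots are exactly the lattice points in the resolution range
    with |delta_psi| <= halfwidth(d) under the true envelope; positions are
    reflecting-position projections, then optional Gaussian jitter and
    optional quantisation to the pixel grid.  Fully deterministic for a
    fixed ``seed``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    beam = beam or psi_beam()
    det = det or psi_detector()
    env_true = env_true or psi_envelope()
    if orientation is None:
        orientation = random_orientation(rng)
    R = orientation.as_matrix() if isinstance(orientation, Rotation) else np.asarray(orientation)
    model = build_a_matrix(cell, R)
    model = CrystalModel(model.A, symmetry_tag=symmetry)

    hkl, d = _cached_lattice(cell, d_min, d_max)
    q = hkl.astype(float) @ model.A.T
    dpsi, valid = delta_psi_batch(q, beam)
    accept = valid & (np.abs(dpsi) <= envelope_halfwidth(env_true, d))
    hkl_a, d_a, dpsi_a = hkl[accept], d[accept], dpsi[accept]
    _, _, r_a = delta_psi_batch(q[accept], beam, with_r=True)
    s1 = r_a + beam.s0
    forward = s1[:, 2] < 0
    hkl_a, d_a, dpsi_a, s1 = hkl_a[forward], d_a[forward], dpsi_a[forward], s1[forward]
    t = -det.distance / s1[:, 2]
    xy = np.stack([t * s1[:, 0], t * s1[:, 1]], axis=1)
    on_panel = det.contains_batch(xy)
    hkl_a, d_a, dpsi_a, xy = hkl_a[on_panel], d_a[on_panel], dpsi_a[on_panel], xy[on_panel]
    if noise_sigma_mm > 0.0:
        xy = xy + rng.normal(0.0, noise_sigma_mm, size=xy.shape)
    if pixel_quantize:
        bc = np.asarray(det.beam_center)
        p = det.pixel_size
        xy = (np.floor((xy + bc) / p) + 0.5) * p - bc
    # spots pushed off the panel by noise are discarded to honour the bounds
    keep = det.contains_batch(xy)
    hkl_a, d_a, dpsi_a, xy = hkl_a[keep], d_a[keep], dpsi_a[keep], xy[keep]
    spots = [
        SpotObservation(
            position=(float(x), float(y)),
            hkl=(int(h[0]), int(h[1]), int(h[2])),
            extras={"delta_psi_rad": float(dp), "d_angstrom": float(dd)},
        )
        for (x, y), h, dp, dd in zip(xy, hkl_a, dpsi_a, d_a)
    ]
    warning = None if spots else "envelope accepted zero reflections"
    return StillScene(
        truth_model=model,
        truth_env=env_true,
        beam=beam,
        det=det,
        spots=spots,
        seed=seed,
        noise_sigma_mm=noise_sigma_mm,
        pixel_quantize=pixel_quantize,
        warning=warning,
    )


def perturb_model(
    model: CrystalModel,
    dR_deg: tuple[float, float, float] = (0.0, 0.0, 0.0),
    cell_rel_error: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CrystalModel:
    """Misorient and mis-scale a model, emulating post-indexing error.

    Without a seed (or rng) the rotations are applied at exactly the stated
    magnitudes about the lab x, y, z axes and all six cell parameters are
    scaled by (1 + cell_rel_error).  With a seed, each rotation angle is
    drawn uniformly in +-dR_deg[i] and each of the six cell parameters gets
    an independent relative error uniform in +-cell_rel_error, so a start
    model carries both metric and angular cell error, as a freshly indexed
    triclinic cell would.
    """
    if rng is None and seed is not None:
        rng = np.random.default_rng(seed)
    if rng is not None:
        angles = [rng.uniform(-m, m) for m in dR_deg]
        scales = 1.0 + rng.uniform(-cell_rel_error, cell_rel_error, size=6)
    else:
        angles = list(dR_deg)
        scales = np.full(6, 1.0 + cell_rel_error)
    rot = (
        Rotation.from_rotvec([math.radians(angles[0]), 0, 0])
        * Rotation.from_rotvec([0, math.radians(angles[1]), 0])
        * Rotation.from_rotvec([0, 0, math.radians(angles[2])])
    )
    cell = model.cell
    new_cell = UnitCell(cell.a * scales[0], cell.b * scales[1], cell.c * scales[2],
                        cell.alpha * scales[3], cell.beta * scales[4], cell.gamma * scales[5])
    new = build_a_matrix(new_cell, rot.as_matrix() @ model.orientation)
    return CrystalModel(new.A, symmetry_tag=model.symmetry_tag)
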