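"""Reflection enumeration, spot prediction, and model-vs-truth scoring.

A reflection is predicted observable when its off-sphere angle satisfies
|delta_psi| <= eta/2 + d/D_eff; its predicted centroid is the detector
projection of the reflecting position (the on-sphere image of q), which is
where the centre of the partial reflection lands.  Agreement between a
predicted and a reference set is scored per reciprocal-space shell of equal
volume (equal increments of 1/d^3) as the falsely-predicted and unmodeled
fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deltapsi import delta_psi_batch
from .geometry import Beam, CrystalModel, Detector, SpotObservation
from .mosaic import MosaicEnvelope, envelope_halfwidth

__all__ = [
    "PredictionReport",
    "enumerate_reflections",
    "predict_spots",
    "shell_boundaries",
    "score_prediction",
]


def _index_bounds(A: np.ndarray, d_min: float) -> np.ndarray:
    """Per-axis bounds |h_i| <= ||a_i|| / d_min (a_i the direct cell vectors),
    guaranteeing no reflection with d >= d_min escapes the search box."""
    A_inv = np.linalg.inv(A)
    real_lengths = np.linalg.norm(A_inv, axis=1)
    return np.ceil(real_lengths / d_min).astype(int)


def candidate_lattice(A: np.ndarray, d_min: float, d_max: float):
    """All nonzero hkl with d_min <= 1/|A h| <= d_max, plus their d spacings.

    |A h|^2 is evaluated through the reciprocal metric G* = A^T A by
    broadcasting over the three index axes, which keeps the full search box
    cheap even for large cells.
    """
    bounds = _index_bounds(A, d_min)
    h0, h1, h2 = (np.arange(-b, b + 1, dtype=float) for b in bounds)
    G = A.T @ A
    q2 = (
        G[0, 0] * h0[:, None, None] ** 2
        + G[1, 1] * h1[None, :, None] ** 2
        + G[2, 2] * h2[None, None, :] ** 2
        + 2.0 * G[0, 1] * h0[:, None, None] * h1[None, :, None]
        + 2.0 * G[0, 2] * h0[:, None, None] * h2[None, None, :]
        + 2.0 * G[1, 2] * h1[None, :, None] * h2[None, None, :]
    )
    mask = (q2 >= d_max**-2) & (q2 <= d_min**-2)
    i, j, k = np.nonzero(mask)
    hkl = np.stack([h0[i], h1[j], h2[k]], axis=1).astype(int)
    d = 1.0 / np.sqrt(q2[mask])
    return hkl, d


def enumerate_reflections(
    model: CrystalModel,
    beam: Beam,
    d_min: float,
    d_max: float,
    env: MosaicEnvelope | None = None,
    coarse_factor: float = 5.0,
) -> np.ndarray:
    """Integer Miller indices within the resolution range, optionally
    pre-filtered to |delta_psi| <= coarse_factor * halfwidth(d)."""
    if d_min >= d_max:
        raise ValueError("d_min must be smaller than d_max")
    hkl, d = candidate_lattice(model.A, d_min, d_max)
    if env is None:
        return hkl
    dpsi, valid = delta_psi_batch(hkl.astype(float) @ model.A.T, beam)
    keep = valid & (np.abs(dpsi) <= coarse_factor * envelope_halfwidth(env, d))
    return hkl[keep]


def predict_spots(
    model: CrystalModel,
    beam: Beam,
    det: Detector,
    env: MosaicEnvelope,
    d_min: float,
    d_max: float,
) -> tuple[list[SpotObservation], int]:
    """Predicted spot list under the envelope, plus the off-detector count.

    A reflection is predicted iff |delta_psi| <= halfwidth(d); its position
    is the detector projection of the reflecting position.  Predictions that
    miss the panel are dropped and counted in the second return value.
    """
    hkl, d = candidate_lattice(model.A, d_min, d_max)
    q = hkl.astype(float) @ model.A.T
    dpsi, valid = delta_psi_batch(q, beam)
    accept = valid & (np.abs(dpsi) <= envelope_halfwidth(env, d))
    hkl, d, dpsi = hkl[accept], d[accept], dpsi[accept]
    _, _, r = delta_psi_batch(q[accept], beam, with_r=True)
    s1 = r + beam.s0
    forward = s1[:, 2] < 0
    xy = np.full((len(s1), 2), np.nan)
    t = -det.distance / s1[forward, 2]
    xy[forward] = np.stack([t * s1[forward, 0], t * s1[forward, 1]], axis=1)
    on_panel = forward & det.contains_batch(np.nan_to_num(xy, nan=1e12))
    spots = [
        SpotObservation(
            position=(float(x), float(y)),
            hkl=(int(h[0]), int(h[1]), int(h[2])),
            extras={"delta_psi_rad": float(dp), "d_angstrom": float(dd), "predicted": 1},
        )
        for (x, y), h, dp, dd in zip(xy[on_panel], hkl[on_panel], dpsi[on_panel], d[on_panel])
    ]
    return spots, int(np.sum(~on_panel))


def shell_boundaries(d_range: tuple[float, float], n_shells: int) -> np.ndarray:
    """Resolution boundaries partitioning [d_low, d_high] into shells of equal
    reciprocal-space volume (volume within |q| <= 1/d grows as 1/d^3, so the
    boundaries are equally spaced in 1/d^3).  Returned descending in d."""
    d_low, d_high = max(d_range), min(d_range)
    u = np.linspace(d_low ** -3, d_high ** -3, n_shells + 1)
    return u ** (-1.0 / 3.0)


def _hkl_set(items) -> set[tuple[int, int, int]]:
    out = set()
    for it in items:
        if isinstance(it, SpotObservation):
            if it.hkl is None:
                raise ValueError("unassigned spot in a scoring set")
            out.add(tuple(int(v) for v in it.hkl))
        else:
            out.add(tuple(int(v) for v in it))
    return out


@dataclass
class PredictionReport:
    per_shell: pd.DataFrame
    false_fraction: float
    unmodeled_fraction: float
    n_predicted: int
    n_reference: int


def score_prediction(
    predicted,
    reference,
    model: CrystalModel,
    d_range: tuple[float, float] = (15.0, 3.5),
    n_shells: int = 10,
) -> PredictionReport:
    """False-prediction and unmodeled fractions, per equal-volume shell.

    ``predicted`` and ``reference`` are iterables of Miller indices or
    assigned :class:`SpotObservation`; matching is by exact index on the
    common lattice.  false = |predicted \\ reference| / |predicted|;
    unmodeled = |reference \\ predicted| / |reference|.  An empty predicted
    set yields NaN for the false fraction.
    """
    pred = _hkl_set(predicted)
    ref = _hkl_set(reference)
    bounds = shell_boundaries(d_range, n_shells)
    all_hkl = np.array(sorted(pred | ref), dtype=float).reshape(-1, 3)
    d_all = {}
    if len(all_hkl):
        qn = np.linalg.norm(all_hkl @ model.A.T, axis=1)
        for h, dd in zip(all_hkl.astype(int), 1.0 / np.maximum(qn, 1e-300)):
            d_all[tuple(h)] = dd
    rows = []
    for i in range(n_shells):
        d_hi, d_lo = bounds[i], bounds[i + 1]
        in_shell = lambda h: d_lo <= d_all[h] <= d_hi if i == n_shells - 1 else d_lo < d_all[h] <= d_hi
        p = {h for h in pred if in_shell(h)}
        r = {h for h in ref if in_shell(h)}
        n_false = len(p - r)
        n_unmod = len(r - p)
        rows.append(
            {
                "d_max": d_hi,
                "d_min": d_lo,
                "n_predicted": len(p),
                "n_reference": len(r),
                "n_false": n_false,
                "n_unmodeled": n_unmod,
                "false_fraction": n_false / len(p) if p else np.nan,
                "unmodeled_fraction": n_unmod / len(r) if r else np.nan,
            }
        )
    per_shell = pd.DataFrame(rows)
    false_fraction = len(pred - ref) / len(pred) if pred else math.nan
    unmodeled_fraction = len(ref - pred) / len(ref) if ref else math.nan
    return PredictionReport(
        per_shell=per_shell,
        false_fraction=false_fraction,
        unmodeled_fraction=unmodeled_fraction,
        n_predicted=len(pred),
        n_reference=len(ref),
    )
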