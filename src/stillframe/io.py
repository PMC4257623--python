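"""Text formats: spot-list CSV, geometry config, model and scene files.

The spot-list dialect is a plain CSV with header
``image_id,x_mm,y_mm,intensity,h,k,l``; ``h,k,l`` are blank for unassigned
spots, coordinates are detector millimetres relative to the beam centre,
and any further columns (``delta_psi_rad``, ``d_angstrom``, ``predicted``,
...) ride along losslessly in ``SpotObservation.extras``.  Geometry,
models, envelopes and scene truths are YAML.
"""

from __future__ import annotations

import csv
import math
import warnings
from pathlib import Path

import numpy as np
import yaml

from .geometry import Beam, CrystalModel, Detector, SpotObservation
from .mosaic import MosaicEnvelope

__all__ = [
    "SPOT_COLUMNS",
    "load_spot_list",
    "write_spot_list",
    "load_geometry",
    "write_geometry",
    "load_model",
    "write_model",
    "load_envelope",
    "write_envelope",
]

SPOT_COLUMNS = ("image_id", "x_mm", "y_mm", "intensity", "h", "k", "l")


class SpotListFormatError(ValueError):
    pass


def load_spot_list(path, det: Detector | None = None) -> list[SpotObservation]:
    """Read a spot-list CSV; malformed rows report their line number.

    With a detector supplied, positions more than ten times the panel
    extent from the centre trigger a unit-mismatch warning.
    """
    path = Path(path)
    spots: list[SpotObservation] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames[:7]) != list(SPOT_COLUMNS):
            raise SpotListFormatError(
                f"{path}: header must start with {','.join(SPOT_COLUMNS)}"
            )
        extra_cols = list(reader.fieldnames[7:])
        for lineno, row in enumerate(reader, start=2):
            try:
                x = float(row["x_mm"])
                y = float(row["y_mm"])
                intensity = float(row["intensity"]) if row["intensity"] not in ("", None) else None
                blank = [row[c] in ("", None) for c in ("h", "k", "l")]
                if any(blank) and not all(blank):
                    raise ValueError("partially blank Miller index")
                hkl = None if all(blank) else (int(row["h"]), int(row["k"]), int(row["l"]))
            except (TypeError, ValueError, KeyError) as exc:
                raise SpotListFormatError(f"{path}:{lineno}: malformed row ({exc})") from exc
            extras = {"image_id": row["image_id"]}
            for c in extra_cols:
                v = row.get(c)
                if v not in ("", None):
                    try:
                        extras[c] = float(v)
                    except ValueError:
                        extras[c] = v
            spots.append(SpotObservation(position=(x, y), intensity=intensity,
                                         hkl=hkl, extras=extras))
    if det is not None and spots:
        extent = 10.0 * max(det.n_fast, det.n_slow) * det.pixel_size
        worst = max(max(abs(s.position[0]), abs(s.position[1])) for s in spots)
        if worst > extent:
            warnings.warn(
                f"{path}: spot positions reach {worst:.0f} mm, more than 10x the "
                "detector extent; check that coordinates are in millimetres"
            )
    return spots


def write_spot_list(spots, path, image_id: str | int = 0) -> None:
    """Write spots in the declared dialect; extras become extension columns."""
    path = Path(path)
    extra_cols: list[str] = []
    for s in spots:
        for k in s.extras:
            if k != "image_id" and k not in extra_cols:
                extra_cols.append(k)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(SPOT_COLUMNS) + extra_cols)
        for s in spots:
            h, k, l = (s.hkl if s.hkl is not None else ("", "", ""))
            row = [
                s.extras.get("image_id", image_id),
                repr(float(s.position[0])),
                repr(float(s.position[1])),
                "" if s.intensity is None else repr(float(s.intensity)),
                h, k, l,
            ]
            row += [s.extras.get(c, "") for c in extra_cols]
            writer.writerow(row)


def load_geometry(path) -> tuple[Beam, Detector]:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    try:
        beam = Beam(wavelength=float(cfg["wavelength_angstrom"]),
                    s0_hat=np.asarray(cfg.get("s0_hat", [0.0, 0.0, -1.0]), dtype=float))
        det = Detector(
            distance=float(cfg["distance_mm"]),
            pixel_size=float(cfg["pixel_size_mm"]),
            n_fast=int(cfg["n_fast"]),
            n_slow=int(cfg["n_slow"]),
            beam_center=tuple(float(v) for v in cfg["beam_center_mm"]),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing geometry key {exc}") from exc
    return beam, det


def write_geometry(beam: Beam, det: Detector, path) -> None:
    cfg = {
        "wavelength_angstrom": float(beam.wavelength),
        "s0_hat": [float(v) for v in beam.s0_hat],
        "distance_mm": float(det.distance),
        "pixel_size_mm": float(det.pixel_size),
        "n_fast": int(det.n_fast),
        "n_slow": int(det.n_slow),
        "beam_center_mm": [float(v) for v in det.beam_center],
    }
    with Path(path).open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def write_model(model: CrystalModel, path) -> None:
    cell = model.cell
    doc = {
        "a_matrix": [[float(v) for v in row] for row in model.A],
        "symmetry_tag": model.symmetry_tag,
        "cell": {
            "a": cell.a, "b": cell.b, "c": cell.c,
            "alpha": cell.alpha, "beta": cell.beta, "gamma": cell.gamma,
        },
    }
    with Path(path).open("w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path) -> CrystalModel:
    with Path(path).open() as fh:
        doc = yaml.safe_load(fh)
    return CrystalModel(np.asarray(doc["a_matrix"], dtype=float),
                        symmetry_tag=doc.get("symmetry_tag", "triclinic"))


def write_envelope(env: MosaicEnvelope, path) -> None:
    doc = {
        "eta_deg_fullwidth": env.eta_deg_fullwidth,
        "eta_deg_halfwidth": env.eta_deg_halfwidth,
        "d_eff_angstrom": None if math.isinf(env.d_eff) else env.d_eff,
        "method": env.method,
        "n_spots": env.n_spots,
        "converged": env.converged,
    }
    with Path(path).open("w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_envelope(path) -> MosaicEnvelope:
    with Path(path).open() as fh:
        doc = yaml.safe_load(fh)
    d_eff = doc.get("d_eff_angstrom")
    return MosaicEnvelope(
        eta=math.radians(doc["eta_deg_fullwidth"]),
        d_eff=math.inf if d_eff is None else float(d_eff),
        method=doc.get("method"),
        converged=doc.get("converged"),
        n_spots=doc.get("n_spots"),
    )
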