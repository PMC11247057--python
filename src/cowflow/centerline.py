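"""Radius-annotated vessel centerlines and their file dialects.

A centerline is the raw product of lumen segmentation: an ordered series of
(not necessarily equidistant) 3-D points, each carrying the local lumen
radius.  Three dialects are read:

* a minimal JSON dialect ``{"label": ..., "points": [{"xyz": [x, y, z],
  "radius": r}, ...]}`` (one object, or a list of objects, per file);
* a flat CSV with columns ``label,x,y,z,radius``;
* optionally, 3D Slicer markup (``.mrk.json``) curve files, from which the
  control-point positions and associated radii are lifted.

All coordinates and radii are in cm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "CenterlinePoint",
    "Centerline",
    "read_centerlines_json",
    "read_centerlines_csv",
    "read_centerlines_mrk",
    "write_centerlines_json",
    "write_centerlines_csv",
]


@dataclass(frozen=True)
class CenterlinePoint:
    """A single centerline sample: position (cm) and lumen radius (cm)."""

    position: tuple[float, float, float]
    radius: float

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise InvalidInputError(f"position must be 3 finite coordinates, got {self.position!r}")
        if not (np.isfinite(self.radius) and self.radius > 0):
            raise InvalidInputError(f"radius must be finite and > 0, got {self.radius!r}")
        object.__setattr__(self, "position", tuple(float(x) for x in pos))
        object.__setattr__(self, "radius", float(self.radius))


@dataclass
class Centerline:
    """An ordered, labelled centerline with at least two distinct points."""

    label: str
    points: list[CenterlinePoint] = field(default_factory=list)

    def __post_init__(self):
        if len(self.points) < 2:
            raise InvalidInputError(
                f"centerline {self.label!r} needs >= 2 points, got {len(self.points)}"
            )
        s = self.arc_lengths()
        if np.any(np.diff(s) <= 0):
            raise InvalidInputError(
                f"centerline {self.label!r} has coincident consecutive points; "
                "cumulative arc length must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.points)

    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.points], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([p.radius for p in self.points], dtype=float)

    def arc_lengths(self) -> np.ndarray:
        """Cumulative chordal arc length (cm), zero at the first point."""
        pos = np.array([p.position for p in self.points], dtype=float)
        seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc_lengths()[-1])

    @classmethod
    def from_arrays(cls, label: str, xyz: np.ndarray, radii: np.ndarray) -> "Centerline":
        xyz = np.asarray(xyz, dtype=float)
        radii = np.asarray(radii, dtype=float)
        pts = [CenterlinePoint(tuple(p), float(r)) for p, r in zip(xyz, radii, strict=True)]
        return cls(label, pts)


# ---------------------------------------------------------------------------
# File dialects
# ---------------------------------------------------------------------------

def _centerline_from_obj(obj: dict) -> Centerline:
    try:
        label = obj["label"]
        pts = [CenterlinePoint(tuple(p["xyz"]), float(p["radius"])) for p in obj["points"]]
    except (KeyError, TypeError) as exc:
        raise InvalidInputError(f"malformed centerline JSON object: {exc}") from exc
    return Centerline(label, pts)


def read_centerlines_json(path: str | Path) -> list[Centerline]:
    """Read the package's JSON dialect (single object or list of objects)."""
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict) and "centerlines" in data:
        data = data["centerlines"]
    if isinstance(data, dict):
        data = [data]
    return [_centerline_from_obj(obj) for obj in data]


def write_centerlines_json(centerlines: Iterable[Centerline], path: str | Path) -> None:
    payload = {
        "centerlines": [
            {
                "label": cl.label,
                "points": [{"xyz": list(p.position), "radius": p.radius} for p in cl.points],
            }
            for cl in centerlines
        ]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_centerlines_csv(path: str | Path) -> list[Centerline]:
    """Read the flat CSV dialect ``label,x,y,z,radius`` (row order preserved)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"label", "x", "y", "z", "radius"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"centerline CSV missing columns: {sorted(missing)}")
    out = []
    for label, grp in df.groupby("label", sort=False):
        out.append(Centerline.from_arrays(str(label), grp[["x", "y", "z"]].to_numpy(), grp["radius"].to_numpy()))
    return out


def write_centerlines_csv(centerlines: Iterable[Centerline], path: str | Path) -> None:
    rows = []
    for cl in centerlines:
        for p in cl.points:
            rows.append((cl.label, *p.position, p.radius))
    pd.DataFrame(rows, columns=["label", "x", "y", "z", "radius"]).to_csv(path, index=False)


def read_centerlines_mrk(path: str | Path, label: str | None = None) -> list[Centerline]:
    """Read a 3D Slicer markups JSON file (``.mrk.json``).

    Control-point positions are used as centerline points.  The radius is
    taken, per point, from the first available of: a ``radius`` key, a
    ``Radius`` measurement array, or the ``description`` field parsed as a
    float.  The markup ``name`` becomes the artery label unless overridden.
    """
    with open(path) as fh:
        data = json.load(fh)
    markups = data.get("markups", [])
    out: list[Centerline] = []
    for mk in markups:
        cps = mk.get("controlPoints", [])
        if len(cps) < 2:
            continue
        xyz = np.array([cp["position"] for cp in cps], dtype=float)
        radii = np.empty(len(cps))
        per_point = None
        for meas in mk.get("measurements", []):
            if meas.get("name", "").lower() == "radius" and "controlPointValues" in meas:
                per_point = np.asarray(meas["controlPointValues"], dtype=float)
        for i, cp in enumerate(cps):
            if "radius" in cp:
                radii[i] = float(cp["radius"])
            elif per_point is not None:
                radii[i] = per_point[i]
            else:
                try:
                    radii[i] = float(cp.get("description", ""))
                except ValueError as exc:
                    raise InvalidInputError(
                        f"markup point {i} in {path} carries no radius information"
                    ) from exc
        name = label or mk.get("name", Path(path).stem)
        out.append(Centerline.from_arrays(name, xyz, radii))
    if not out:
        raise InvalidInputError(f"no usable markup curves found in {path}")
    return out
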