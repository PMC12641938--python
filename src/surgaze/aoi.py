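"""Area-of-interest mapping: fixations onto labeled scene surfaces.

The scene is partitioned into three labeled regions — the heads-up display
(HUD), the instrument field (the physical eye model), and the peripheral
view — supplied as simple polygons in pixel coordinates (origin top-left,
y down). Each fixation is assigned by the surface containing its centroid;
boundary points count as inside, overlaps resolve by the fixed priority
HUD > instrument_field > peripheral, and a centroid outside every polygon
falls back to peripheral. The gaze distribution is the per-label share of
assigned fixations (count-weighted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .events import Fixation
from .geometry import ViewGeometry
from .profiles import AOI_LABELS

__all__ = [
    "Surface",
    "GazeDistribution",
    "assign_fixations",
    "gaze_distribution",
    "read_surfaces",
    "write_surfaces",
]

FALLBACK_LABEL = "peripheral"


@dataclass(frozen=True)
class Surface:
    """A labeled AOI polygon in pixel coordinates."""

    label: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise ValueError(f"surface {self.label!r}: need >= 3 vertices")
        if not self.polygon.is_valid:
            raise ValueError(f"surface {self.label!r}: polygon must be simple")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class GazeDistribution:
    """Per-label fixation shares; fractions sum to 1 when any are assigned."""

    proportions: dict[str, float] = field(default_factory=dict)
    assigned_count: int = 0


def _priority(label: str) -> tuple[int, str]:
    try:
        return (AOI_LABELS.index(label), label)
    except ValueError:
        return (len(AOI_LABELS), label)


def assign_fixations(
    fixations: list[Fixation],
    surfaces: list[Surface],
    geometry: ViewGeometry,
) -> list[tuple[int, str]]:
    """Label each fixation by the surface containing its centroid.

    Centroids (degrees) are converted to pixels via the geometry's linear
    scale. Containment includes the boundary; with overlapping surfaces the
    canonical priority order wins; unmatched centroids get the peripheral
    fallback label.
    """
    if geometry is None:
        raise ValueError("geometry is required to map centroids to pixels")
    labels = [s.label for s in surfaces]
    if len(set(labels)) != len(labels):
        raise ValueError("surface labels must be unique")
    ordered = sorted(surfaces, key=lambda s: _priority(s.label))
    prepared = [(s.label, prep(s.polygon)) for s in ordered]

    out: list[tuple[int, str]] = []
    for i, f in enumerate(fixations):
        px, py = geometry.deg_to_px(f.centroid_x, f.centroid_y)
        pt = Point(float(px), float(py))
        label = FALLBACK_LABEL
        for lab, poly in prepared:
            if poly.covers(pt):  # boundary counts as inside
                label = lab
                break
        out.append((i, label))
    return out


def gaze_distribution(assignments: list[tuple[int, str]]) -> GazeDistribution:
    """Per-label counts over the total; empty input gives an empty map."""
    if not assignments:
        return GazeDistribution(proportions={}, assigned_count=0)
    labels = [lab for _, lab in assignments]
    total = len(labels)
    props: dict[str, float] = {}
    for lab in labels:
        props[lab] = props.get(lab, 0.0) + 1.0
    props = {lab: c / total for lab, c in sorted(props.items())}
    return GazeDistribution(proportions=props, assigned_count=total)


def write_surfaces(surfaces: list[Surface], path) -> None:
    """Write surfaces as YAML (or JSON if the suffix says so)."""
    payload = [
        {"label": s.label, "vertices": [[x, y] for x, y in s.vertices]}
        for s in surfaces
    ]
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(payload, fh, indent=1, sort_keys=True)
        else:
            yaml.safe_dump(payload, fh, sort_keys=True)


def read_surfaces(path) -> list[Surface]:
    path = str(path)
    with open(path) as fh:
        payload = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    return [
        Surface(label=item["label"], vertices=tuple(map(tuple, item["vertices"])))
        for item in payload
    ]
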