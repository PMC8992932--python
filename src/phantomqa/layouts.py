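"""Declarative geometric models of the QA phantoms.

A :class:`PhantomLayout` describes, in a phantom-fixed coordinate frame, every
test structure of one phantom model: the signal-producing region, the grid
landmarks and measurement paths used for geometric accuracy, the periodic
resolution patterns or hole arrays, the slice-thickness ramp pairs, the
slice/laser position structures, and the uniformity regions.  Both the
simulator and the analyzers consume the same layout, so recovery tests are
self-consistent by construction.

Coordinate frame
----------------
Right-handed, origin at the phantom center, units mm.  ``+x`` points toward
the phantom's left side and ``+y`` toward anterior; when a layout is rendered
with zero rotation, ``+x`` maps to increasing image column and ``+y`` to
decreasing image row (anterior up).  Structures are positioned with continuous
coordinates; rasterization places pixel centers on a half-integer grid.

Layouts are stored as YAML documents (bundled ``acr.yaml`` and
``insight.yaml``); :func:`load_layout` / :func:`save_layout` round-trip them
losslessly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable

import yaml

__all__ = [
    "StructureSpec",
    "ZoneSpec",
    "PathSpec",
    "PhantomLayout",
    "get_layout",
    "load_layout",
    "save_layout",
    "structures_in_zone",
    "LayoutError",
]

#: Structure kinds understood by the simulator and the analyzers.
STRUCTURE_KINDS = (
    "grid_line",
    "periodic_pattern",
    "ramp_pair",
    "wedge_pair",
    "alignment_channel",
    "uniformity_well",
    "hole_array",
)


class LayoutError(ValueError):
    """Raised for unknown layouts, invalid zones, or malformed layout files."""


@dataclass(frozen=True)
class StructureSpec:
    """One physical test structure.

    ``geometry`` holds kind-specific parameters (all lengths in mm, angles in
    degrees); see the bundled YAML files for the schema of each kind.
    """

    kind: str
    id: str
    zone_id: int
    slice_index: int
    geometry: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in STRUCTURE_KINDS:
            raise LayoutError(f"unknown structure kind {self.kind!r}")

    @property
    def center(self) -> tuple[float, float]:
        return tuple(self.geometry["center"])  # type: ignore[return-value]


@dataclass(frozen=True)
class ZoneSpec:
    """A test zone: a labelled region where tests 2-5 are evaluated."""

    zone_id: int
    center: tuple[float, float]
    label: str


@dataclass(frozen=True)
class PathSpec:
    """A geometric-accuracy measurement path.

    ``kind`` is ``"grid"`` (endpoints are grid-landmark ids) or ``"edge"``
    (endpoints are the phantom-boundary half-maximum crossings along a ray of
    the given angle through the phantom center, as measured with calipers on
    the ACR phantom outline).
    """

    path_id: str
    kind: str  # "grid" | "edge"
    nominal_mm: float
    endpoints: tuple[str, str] | None = None  # grid-node ids (kind == "grid")
    angle_deg: float | None = None  # ray direction (kind == "edge")


@dataclass(frozen=True)
class PhantomLayout:
    """Complete geometric description of one phantom model."""

    name: str  # "ACR" | "INSIGHT"
    signal_region: dict[str, Any]
    structures: tuple[StructureSpec, ...]
    zones: tuple[ZoneSpec, ...]
    paths: tuple[PathSpec, ...]
    analysis_slices: dict[str, int]
    n_slices: int

    # -- lookup helpers ----------------------------------------------------
    @property
    def nominal_lengths(self) -> dict[str, float]:
        return {p.path_id: p.nominal_mm for p in self.paths}

    def zone(self, zone_id: int) -> ZoneSpec:
        for z in self.zones:
            if z.zone_id == zone_id:
                return z
        raise LayoutError(f"layout {self.name} has no zone {zone_id}")

    def structure(self, structure_id: str) -> StructureSpec:
        for s in self.structures:
            if s.id == structure_id:
                return s
        raise LayoutError(f"layout {self.name} has no structure {structure_id!r}")

    def path(self, path_id: str) -> PathSpec:
        for p in self.paths:
            if p.path_id == path_id:
                return p
        raise LayoutError(f"layout {self.name} has no path {path_id!r}")

    def structures_on_slice(self, slice_index: int) -> list[StructureSpec]:
        return [s for s in self.structures if s.slice_index == slice_index]

    def contains(self, points: Iterable[tuple[float, float]], margin: float = 0.0) -> bool:
        """True if every point lies inside the signal region (shrunk by margin)."""
        reg = self.signal_region
        if reg["shape"] == "circle":
            r = reg["radius"] - margin
            return all(math.hypot(x, y) <= r for x, y in points)
        hx, hy = reg["half_size"]
        return all(abs(x) <= hx - margin and abs(y) <= hy - margin for x, y in points)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "n_slices": self.n_slices,
            "signal_region": dict(self.signal_region),
            "analysis_slices": dict(self.analysis_slices),
            "zones": [
                {"zone_id": z.zone_id, "center": list(z.center), "label": z.label}
                for z in self.zones
            ],
            "paths": [
                {
                    "path_id": p.path_id,
                    "kind": p.kind,
                    "nominal_mm": p.nominal_mm,
                    **({"endpoints": list(p.endpoints)} if p.endpoints else {}),
                    **({"angle_deg": p.angle_deg} if p.angle_deg is not None else {}),
                }
                for p in self.paths
            ],
            "structures": [
                {
                    "kind": s.kind,
                    "id": s.id,
                    "zone_id": s.zone_id,
                    "slice_index": s.slice_index,
                    "geometry": dict(s.geometry),
                }
                for s in self.structures
            ],
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PhantomLayout":
        try:
            layout = cls(
                name=d["name"],
                n_slices=int(d["n_slices"]),
                signal_region=dict(d["signal_region"]),
                analysis_slices={k: int(v) for k, v in d["analysis_slices"].items()},
                zones=tuple(
                    ZoneSpec(int(z["zone_id"]), tuple(z["center"]), z["label"])
                    for z in d["zones"]
                ),
                paths=tuple(
                    PathSpec(
                        path_id=p["path_id"],
                        kind=p["kind"],
                        nominal_mm=float(p["nominal_mm"]),
                        endpoints=tuple(p["endpoints"]) if "endpoints" in p else None,
                        angle_deg=p.get("angle_deg"),
                    )
                    for p in d["paths"]
                ),
                structures=tuple(
                    StructureSpec(
                        kind=s["kind"],
                        id=s["id"],
                        zone_id=int(s["zone_id"]),
                        slice_index=int(s["slice_index"]),
                        geometry=dict(s["geometry"]),
                    )
                    for s in d["structures"]
                ),
            )
        except (KeyError, TypeError) as exc:
            raise LayoutError(f"malformed layout document: {exc}") from exc
        layout.validate()
        return layout

    def validate(self) -> None:
        zone_ids = {z.zone_id for z in self.zones}
        for s in self.structures:
            if s.zone_id not in zone_ids:
                raise LayoutError(f"structure {s.id} references unknown zone {s.zone_id}")
            if not (0 <= s.slice_index < self.n_slices):
                raise LayoutError(f"structure {s.id} on out-of-range slice {s.slice_index}")
            if not self.contains([s.center]):
                raise LayoutError(f"structure {s.id} lies outside the signal region")
        node_ids = {s.id for s in self.structures if s.kind == "grid_line"}
        for p in self.paths:
            if p.kind == "grid":
                if p.endpoints is None or any(e not in node_ids for e in p.endpoints):
                    raise LayoutError(f"path {p.path_id} endpoints are not grid landmarks")
            elif p.kind == "edge":
                if p.angle_deg is None:
                    raise LayoutError(f"edge path {p.path_id} needs angle_deg")
            else:
                raise LayoutError(f"path {p.path_id} has unknown kind {p.kind!r}")


def load_layout(path: str | Path) -> PhantomLayout:
    """Read a layout from a YAML file."""
    with open(path) as fh:
        return PhantomLayout.from_dict(yaml.safe_load(fh))


def save_layout(layout: PhantomLayout, path: str | Path) -> None:
    """Write a layout to YAML such that :func:`load_layout` restores it exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(layout.to_dict(), fh, sort_keys=False)


def get_layout(name: str) -> PhantomLayout:
    """Return the bundled layout for ``name`` (``"ACR"`` or ``"INSIGHT"``).

    The returned object is immutable and satisfies all layout invariants
    (e.g. ACR nominal path lengths of 190 mm; Insight 200 mm axes, 282.9 mm
    diagonals and 100 mm peripheral segments; four Insight zones).
    """
    key = name.strip().upper()
    if key not in ("ACR", "INSIGHT"):
        raise LayoutError(f"unknown phantom model {name!r}; expected ACR or INSIGHT")
    ref = resources.files("phantomqa.data").joinpath(f"{key.lower()}.yaml")
    with ref.open() as fh:
        return PhantomLayout.from_dict(yaml.safe_load(fh))


def structures_in_zone(layout: PhantomLayout, zone_id: int, kind: str | None = None) -> list[StructureSpec]:
    """All structures of ``kind`` (any kind if None) assigned to a zone.

    Raises :class:`LayoutError` for a zone id the layout does not define.
    An empty list is a valid result.
    """
    layout.zone(zone_id)  # validates zone_id
    if kind is not None and kind not in STRUCTURE_KINDS:
        raise LayoutError(f"unknown structure kind {kind!r}")
    return [
        s
        for s in layout.structures
        if s.zone_id == zone_id and (kind is None or s.kind == kind)
    ]
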