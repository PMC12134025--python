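"""Plane and marker-layout definitions plus study-setup validation.

A plane is a flat world surface carrying an array of square fiducial
markers (ArUco-style) of known size, position and in-plane orientation.
Individual (single) markers signal trial starts/ends or serve as the
visual transient for multi-recording synchronization.

Setup validation enforces the rules a working study setup must obey:
every marker id is unique across all planes, individual markers never
reuse a plane's ids, and a plane's markers should not be bunched
together (near-degenerate layouts give unstable geometry).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "MarkerSpec",
    "PlaneDefinition",
    "IndividualMarker",
    "TargetPoint",
    "SetupIssue",
    "marker_corners_mm",
    "load_plane_definition",
    "save_plane_definition",
    "validate_setup",
]

INDIVIDUAL_PURPOSES = ("trial_start", "trial_end", "sync_transient")


@dataclass(frozen=True)
class MarkerSpec:
    """One square fiducial marker on a plane."""

    marker_id: int
    edge_size: float            # mm
    center: tuple[float, float]  # mm, plane coords
    rotation: float = 0.0       # deg, counterclockwise in-plane
    family: str = "4x4_50"

    def __post_init__(self) -> None:
        if self.edge_size <= 0:
            raise ValueError("edge_size must be positive")
        if self.marker_id < 0:
            raise ValueError("marker_id must be >= 0")


@dataclass(frozen=True)
class TargetPoint:
    """A named fixation target on a plane (e.g., one of nine validation dots)."""

    name: str
    x: float
    y: float
    is_center: bool = False


@dataclass(frozen=True)
class PlaneDefinition:
    name: str
    markers: tuple[MarkerSpec, ...]
    width: float   # mm bounding box
    height: float
    min_markers: int = 3
    targets: tuple[TargetPoint, ...] = ()

    def __post_init__(self) -> None:
        if len(self.markers) < 1:
            raise ValueError("a plane needs at least one marker")
        if self.min_markers < 1:
            raise ValueError("min_markers must be >= 1")
        ids = [m.marker_id for m in self.markers]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate marker ids within plane {self.name!r}: {sorted(dupes)}")
        for m in self.markers:
            c = marker_corners_mm(m)
            if (np.abs(c[:, 0]) > self.width / 2 + 1e-9).any() or (
                np.abs(c[:, 1]) > self.height / 2 + 1e-9
            ).any():
                raise ValueError(
                    f"marker {m.marker_id} footprint falls outside plane {self.name!r} bounds"
                )

    @property
    def marker_ids(self) -> set[int]:
        return {m.marker_id for m in self.markers}

    def marker_by_id(self, marker_id: int) -> MarkerSpec:
        for m in self.markers:
            if m.marker_id == marker_id:
                return m
        raise KeyError(marker_id)

    def center_target(self) -> TargetPoint:
        for t in self.targets:
            if t.is_center:
                return t
        return TargetPoint("center", 0.0, 0.0, True)


@dataclass(frozen=True)
class IndividualMarker:
    marker_id: int
    purpose: str
    edge_size: float = 40.0
    family: str = "4x4_50"

    def __post_init__(self) -> None:
        if self.purpose not in INDIVIDUAL_PURPOSES:
            raise ValueError(
                f"purpose must be one of {INDIVIDUAL_PURPOSES}, got {self.purpose!r}"
            )


@dataclass(frozen=True)
class SetupIssue:
    severity: str  # "ERROR" | "WARNING"
    message: str


def marker_corners_mm(m: MarkerSpec) -> np.ndarray:
    """Marker corners in plane mm, detector order: TL, TR, BR, BL.

    Corners of the unrotated marker are rotated about the marker centre
    by ``m.rotation`` (counterclockwise, i.e., towards negative y in the
    y-down plane frame) and translated to ``m.center``.
    """
    e = m.edge_size / 2.0
    base = np.array([[-e, -e], [e, -e], [e, e], [-e, e]])
    th = np.deg2rad(m.rotation)
    # counterclockwise on a y-down axis system
    rot = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
    return base @ rot.T + np.asarray(m.center, dtype=float)


# --------------------------------------------------------------------------
# file format (TOML)
# --------------------------------------------------------------------------

def load_plane_definition(path) -> PlaneDefinition:
    """Read a plane-definition TOML file.

    Layout::

        name = "table"
        width_mm = 600.0
        height_mm = 400.0
        min_markers = 3        # optional, default 3

        [[marker]]
        id = 1
        family = "4x4_50"      # optional
        edge_size_mm = 40.0
        center_x_mm = -100.0
        center_y_mm = 0.0
        rotation_deg = 0.0     # optional

        [[target]]             # optional block
        name = "T1"
        x_mm = 0.0
        y_mm = 0.0
        is_center = true       # optional
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    try:
        markers = tuple(
            MarkerSpec(
                marker_id=int(m["id"]),
                edge_size=float(m["edge_size_mm"]),
                center=(float(m["center_x_mm"]), float(m["center_y_mm"])),
                rotation=float(m.get("rotation_deg", 0.0)),
                family=str(m.get("family", "4x4_50")),
            )
            for m in raw.get("marker", [])
        )
        targets = tuple(
            TargetPoint(
                name=str(t["name"]),
                x=float(t["x_mm"]),
                y=float(t["y_mm"]),
                is_center=bool(t.get("is_center", False)),
            )
            for t in raw.get("target", [])
        )
        return PlaneDefinition(
            name=str(raw["name"]),
            markers=markers,
            width=float(raw["width_mm"]),
            height=float(raw["height_mm"]),
            min_markers=int(raw.get("min_markers", 3)),
            targets=targets,
        )
    except KeyError as exc:
        raise ValueError(f"plane definition {path}: missing key {exc}") from exc


def save_plane_definition(plane: PlaneDefinition, path) -> None:
    lines = [
        f'name = "{plane.name}"',
        f"width_mm = {plane.width}",
        f"height_mm = {plane.height}",
        f"min_markers = {plane.min_markers}",
    ]
    for m in plane.markers:
        lines += [
            "",
            "[[marker]]",
            f"id = {m.marker_id}",
            f'family = "{m.family}"',
            f"edge_size_mm = {m.edge_size}",
            f"center_x_mm = {m.center[0]}",
            f"center_y_mm = {m.center[1]}",
            f"rotation_deg = {m.rotation}",
        ]
    for t in plane.targets:
        lines += [
            "",
            "[[target]]",
            f'name = "{t.name}"',
            f"x_mm = {t.x}",
            f"y_mm = {t.y}",
            f"is_center = {'true' if t.is_center else 'false'}",
        ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# setup validation
# --------------------------------------------------------------------------

def validate_setup(
    planes: list[PlaneDefinition],
    singles: list[IndividualMarker] = (),
    spread_ratio_threshold: float = 0.10,
) -> list[SetupIssue]:
    """Check a study setup for the marker-layout pitfalls.

    ERRORs: a marker id used in two planes, or shared between a plane
    and an individual marker.  WARNING: a plane whose marker centres
    span a convex hull smaller than ``spread_ratio_threshold`` of the
    plane area ("markers too close together").  Order-independent and
    idempotent; an empty list means the setup is clean.
    """
    issues: list[SetupIssue] = []
    planes = sorted(planes, key=lambda p: p.name)
    singles = sorted(singles, key=lambda s: s.marker_id)

    for i, a in enumerate(planes):
        for b in planes[i + 1:]:
            for mid in sorted(a.marker_ids & b.marker_ids):
                issues.append(SetupIssue(
                    "ERROR",
                    f"marker {mid} is used in both plane {a.name!r} and plane {b.name!r}; "
                    "every marker must be unique across all planes",
                ))
    for s in singles:
        for p in planes:
            if s.marker_id in p.marker_ids:
                issues.append(SetupIssue(
                    "ERROR",
                    f"individual marker {s.marker_id} ({s.purpose}) is also used in "
                    f"plane {p.name!r}",
                ))
    single_ids = [s.marker_id for s in singles]
    for mid in sorted({i for i in single_ids if single_ids.count(i) > 1}):
        issues.append(SetupIssue(
            "ERROR", f"individual marker {mid} is assigned more than one purpose"))

    for p in planes:
        centers = np.array([m.center for m in p.markers], dtype=float)
        area = 0.0
        if len(centers) >= 3:
            try:
                area = ConvexHull(centers).volume  # 2-D hull "volume" is area
            except QhullError:
                area = 0.0
        if area < spread_ratio_threshold * p.width * p.height:
            issues.append(SetupIssue(
                "WARNING",
                f"markers of plane {p.name!r} are close together (convex-hull area "
                f"{area:.0f} mm^2 < {spread_ratio_threshold:.0%} of plane area); "
                "geometry estimates may be unstable",
            ))
    return issues
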