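"""Landmark annotations, calibration, and result tables.

A *tab* is a 25 x 40 mm wax sheet photographed before and after bees have
built on it.  Everything measured downstream starts from point landmarks
marked on those two photographs: stimulus landmarks on the *before* image,
built-wall endpoints on the *after* image, and four alignment point pairs
that tie the two frames together.  This module owns the on-disk JSON schema
for one tab, the pixel/mm unit handling, and the flat CSV of measurement
records the experiments emit.

Coordinate convention: x rightward, y downward (image convention), origin
top-left.  Angles are measured clockwise from horizontal; undirected wall
orientations are reduced mod 180 deg.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

FRAME_BEFORE = "image-before"
FRAME_AFTER = "image-after"
FRAME_WORLD = "world-mm"
_FRAMES = (FRAME_BEFORE, FRAME_AFTER, FRAME_WORLD)

STIMULUS_KINDS = ("pit", "pit_pair", "v_form", "hybrid")

# landmark names required per stimulus kind
_KIND_POINTS = {
    "pit": ("centre",),
    "pit_pair": ("centre_a", "centre_b"),
    "v_form": ("end_a", "apex", "end_b"),
    "hybrid": ("end_a", "apex", "end_b", "centre_a", "centre_b"),
}


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation content."""


@dataclass(frozen=True)
class Calibration:
    """Image scale of the photographic rig (the study's was ~9 px/mm)."""

    pixels_per_mm: float = 9.0

    def __post_init__(self) -> None:
        if not (self.pixels_per_mm > 0 and math.isfinite(self.pixels_per_mm)):
            raise AnnotationError(
                f"pixels_per_mm must be a positive finite number, got {self.pixels_per_mm!r}"
            )


@dataclass(frozen=True)
class PlanarPoint:
    """A 2-D landmark with an explicit coordinate-frame tag."""

    x: float
    y: float
    frame: str = FRAME_WORLD

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise AnnotationError(f"non-finite coordinates ({self.x}, {self.y})")
        if self.frame not in _FRAMES:
            raise AnnotationError(f"unknown frame tag {self.frame!r}")

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


def px_to_mm(p: PlanarPoint, cal: Calibration) -> PlanarPoint:
    """Convert an image-frame point to world millimetres.

    Raises on world-frame input so a point can never be divided by the
    calibration twice.
    """
    if p.frame == FRAME_WORLD:
        raise AnnotationError("point is already in world-mm; refusing double conversion")
    s = cal.pixels_per_mm
    return PlanarPoint(p.x / s, p.y / s, FRAME_WORLD)


def mm_to_px(p: PlanarPoint, cal: Calibration, frame: str = FRAME_AFTER) -> PlanarPoint:
    """Inverse of :func:`px_to_mm` (world-mm -> image pixels)."""
    if p.frame != FRAME_WORLD:
        raise AnnotationError("mm_to_px expects a world-mm point")
    if frame == FRAME_WORLD:
        raise AnnotationError("target frame must be an image frame")
    s = cal.pixels_per_mm
    return PlanarPoint(p.x * s, p.y * s, frame)


@dataclass(frozen=True)
class StimulusAnnotation:
    """One stimulus (pit, pit pair, V form, or hybrid) as named landmarks."""

    stimulus_id: str
    kind: str
    points: dict[str, PlanarPoint]
    gauge_diameter_mm: float = 4.0
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.kind not in STIMULUS_KINDS:
            raise AnnotationError(
                f"stimulus {self.stimulus_id!r}: unknown kind {self.kind!r}"
            )
        required = _KIND_POINTS[self.kind]
        missing = [n for n in required if n not in self.points]
        if missing:
            raise AnnotationError(
                f"stimulus {self.stimulus_id!r} ({self.kind}): missing landmarks {missing}"
            )
        if not self.gauge_diameter_mm > 0:
            raise AnnotationError(
                f"stimulus {self.stimulus_id!r}: gauge diameter must be positive"
            )
        frames = {p.frame for p in self.points.values()}
        if len(frames) > 1:
            raise AnnotationError(
                f"stimulus {self.stimulus_id!r}: landmarks span frames {sorted(frames)}"
            )

    @property
    def frame(self) -> str:
        return next(iter(self.points.values())).frame


@dataclass(frozen=True)
class WallAnnotation:
    """An undirected built-wall segment marked by its two endpoints."""

    wall_id: str
    p1: PlanarPoint
    p2: PlanarPoint

    def __post_init__(self) -> None:
        if self.p1.frame != self.p2.frame:
            raise AnnotationError(f"wall {self.wall_id!r}: endpoint frames differ")
        if self.p1.xy == self.p2.xy:
            raise AnnotationError(f"wall {self.wall_id!r}: zero-length segment")


@dataclass(frozen=True)
class AlignmentPair:
    """One landmark visible in both photographs."""

    before: PlanarPoint
    after: PlanarPoint

    def __post_init__(self) -> None:
        if self.before.frame != FRAME_BEFORE or self.after.frame != FRAME_AFTER:
            raise AnnotationError("alignment pair frames must be image-before / image-after")


@dataclass
class TabAnnotation:
    """All annotations for one tab: calibration, alignment, stimuli, walls."""

    tab_id: str
    calibration: Calibration
    alignment_pairs: list[AlignmentPair] = field(default_factory=list)
    stimuli: list[StimulusAnnotation] = field(default_factory=list)
    walls: list[WallAnnotation] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.alignment_pairs and len(self.alignment_pairs) != 4:
            raise AnnotationError(
                f"4 alignment points required, got {len(self.alignment_pairs)}"
            )
        image_frames = {s.frame for s in self.stimuli} | {w.p1.frame for w in self.walls}
        image_frames -= {FRAME_WORLD}
        if len(image_frames) > 1 and len(self.alignment_pairs) != 4:
            # both photographs in play -> alignment landmarks must be present
            raise AnnotationError("4 alignment points required to relate the two frames")


# ---------------------------------------------------------------------------
# JSON schema
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


def _point_to_json(p: PlanarPoint) -> list[float]:
    return [p.x, p.y]


def _point_from_json(obj, frame: str, where: str) -> PlanarPoint:
    if not (isinstance(obj, (list, tuple)) and len(obj) == 2):
        raise AnnotationError(f"{where}: expected [x, y], got {obj!r}")
    try:
        return PlanarPoint(float(obj[0]), float(obj[1]), frame)
    except (TypeError, ValueError) as e:
        raise AnnotationError(f"{where}: {e}") from e


def save_tab(tab: TabAnnotation, path) -> None:
    """Write one tab's annotations as a JSON document."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "tab_id": tab.tab_id,
        "calibration": {"pixels_per_mm": tab.calibration.pixels_per_mm},
        "alignment": [
            {"before": _point_to_json(a.before), "after": _point_to_json(a.after)}
            for a in tab.alignment_pairs
        ],
        "stimuli": [
            {
                "id": s.stimulus_id,
                "kind": s.kind,
                "frame": s.frame,
                "is_control": s.is_control,
                "gauge_diameter_mm": s.gauge_diameter_mm,
                "points": {n: _point_to_json(p) for n, p in s.points.items()},
            }
            for s in tab.stimuli
        ],
        "walls": [
            {
                "id": w.wall_id,
                "frame": w.p1.frame,
                "p1": _point_to_json(w.p1),
                "p2": _point_to_json(w.p2),
            }
            for w in tab.walls
        ],
        "meta": tab.meta,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_tab(path) -> TabAnnotation:
    """Load one tab's annotations from the documented JSON schema."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise AnnotationError(f"{path}: not valid JSON ({e})") from e

    if "calibration" not in doc or "pixels_per_mm" not in doc.get("calibration", {}):
        raise AnnotationError(f"{path}: missing calibration.pixels_per_mm")
    cal = Calibration(float(doc["calibration"]["pixels_per_mm"]))

    pairs = []
    for i, a in enumerate(doc.get("alignment", [])):
        pairs.append(
            AlignmentPair(
                before=_point_from_json(a.get("before"), FRAME_BEFORE, f"alignment[{i}].before"),
                after=_point_from_json(a.get("after"), FRAME_AFTER, f"alignment[{i}].after"),
            )
        )

    stimuli = []
    for i, s in enumerate(doc.get("stimuli", [])):
        frame = s.get("frame", FRAME_BEFORE)
        pts = {
            n: _point_from_json(p, frame, f"stimuli[{i}].points[{n}]")
            for n, p in s.get("points", {}).items()
        }
        stimuli.append(
            StimulusAnnotation(
                stimulus_id=str(s.get("id", f"s{i}")),
                kind=s.get("kind", ""),
                points=pts,
                gauge_diameter_mm=float(s.get("gauge_diameter_mm", 4.0)),
                is_control=bool(s.get("is_control", False)),
            )
        )

    walls = []
    for i, w in enumerate(doc.get("walls", [])):
        frame = w.get("frame", FRAME_AFTER)
        walls.append(
            WallAnnotation(
                wall_id=str(w.get("id", f"w{i}")),
                p1=_point_from_json(w.get("p1"), frame, f"walls[{i}].p1"),
                p2=_point_from_json(w.get("p2"), frame, f"walls[{i}].p2"),
            )
        )

    tab = TabAnnotation(
        tab_id=str(doc.get("tab_id", "")),
        calibration=cal,
        alignment_pairs=pairs,
        stimuli=stimuli,
        walls=walls,
        meta=doc.get("meta", {}),
    )
    log.info(
        "loaded tab %s: %d stimuli, %d walls, %d alignment pairs",
        tab.tab_id, len(tab.stimuli), len(tab.walls), len(tab.alignment_pairs),
    )
    return tab


# ---------------------------------------------------------------------------
# Measurement records
# ---------------------------------------------------------------------------

# metric name -> inclusive value range
METRIC_RANGES = {
    "rim_overlap_deg": (0.0, 360.0),
    "tangent_divergence_deg": (0.0, 90.0),
    "bisection_divergence_deg": (0.0, 90.0),
    "proximity_ratio": (0.0, 0.5),
    "wall_orientation_deg": (0.0, 180.0),
    "predicted_orientation_deg": (0.0, 180.0),
}


@dataclass(frozen=True)
class MeasurementRecord:
    """One stimulus's metric value plus real/control provenance."""

    tab_id: str
    stimulus_id: str
    kind: str
    metric: str
    value: float
    is_control: bool
    excluded: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise AnnotationError(
                f"record {self.stimulus_id}/{self.metric}: non-finite value"
            )
        rng = METRIC_RANGES.get(self.metric)
        if rng is not None and not (rng[0] - 1e-9 <= self.value <= rng[1] + 1e-9):
            raise AnnotationError(
                f"record {self.stimulus_id}/{self.metric}: value {self.value} "
                f"outside [{rng[0]}, {rng[1]}]"
            )


_RECORD_COLUMNS = (
    "tab_id", "stimulus_id", "kind", "metric", "value", "is_control", "excluded", "note",
)


def write_records(records: list[MeasurementRecord], path, *, seed=None) -> None:
    """Write measurement records as CSV with a small metadata header.

    Header lines start with ``#`` and carry the schema version and, when
    given, the RNG seed that produced any control stimuli in the table.
    """
    if not records:
        raise AnnotationError("refusing to write an empty record table")
    with open(path, "w", newline="") as fh:
        fh.write(f"# combmetrics records v{SCHEMA_VERSION}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        writer = csv.writer(fh)
        writer.writerow(_RECORD_COLUMNS)
        for r in records:
            writer.writerow(
                [r.tab_id, r.stimulus_id, r.kind, r.metric,
                 repr(r.value), int(r.is_control), int(r.excluded), r.note]
            )


def read_records(path) -> list[MeasurementRecord]:
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(line for line in fh if not line.startswith("#"))]
    if not rows or tuple(rows[0]) != _RECORD_COLUMNS:
        raise AnnotationError(f"{path}: unexpected record header {rows[:1]!r}")
    out = []
    for row in rows[1:]:
        out.append(
            MeasurementRecord(
                tab_id=row[0], stimulus_id=row[1], kind=row[2], metric=row[3],
                value=float(row[4]), is_control=bool(int(row[5])),
                excluded=bool(int(row[6])), note=row[7],
            )
        )
    return out


__all__ = [
    "AnnotationError", "Calibration", "PlanarPoint", "StimulusAnnotation",
    "WallAnnotation", "AlignmentPair", "TabAnnotation", "MeasurementRecord",
    "px_to_mm", "mm_to_px", "save_tab", "load_tab", "write_records",
    "read_records", "FRAME_BEFORE", "FRAME_AFTER", "FRAME_WORLD",
    "STIMULUS_KINDS", "METRIC_RANGES",
]
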