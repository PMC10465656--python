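"""Synthetic annotated tabs with a tunable construction bias.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage — alignment, measurement, controls, inference — is
testable at desk scale without photographs:

* stimuli of the four kinds are laid out on a 25 x 40 mm tab at the study's
  spacing (nearest neighbours ~10-15 mm apart);
* a background of distractor walls sits on a jittered hexagonal lattice
  (worker-cell pitch ~5.2 mm) with a random phase and rotation per tab;
* each stimulus receives one "response" wall.  In **biased** mode its
  orientation is the stimulus-predicted orientation plus folded-normal
  angular noise (sd ``sigma_deg``) and its position tracks the predicted
  location with a small Gaussian offset; the lattice keeps a clearance
  around each stimulus, standing in for the built cell that displaces
  background comb.  In **null** mode construction ignores the stimuli
  entirely: response walls have uniform orientation and uniform position
  over the tab and no clearance is carved, so real and virtual stimuli see
  an exchangeable wall field — the property a type-I-error check needs;
* four alignment landmarks and a mild random projective perturbation give
  each tab a distinct before/after frame pair, so the registration stage is
  exercised end to end.

Ground truth (predicted orientations, realized noise draws) is returned
alongside each tab for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import Homography, estimate_homography
from .annotations import (
    FRAME_AFTER, FRAME_BEFORE, AlignmentPair, Calibration, PlanarPoint,
    StimulusAnnotation, TabAnnotation, WallAnnotation, mm_to_px,
)
from .controls import Bounds, PAIR_SEPARATION_RANGE_MM, V_SPLAY_RANGE_DEG, _as_rng
from .geometry import (
    PitPairStimulus, PitStimulus, VStimulus, bisection_orientation,
    common_tangent_orientation, norm180,
)

DEFAULT_STIMULI_PER_TAB = {"pit": 6, "pit_pair": 6, "v_form": 4, "hybrid": 4}


@dataclass(frozen=True)
class SyntheticTabSpec:
    """Parameters of one synthetic tab.

    Defaults follow the study's set-up: 25 x 40 mm tabs, 4-6 stimuli per tab
    ~10-15 mm apart, 4.0 mm pit gauge, pair separation U[5, 6] mm, V splay
    U[90, 152.2] deg, worker-cell lattice pitch 5.2 mm, ~9 px/mm imaging.
    ``sigma_deg`` is the angular noise of biased response walls (the study's
    empirical spreads of ~5-8 deg motivate the default 5).
    """

    kind: str = "pit_pair"
    n_stimuli: int | None = None          # default depends on kind
    width_mm: float = 25.0
    height_mm: float = 40.0
    margin_mm: float = 4.0                # stimulus keep-out from tab edges
    lattice_pitch_mm: float = 5.2
    lattice_jitter_deg: float = 3.0
    clearance_mm: float = 4.0             # biased mode: no distractors this close
    sigma_deg: float = 5.0
    offset_sd_mm: float = 0.5
    bias_mode: str = "biased"             # "biased" | "null"
    response_wall_mm: float = 4.0
    v_arm_mm: float = 6.0
    hybrid_misalignment_deg: float = 30.0 # tangent vs bisection guide angle
    tangent_follow_frac: float = 1.0      # hybrid: share of walls following the tangent
    pixels_per_mm: float = 9.0
    perturb_px: float = 5.0               # before-frame corner displacement

    def __post_init__(self) -> None:
        if self.kind not in DEFAULT_STIMULI_PER_TAB:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.bias_mode not in ("biased", "null"):
            raise ValueError(f"bias_mode must be 'biased' or 'null', got {self.bias_mode!r}")
        if self.sigma_deg < 0 or self.lattice_pitch_mm <= 0:
            raise ValueError("sigma_deg must be >= 0 and lattice pitch positive")
        if not 0.0 <= self.tangent_follow_frac <= 1.0:
            raise ValueError("tangent_follow_frac must lie in [0, 1]")
        count = self.n_stimuli if self.n_stimuli is not None else DEFAULT_STIMULI_PER_TAB[self.kind]
        if count < 1:
            raise ValueError("n_stimuli must be >= 1")

    @property
    def count(self) -> int:
        return self.n_stimuli if self.n_stimuli is not None else DEFAULT_STIMULI_PER_TAB[self.kind]

    @property
    def bounds(self) -> Bounds:
        return Bounds(0.0, 0.0, self.width_mm, self.height_mm)

    @property
    def stimulus_bounds(self) -> Bounds:
        return self.bounds.inset(self.margin_mm)


@dataclass
class StimulusTruth:
    """Ground truth for one generated stimulus."""

    stimulus_id: str
    kind: str
    focus_mm: tuple[float, float]         # pit centre / pair midpoint / V apex
    predicted_orientation_deg: float | None
    realized_orientation_deg: float | None
    noise_deg: float | None               # signed angular noise actually drawn
    followed: str = ""                    # hybrid: which guide the wall followed
    tangent_orientation_deg: float | None = None
    bisection_orientation_deg: float | None = None
    contact_arc_deg: float | None = None  # pit: rim arc covered by deposition


@dataclass
class SyntheticTruth:
    """Ground truth for one generated tab."""

    spec: SyntheticTabSpec
    homography_before_to_after: Homography
    stimuli: list[StimulusTruth] = field(default_factory=list)
    n_distractor_walls: int = 0


# ---------------------------------------------------------------------------
# Placement and lattice
# ---------------------------------------------------------------------------

def _grid_layout(spec: SyntheticTabSpec, rng: np.random.Generator) -> list[np.ndarray]:
    """Jittered-grid stimulus layout with nearest-neighbour spacing ~10-15 mm.

    A hard-core rejection sampler cannot pack 6 points at >= 10 mm spacing
    on a 25 x 40 mm tab; the study pressed stimuli in rough rows, which a
    jittered grid reproduces.
    """
    b = spec.stimulus_bounds
    n = spec.count
    w, h = b.x_max - b.x_min, b.y_max - b.y_min
    step_lo, step_hi, jitter = 11.5, 13.0, 0.7

    def _steps(n_cols: int):
        n_rows = math.ceil(n / n_cols)
        sx = min(step_hi, w / (n_cols - 1)) if n_cols > 1 else math.inf
        sy = min(step_hi, h / (n_rows - 1)) if n_rows > 1 else math.inf
        return n_rows, sx, sy

    best = None
    for n_cols in range(1, n + 1):
        n_rows, sx, sy = _steps(n_cols)
        if (n_cols > 1 and sx < step_lo) or (n_rows > 1 and sy < step_lo):
            continue
        score = min(sx, sy)
        if best is None or score > best[0]:
            best = (score, n_cols, n_rows, sx, sy)
    if best is None:
        raise ValueError(
            f"cannot place {n} stimuli with ~10-15 mm spacing on a "
            f"{spec.width_mm} x {spec.height_mm} mm tab")
    _, n_cols, n_rows, sx, sy = best
    cx, cy = (b.x_min + b.x_max) / 2.0, (b.y_min + b.y_max) / 2.0
    xs = cx + (np.arange(n_cols) - (n_cols - 1) / 2.0) * (sx if n_cols > 1 else 0.0)
    ys = cy + (np.arange(n_rows) - (n_rows - 1) / 2.0) * (sy if n_rows > 1 else 0.0)
    cells = [(x, y) for y in ys for x in xs][:n]
    out = []
    for x, y in cells:
        out.append(np.array([
            min(b.x_max, max(b.x_min, x + rng.uniform(-jitter, jitter))),
            min(b.y_max, max(b.y_min, y + rng.uniform(-jitter, jitter))),
        ]))
    return out


def _hex_lattice_walls(spec: SyntheticTabSpec, rng: np.random.Generator,
                       keep_out: list[np.ndarray]) -> list[tuple[np.ndarray, np.ndarray]]:
    """Distractor walls: unique edges of a jittered hexagonal tiling.

    The lattice has a random phase offset and a random global rotation per
    tab, and each edge is rotated about its midpoint by Gaussian jitter.
    Edges with a midpoint within ``clearance_mm`` of a keep-out focus are
    dropped (biased mode only — the caller passes an empty list in null
    mode).
    """
    pitch = spec.lattice_pitch_mm
    a = pitch / math.sqrt(3.0)  # hexagon circumradius / edge length
    cx, cy = spec.width_mm / 2.0, spec.height_mm / 2.0
    rot = math.radians(rng.uniform(0.0, 60.0))
    phase = rng.uniform(-pitch, pitch, size=2)
    R = np.array([[math.cos(rot), -math.sin(rot)], [math.sin(rot), math.cos(rot)]])

    # hex centres on a triangular lattice covering the (rotated) tab
    reach = math.hypot(spec.width_mm, spec.height_mm) / 2.0 + 2 * pitch
    n_i = int(reach / pitch) + 2
    n_j = int(reach / (1.5 * a)) + 2
    verts_seen: dict[tuple[int, int], None] = {}
    edges: list[tuple[np.ndarray, np.ndarray]] = []
    edge_keys = set()
    for j in range(-n_j, n_j + 1):
        for i in range(-n_i, n_i + 1):
            hx = i * pitch + (pitch / 2.0 if j % 2 else 0.0) + phase[0]
            hy = j * 1.5 * a + phase[1]
            centre = R @ np.array([hx, hy]) + (cx, cy)
            if not (-pitch <= centre[0] <= spec.width_mm + pitch
                    and -pitch <= centre[1] <= spec.height_mm + pitch):
                continue
            # pointy-top hexagon vertices
            vs = []
            for k in range(6):
                ang = rot + math.radians(60.0 * k + 30.0)
                vs.append(centre + a * np.array([math.cos(ang), math.sin(ang)]))
            for k in range(6):
                p, q = vs[k], vs[(k + 1) % 6]
                key = tuple(sorted((tuple(np.round(p, 4)), tuple(np.round(q, 4)))))
                if key in edge_keys:
                    continue
                edge_keys.add(key)
                mid = (p + q) / 2.0
                if not (0.0 <= mid[0] <= spec.width_mm and 0.0 <= mid[1] <= spec.height_mm):
                    continue
                if any(np.hypot(*(mid - f)) < spec.clearance_mm for f in keep_out):
                    continue
                # jitter the edge about its midpoint
                theta = math.radians(rng.normal(0.0, spec.lattice_jitter_deg))
                Rj = np.array([[math.cos(theta), -math.sin(theta)],
                               [math.sin(theta), math.cos(theta)]])
                edges.append((mid + Rj @ (p - mid), mid + Rj @ (q - mid)))
    del verts_seen
    return edges


def _segment_from_midpoint(mid: np.ndarray, orientation_deg: float,
                           length: float) -> tuple[np.ndarray, np.ndarray]:
    t = math.radians(orientation_deg)
    half = 0.5 * length * np.array([math.cos(t), math.sin(t)])
    return mid - half, mid + half


# ---------------------------------------------------------------------------
# Stimulus + response-wall construction
# ---------------------------------------------------------------------------

def _make_stimulus(spec: SyntheticTabSpec, focus: np.ndarray, sid: str,
                   rng: np.random.Generator):
    """Build one stimulus of the requested kind at a focus point.

    Returns (geometry object(s), landmark dict, predicted orientation or
    None, truth extras).
    """
    kind = spec.kind
    if kind == "pit":
        pit = PitStimulus(tuple(focus))
        return pit, {"centre": focus}, None, {}
    if kind == "pit_pair":
        theta = math.radians(rng.uniform(0.0, 180.0))
        sep = rng.uniform(*PAIR_SEPARATION_RANGE_MM)
        half = 0.5 * sep * np.array([math.cos(theta), math.sin(theta)])
        pair = PitPairStimulus(tuple(focus - half), tuple(focus + half))
        return pair, {"centre_a": focus - half, "centre_b": focus + half}, \
            common_tangent_orientation(pair), {}
    if kind == "v_form":
        bis = rng.uniform(0.0, 360.0)
        splay = rng.uniform(*V_SPLAY_RANGE_DEG)
        ea = focus + spec.v_arm_mm * _unit(bis + splay / 2.0)
        eb = focus + spec.v_arm_mm * _unit(bis - splay / 2.0)
        v = VStimulus(tuple(ea), tuple(focus), tuple(eb))
        return v, {"end_a": ea, "apex": focus, "end_b": eb}, \
            bisection_orientation(v), {}
    # hybrid: V plus a pit pair whose common tangent is deliberately
    # misaligned with the V bisection by hybrid_misalignment_deg
    bis = rng.uniform(0.0, 360.0)
    splay = rng.uniform(*V_SPLAY_RANGE_DEG)
    ea = focus + spec.v_arm_mm * _unit(bis + splay / 2.0)
    eb = focus + spec.v_arm_mm * _unit(bis - splay / 2.0)
    v = VStimulus(tuple(ea), tuple(focus), tuple(eb))
    sign = 1.0 if rng.uniform() < 0.5 else -1.0
    tangent = norm180(bisection_orientation(v) + sign * spec.hybrid_misalignment_deg)
    sep = rng.uniform(*PAIR_SEPARATION_RANGE_MM)
    centre_dir = _unit(tangent + 90.0)  # centre line is orthogonal to the tangent
    ca = focus - 0.5 * sep * centre_dir
    cb = focus + 0.5 * sep * centre_dir
    pair = PitPairStimulus(tuple(ca), tuple(cb))
    points = {"end_a": ea, "apex": focus, "end_b": eb, "centre_a": ca, "centre_b": cb}
    extras = {
        "tangent_orientation_deg": tangent,
        "bisection_orientation_deg": bisection_orientation(v),
    }
    return (v, pair), points, None, extras


def _unit(angle_deg: float) -> np.ndarray:
    t = math.radians(angle_deg)
    return np.array([math.cos(t), math.sin(t)])


def _rim_chain(spec: SyntheticTabSpec, centre: np.ndarray, arc_deg: float,
               start_deg: float, rng: np.random.Generator,
               ) -> list[tuple[np.ndarray, np.ndarray]]:
    """A chain of chords hugging a pit rim over ``arc_deg`` of circumference.

    Emulates wax deposited along part of the rim: chord vertices sit on the
    gauge circle (radius 2 mm) with small radial noise, each chord
    subtending ~30 deg, so the chain stays inside the overlap tolerance
    band along its whole contact arc.
    """
    pit_r = 2.0
    n_seg = max(1, int(round(arc_deg / 30.0)))
    angles = start_deg + np.linspace(0.0, arc_deg, n_seg + 1)
    radii = pit_r + rng.normal(0.0, 0.1, size=n_seg + 1)
    verts = [centre + r * _unit(a) for r, a in zip(radii, angles)]
    return [(verts[k], verts[k + 1]) for k in range(n_seg)]


def _response_walls(spec: SyntheticTabSpec, focus: np.ndarray,
                    predicted_deg: float | None, rng: np.random.Generator,
                    truth: StimulusTruth) -> list[tuple[np.ndarray, np.ndarray]]:
    """The wall(s) built in response to a stimulus, per the bias mode."""
    if spec.kind == "pit":
        # rim deposition covering a partial arc; mean ~140 deg of contact
        arc = float(np.clip(rng.normal(140.0, 40.0), 30.0, 360.0))
        start = rng.uniform(0.0, 360.0)
        truth.contact_arc_deg = arc
        if spec.bias_mode == "null":
            # same chain shape, but placed without regard to the stimulus
            centre = spec.bounds.sample(rng)
        else:
            centre = focus
        return _rim_chain(spec, centre, arc, start, rng)

    if spec.bias_mode == "null":
        # construction indifferent to the stimulus: uniform position and angle
        mid = spec.bounds.sample(rng)
        orient = rng.uniform(0.0, 180.0)
        truth.realized_orientation_deg = orient
        truth.noise_deg = None
        return [_segment_from_midpoint(mid, orient, spec.response_wall_mm)]

    mid = focus + rng.normal(0.0, spec.offset_sd_mm, size=2)
    eps = rng.normal(0.0, spec.sigma_deg)
    # fold the noise into (-90, 90] so the realized wall is an orientation
    eps = (eps + 90.0) % 180.0 - 90.0
    orient = norm180(predicted_deg + eps)
    truth.predicted_orientation_deg = predicted_deg
    truth.realized_orientation_deg = orient
    truth.noise_deg = eps
    return [_segment_from_midpoint(mid, orient, spec.response_wall_mm)]


def _hybrid_response_wall(spec: SyntheticTabSpec, focus: np.ndarray,
                          extras: dict, rng: np.random.Generator,
                          truth: StimulusTruth) -> tuple[np.ndarray, np.ndarray]:
    if spec.bias_mode == "null":
        mid = spec.bounds.sample(rng)
        orient = rng.uniform(0.0, 180.0)
        truth.realized_orientation_deg = orient
        return _segment_from_midpoint(mid, orient, spec.response_wall_mm)
    follow_tangent = rng.uniform() < spec.tangent_follow_frac
    guide = extras["tangent_orientation_deg"] if follow_tangent \
        else extras["bisection_orientation_deg"]
    eps = rng.normal(0.0, spec.sigma_deg)
    eps = (eps + 90.0) % 180.0 - 90.0
    orient = norm180(guide + eps)
    mid = focus + rng.normal(0.0, spec.offset_sd_mm, size=2)
    truth.followed = "tangent" if follow_tangent else "bisection"
    truth.predicted_orientation_deg = guide
    truth.realized_orientation_deg = orient
    truth.noise_deg = eps
    return _segment_from_midpoint(mid, orient, spec.response_wall_mm)


# ---------------------------------------------------------------------------
# Frames and assembly
# ---------------------------------------------------------------------------

def _synthetic_homography(spec: SyntheticTabSpec,
                          rng: np.random.Generator) -> tuple[Homography, list[AlignmentPair]]:
    """A mild projective before->after perturbation with its landmark pairs.

    The after-frame landmarks are the tab corners in pixels; the before
    frame displaces each corner by up to ``perturb_px`` (a fixed
    photographic jig moves little between shots).
    """
    ppm = spec.pixels_per_mm
    corners_after = np.array([
        [0.0, 0.0], [spec.width_mm * ppm, 0.0],
        [spec.width_mm * ppm, spec.height_mm * ppm], [0.0, spec.height_mm * ppm],
    ])
    corners_before = corners_after + rng.uniform(
        -spec.perturb_px, spec.perturb_px, size=corners_after.shape)
    pairs = [
        AlignmentPair(
            before=PlanarPoint(float(b[0]), float(b[1]), FRAME_BEFORE),
            after=PlanarPoint(float(a[0]), float(a[1]), FRAME_AFTER),
        )
        for b, a in zip(corners_before, corners_after)
    ]
    h = estimate_homography(pairs)
    return h, pairs


def generate_tab(spec: SyntheticTabSpec, rng,
                 tab_id: str = "synthetic") -> tuple[TabAnnotation, SyntheticTruth]:
    """Generate one annotated synthetic tab plus its ground truth.

    Stimulus landmarks are written in before-frame pixels and walls in
    after-frame pixels, exactly as a human annotator working on the two
    photographs would produce them; the tab carries the four alignment
    pairs needed to register the frames.
    """
    g = _as_rng(rng)
    cal = Calibration(spec.pixels_per_mm)
    h_ba, align_pairs = _synthetic_homography(spec, g)
    h_ab = h_ba.invert()  # after -> before, for writing stimulus landmarks

    foci = _grid_layout(spec, g)
    truth = SyntheticTruth(spec=spec, homography_before_to_after=h_ba)
    stimuli, walls = [], []
    wall_n = 0
    keep_out = []

    for i, focus in enumerate(foci):
        sid = f"{spec.kind}_{i}"
        st = StimulusTruth(stimulus_id=sid, kind=spec.kind, focus_mm=tuple(focus),
                           predicted_orientation_deg=None,
                           realized_orientation_deg=None, noise_deg=None)
        geom, points, predicted, extras = _make_stimulus(spec, focus, sid, g)
        st.tangent_orientation_deg = extras.get("tangent_orientation_deg")
        st.bisection_orientation_deg = extras.get("bisection_orientation_deg")
        if spec.kind == "hybrid":
            resp = [_hybrid_response_wall(spec, focus, extras, g, st)]
        else:
            st.predicted_orientation_deg = predicted
            resp = _response_walls(spec, focus, predicted, g, st)
        truth.stimuli.append(st)
        keep_out.append(focus)

        # landmarks -> before-frame pixels via the inverse homography
        pts = {}
        for name, mm in points.items():
            after_px = mm_to_px(PlanarPoint(float(mm[0]), float(mm[1])), cal, FRAME_AFTER)
            pts[name] = h_ab.apply(after_px)
        stimuli.append(StimulusAnnotation(
            stimulus_id=sid, kind=spec.kind, points=pts, is_control=False))

        for q1, q2 in resp:
            walls.append(WallAnnotation(
                wall_id=f"resp_{wall_n}",
                p1=mm_to_px(PlanarPoint(float(q1[0]), float(q1[1])), cal, FRAME_AFTER),
                p2=mm_to_px(PlanarPoint(float(q2[0]), float(q2[1])), cal, FRAME_AFTER),
            ))
            wall_n += 1

    lattice_keep_out = keep_out if spec.bias_mode == "biased" else []
    for q1, q2 in _hex_lattice_walls(spec, g, lattice_keep_out):
        walls.append(WallAnnotation(
            wall_id=f"hex_{wall_n}",
            p1=mm_to_px(PlanarPoint(float(q1[0]), float(q1[1])), cal, FRAME_AFTER),
            p2=mm_to_px(PlanarPoint(float(q2[0]), float(q2[1])), cal, FRAME_AFTER),
        ))
        wall_n += 1
    truth.n_distractor_walls = wall_n - len(foci)

    tab = TabAnnotation(
        tab_id=tab_id, calibration=cal, alignment_pairs=align_pairs,
        stimuli=stimuli, walls=walls,
        meta={"synthetic": True, "kind": spec.kind, "bias_mode": spec.bias_mode,
              "sigma_deg": spec.sigma_deg},
    )
    return tab, truth


def render_tab(tab: TabAnnotation, cal: Calibration | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Render grayscale before/after images of a tab's annotations.

    Pits are drawn as dark discs, V strips and walls as bright ridges; the
    two images are related by the tab's alignment landmarks.  Image size is
    the tab extent implied by the after-frame landmarks (a 25 x 40 mm tab at
    9 px/mm renders as 225 x 360 px, width x height).  Intended for visual
    checks and documentation, never for measurement.
    """
    from skimage.draw import disk, line

    cal = cal or tab.calibration
    if tab.alignment_pairs:
        xs = [a.after.x for a in tab.alignment_pairs]
        ys = [a.after.y for a in tab.alignment_pairs]
        w_px, h_px = int(round(max(xs))), int(round(max(ys)))
    else:
        pts = [p for s in tab.stimuli for p in s.points.values()]
        pts += [w.p1 for w in tab.walls] + [w.p2 for w in tab.walls]
        w_px = int(math.ceil(max(p.x for p in pts))) + 10
        h_px = int(math.ceil(max(p.y for p in pts))) + 10
    shape = (h_px, w_px)  # rows = y, cols = x
    before = np.full(shape, 0.5, dtype=float)
    after = np.full(shape, 0.5, dtype=float)

    def _clip_rr_cc(rr, cc):
        ok = (rr >= 0) & (rr < h_px) & (cc >= 0) & (cc < w_px)
        return rr[ok], cc[ok]

    pit_r_px = 2.0 * cal.pixels_per_mm
    for s in tab.stimuli:
        img = before if s.frame == FRAME_BEFORE else after
        if s.kind in ("pit",):
            c = s.points["centre"]
            rr, cc = disk((c.y, c.x), pit_r_px, shape=shape)
            img[rr, cc] = 0.15
        if s.kind in ("pit_pair", "hybrid"):
            for name in ("centre_a", "centre_b"):
                c = s.points[name]
                rr, cc = disk((c.y, c.x), pit_r_px / 2.0, shape=shape)
                img[rr, cc] = 0.15
        if s.kind in ("v_form", "hybrid"):
            apex = s.points["apex"]
            for name in ("end_a", "end_b"):
                e = s.points[name]
                rr, cc = line(int(round(apex.y)), int(round(apex.x)),
                              int(round(e.y)), int(round(e.x)))
                rr, cc = _clip_rr_cc(rr, cc)
                img[rr, cc] = 0.95
    for w in tab.walls:
        img = before if w.p1.frame == FRAME_BEFORE else after
        rr, cc = line(int(round(w.p1.y)), int(round(w.p1.x)),
                      int(round(w.p2.y)), int(round(w.p2.x)))
        rr, cc = _clip_rr_cc(rr, cc)
        img[rr, cc] = 0.95
    return before, after


def recover_bias(tabs, seed=0, kind: str = "pit_pair"):
    """Run the full pipeline on synthetic tabs and recover the angular noise.

    Convenience re-export; see :func:`combmetrics.experiments.recover_bias`.
    """
    from .experiments import recover_bias as _recover

    return _recover(tabs, seed=seed, kind=kind)


__all__ = [
    "SyntheticTabSpec", "StimulusTruth", "SyntheticTruth",
    "generate_tab", "render_tab", "recover_bias", "DEFAULT_STIMULI_PER_TAB",
]
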