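"""End-to-end experiment runners: align -> measure -> controls -> compare.

Each runner mirrors one of the four comb-construction experiments:

1. single pits — rim/wall angular overlap, real vs virtual pits, unpaired
   two-tailed t test;
2. pit pairs — divergence of the nearest wall from the pair's common
   tangent, with the "wall not between the centres" exclusion, rank-sum
   test, Spearman correlation and orientation ratio on the real set;
3. V forms — divergence from the V bisection and the apex proximity ratio
   P = d1/(d1+d2), rank-sum tests for both;
4. hybrids (V + deliberately misaligned pit pair) — per-wall divergence
   from each guide, preference count, paired signed-rank test, plus
   cross-experiment comparisons (tangent divergence vs experiment 2,
   bisection divergence vs experiment 3).

Measurements are taken in the after-image frame: stimulus landmarks marked
on the before photograph are mapped forward through the 4-point homography,
then converted to millimetres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment import estimate_homography
from .annotations import (
    FRAME_BEFORE, FRAME_WORLD, AnnotationError, Calibration,
    MeasurementRecord, PlanarPoint, TabAnnotation, px_to_mm,
)
from .controls import Bounds, _as_rng, virtual_pit, virtual_pit_pair, virtual_v
from .geometry import (
    DEFAULT_OVERLAP_TOL_MM, PitPairStimulus, PitStimulus,
    VStimulus, WallSegment, angular_divergence, bisection_orientation,
    common_tangent_orientation, proximity_ratio,
    rim_wall_overlap, undirected_orientation, wall_between_centres,
)
from .stats import (
    ComparisonResult, orientation_ratio, rank_sum_test, signed_rank_test,
    spearman, t_test_unpaired,
)

log = logging.getLogger(__name__)

DEFAULT_CONTROL_MARGIN_MM = 4.0


class ExperimentError(RuntimeError):
    """Inputs unusable for the requested experiment."""


# ---------------------------------------------------------------------------
# Aligned tab: everything in world millimetres, after-image frame canonical
# ---------------------------------------------------------------------------

class WallField:
    """All walls of one tab in mm, with vectorized distance queries."""

    def __init__(self, walls: list[WallSegment]):
        self.walls = walls
        if walls:
            self.p1 = np.array([w.p1 for w in walls])
            self.p2 = np.array([w.p2 for w in walls])
            self._d = self.p2 - self.p1
            self._dd = np.einsum("ij,ij->i", self._d, self._d)
            self.orientations = np.array([undirected_orientation(w) for w in walls])
        else:
            self.p1 = np.empty((0, 2))
            self.p2 = np.empty((0, 2))
            self._d = np.empty((0, 2))
            self._dd = np.empty(0)
            self.orientations = np.empty(0)

    def __len__(self) -> int:
        return len(self.walls)

    def segment_distances(self, point) -> np.ndarray:
        """Distance from a point to every wall segment."""
        q = np.asarray(point, dtype=float)
        if not len(self.walls):
            return np.empty(0)
        t = np.einsum("ij,ij->i", q - self.p1, self._d) / self._dd
        t = np.clip(t, 0.0, 1.0)
        proj = self.p1 + t[:, None] * self._d
        return np.hypot(*(proj - q).T)

    def corner_distances(self, point) -> np.ndarray:
        """Distance from a point to every wall's nearer endpoint."""
        q = np.asarray(point, dtype=float)
        if not len(self.walls):
            return np.empty(0)
        return np.minimum(np.hypot(*(self.p1 - q).T), np.hypot(*(self.p2 - q).T))

    def near(self, point, radius: float) -> list[WallSegment]:
        d = self.segment_distances(point)
        return [self.walls[i] for i in np.flatnonzero(d <= radius)]

    def nearest(self, point) -> tuple[WallSegment, int]:
        if not len(self.walls):
            raise ExperimentError("no walls on tab")
        i = int(np.argmin(self.segment_distances(point)))
        return self.walls[i], i


@dataclass
class AlignedTab:
    """A tab with all annotations registered and converted to world mm."""

    tab_id: str
    calibration: Calibration
    stimuli: list  # (stimulus_id, kind, geometry object or tuple)
    wall_field: WallField
    bounds: Bounds
    meta: dict = field(default_factory=dict)


def _stimulus_geometry(kind: str, pts: dict, gauge: float):
    if kind == "pit":
        return PitStimulus(pts["centre"], gauge)
    if kind == "pit_pair":
        return PitPairStimulus(pts["centre_a"], pts["centre_b"])
    if kind == "v_form":
        return VStimulus(pts["end_a"], pts["apex"], pts["end_b"])
    if kind == "hybrid":
        return (VStimulus(pts["end_a"], pts["apex"], pts["end_b"]),
                PitPairStimulus(pts["centre_a"], pts["centre_b"]))
    raise AnnotationError(f"unknown stimulus kind {kind!r}")


def align_tab(tab: TabAnnotation,
              control_margin_mm: float = DEFAULT_CONTROL_MARGIN_MM) -> AlignedTab:
    """Register a tab's annotations into the after frame and convert to mm.

    Before-frame stimulus landmarks pass through the homography estimated
    from the tab's four alignment pairs; after-frame landmarks and walls
    only need the px -> mm calibration.  The control-placement bounds are
    the after-frame landmark extent inset by ``control_margin_mm`` (the
    same keep-out real stimuli respect).
    """
    cal = tab.calibration
    h = estimate_homography(tab.alignment_pairs) if tab.alignment_pairs else None

    def to_mm(p: PlanarPoint) -> tuple[float, float]:
        if p.frame == FRAME_WORLD:
            return (p.x, p.y)
        if p.frame == FRAME_BEFORE:
            if h is None:
                raise AnnotationError(
                    "before-frame landmarks present but no alignment pairs")
            p = h.apply(p)
        return px_to_mm(p, cal).xy

    stimuli = []
    for s in tab.stimuli:
        pts = {name: to_mm(p) for name, p in s.points.items()}
        stimuli.append((s.stimulus_id, s.kind,
                        _stimulus_geometry(s.kind, pts, s.gauge_diameter_mm)))

    walls = [WallSegment(to_mm(w.p1), to_mm(w.p2), w.wall_id) for w in tab.walls]

    if tab.alignment_pairs:
        xs = [to_mm(a.after)[0] for a in tab.alignment_pairs]
        ys = [to_mm(a.after)[1] for a in tab.alignment_pairs]
        outer = Bounds(min(xs), min(ys), max(xs), max(ys))
    else:
        pts = [p for _, _, g in stimuli
               for p in (np.atleast_2d(_focus_of(g)))]
        qs = [w.p1 for w in walls] + [w.p2 for w in walls] + [tuple(p) for p in pts]
        xs, ys = zip(*qs)
        outer = Bounds(min(xs), min(ys), max(xs), max(ys))
    bounds = outer.inset(control_margin_mm) if (
        outer.x_max - outer.x_min > 2 * control_margin_mm
        and outer.y_max - outer.y_min > 2 * control_margin_mm) else outer

    return AlignedTab(tab_id=tab.tab_id, calibration=cal, stimuli=stimuli,
                      wall_field=WallField(walls), bounds=bounds, meta=dict(tab.meta))


def _focus_of(geom):
    if isinstance(geom, PitStimulus):
        return geom.centre
    if isinstance(geom, PitPairStimulus):
        return geom.midpoint
    if isinstance(geom, VStimulus):
        return geom.apex
    v, _pair = geom
    return v.apex


# ---------------------------------------------------------------------------
# Per-stimulus measurements
# ---------------------------------------------------------------------------

def measure_pit(pit: PitStimulus, field_: WallField,
                tol_mm: float = DEFAULT_OVERLAP_TOL_MM) -> float:
    """Rim overlap (degrees) of one pit against the tab's wall field."""
    candidates = field_.near(pit.centre, pit.radius + tol_mm)
    return rim_wall_overlap(pit, candidates, tol_mm).total_degrees


def measure_pair(pair: PitPairStimulus, field_: WallField):
    """Tangent divergence of the wall nearest the pair midpoint.

    Returns ``(divergence_deg, excluded, wall_orientation, tangent_orientation)``;
    ``excluded`` is True when the nearest wall's line does not pass between
    the pit centres and the record should be dropped from analysis.
    """
    wall, _ = field_.nearest(pair.midpoint)
    tangent = common_tangent_orientation(pair)
    orient = undirected_orientation(wall)
    div = angular_divergence(orient, tangent)
    excluded = not wall_between_centres(pair, wall)
    return div, excluded, orient, tangent


def measure_v(v: VStimulus, field_: WallField):
    """Bisection divergence and proximity ratio at a V apex.

    The closest wall (by corner distance, matching how walls were marked)
    provides the divergence; the two closest walls provide d1, d2 and
    P = d1/(d1+d2).
    """
    if len(field_) < 2:
        raise ExperimentError("V measurement needs at least 2 walls")
    cd = field_.corner_distances(v.apex)
    order = np.argsort(cd, kind="stable")
    i1, i2 = int(order[0]), int(order[1])
    d1, d2 = float(cd[i1]), float(cd[i2])
    bis = bisection_orientation(v)
    orient = float(field_.orientations[i1])
    div = angular_divergence(orient, bis)
    return div, proximity_ratio(d1, d2), d1, d2


def measure_hybrid(v: VStimulus, pair: PitPairStimulus, field_: WallField):
    """Divergence of the apex-nearest wall from both guides of a hybrid."""
    wall, i = field_.nearest(v.apex)
    orient = undirected_orientation(wall)
    div_t = angular_divergence(orient, common_tangent_orientation(pair))
    div_b = angular_divergence(orient, bisection_orientation(v))
    return div_t, div_b


# ---------------------------------------------------------------------------
# Experiment runners
# ---------------------------------------------------------------------------

@dataclass
class ExperimentOutput:
    """Records plus comparison results for one experiment run."""

    experiment: str
    records: list[MeasurementRecord]
    results: list[ComparisonResult]
    n_excluded_real: int = 0
    n_excluded_control: int = 0
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        parts = [r.summary() for r in self.results]
        if self.n_excluded_real or self.n_excluded_control:
            parts.append(
                f"  excluded: {self.n_excluded_real} real, "
                f"{self.n_excluded_control} control"
            )
        return "\n".join(parts)


def _aligned(tabs, margin):
    out = []
    for t in tabs:
        out.append(t if isinstance(t, AlignedTab) else align_tab(t, margin))
    return out


def _values(records, metric, control):
    return [r.value for r in records
            if r.metric == metric and r.is_control == control and not r.excluded]


def run_experiment1(tabs, seed=0, tol_mm: float = DEFAULT_OVERLAP_TOL_MM,
                    t_variant: str = "welch",
                    control_margin_mm: float = DEFAULT_CONTROL_MARGIN_MM) -> ExperimentOutput:
    """Single-pit rim-overlap experiment with matched virtual-pit controls."""
    rng = _as_rng(seed)
    records = []
    for tab in _aligned(tabs, control_margin_mm):
        pits = [(sid, g) for sid, kind, g in tab.stimuli if kind == "pit"]
        if not pits:
            continue
        for sid, pit in pits:
            records.append(MeasurementRecord(
                tab.tab_id, sid, "pit", "rim_overlap_deg",
                measure_pit(pit, tab.wall_field, tol_mm), is_control=False))
            vp = virtual_pit(pit, tab.bounds, rng)
            records.append(MeasurementRecord(
                tab.tab_id, f"{sid}_ctrl", "pit", "rim_overlap_deg",
                measure_pit(vp, tab.wall_field, tol_mm), is_control=True))
    if not records:
        raise ExperimentError("no pit stimuli found")
    real = _values(records, "rim_overlap_deg", False)
    ctrl = _values(records, "rim_overlap_deg", True)
    res = t_test_unpaired(real, ctrl, t_variant,
                          experiment="experiment 1 (single pits)",
                          metric="rim_overlap_deg")
    return ExperimentOutput("experiment1", records, [res])


def run_experiment2(tabs, seed=0,
                    control_margin_mm: float = DEFAULT_CONTROL_MARGIN_MM) -> ExperimentOutput:
    """Pit-pair tangent-divergence experiment with virtual-pair controls."""
    rng = _as_rng(seed)
    records = []
    real_built, real_pred = [], []
    n_exc = [0, 0]
    for tab in _aligned(tabs, control_margin_mm):
        pairs = [(sid, g) for sid, kind, g in tab.stimuli if kind == "pit_pair"]
        if not pairs:
            continue
        for sid, pair in pairs:
            for is_ctrl, stim, label in (
                    (False, pair, sid),
                    (True, virtual_pit_pair(tab.bounds, rng), f"{sid}_ctrl")):
                div, excluded, orient, tangent = measure_pair(stim, tab.wall_field)
                records.append(MeasurementRecord(
                    tab.tab_id, label, "pit_pair", "tangent_divergence_deg",
                    div, is_control=is_ctrl, excluded=excluded,
                    note="wall not between centres" if excluded else ""))
                if excluded:
                    n_exc[int(is_ctrl)] += 1
                    log.info("excluding %s/%s: nearest wall not between centres",
                             tab.tab_id, label)
                elif not is_ctrl:
                    real_built.append(orient)
                    real_pred.append(tangent)
    if not records:
        raise ExperimentError("no pit-pair stimuli found")
    real = _values(records, "tangent_divergence_deg", False)
    ctrl = _values(records, "tangent_divergence_deg", True)
    res = rank_sum_test(real, ctrl,
                        experiment="experiment 2 (pit pairs)",
                        metric="tangent_divergence_deg")
    if len(real_built) >= 3:
        r, p = spearman(real_pred, real_built)
        res.extras["spearman_r"] = r
        res.extras["spearman_p"] = p
        res.extras["orientation_ratio"] = orientation_ratio(real_built, real_pred)
    return ExperimentOutput("experiment2", records, [res],
                            n_excluded_real=n_exc[0], n_excluded_control=n_exc[1])


def run_experiment3(tabs, seed=0,
                    control_margin_mm: float = DEFAULT_CONTROL_MARGIN_MM) -> ExperimentOutput:
    """V-form experiment: bisection divergence and proximity ratio."""
    rng = _as_rng(seed)
    records = []
    for tab in _aligned(tabs, control_margin_mm):
        vs = [(sid, g) for sid, kind, g in tab.stimuli if kind == "v_form"]
        if not vs:
            continue
        for sid, v in vs:
            for is_ctrl, stim, label in (
                    (False, v, sid),
                    (True, virtual_v(tab.bounds, rng), f"{sid}_ctrl")):
                div, prox, d1, d2 = measure_v(stim, tab.wall_field)
                records.append(MeasurementRecord(
                    tab.tab_id, label, "v_form", "bisection_divergence_deg",
                    div, is_control=is_ctrl))
                records.append(MeasurementRecord(
                    tab.tab_id, label, "v_form", "proximity_ratio",
                    prox, is_control=is_ctrl))
    if not records:
        raise ExperimentError("no V stimuli found")
    res_div = rank_sum_test(
        _values(records, "bisection_divergence_deg", False),
        _values(records, "bisection_divergence_deg", True),
        experiment="experiment 3 (V forms)", metric="bisection_divergence_deg")
    res_prox = rank_sum_test(
        _values(records, "proximity_ratio", False),
        _values(records, "proximity_ratio", True),
        experiment="experiment 3 (V forms)", metric="proximity_ratio")
    return ExperimentOutput("experiment3", records, [res_div, res_prox])


def run_experiment4(tabs, seed=0, paired: bool = True,
                    exp2_divergences=None, exp3_divergences=None,
                    control_margin_mm: float = DEFAULT_CONTROL_MARGIN_MM) -> ExperimentOutput:
    """Hybrid experiment: which guide (tangent or bisection) wins.

    Measures per-wall divergence from both guides, counts walls closer to
    the tangent, and runs a paired signed-rank test between the two
    divergence sets (``paired=False`` switches to the unpaired rank-sum).
    If divergence samples from experiments 2 and 3 are supplied, the
    corresponding cross-experiment rank-sum comparisons are added.
    """
    records = []
    div_t_all, div_b_all = [], []
    for tab in _aligned(tabs, control_margin_mm):
        hybrids = [(sid, g) for sid, kind, g in tab.stimuli if kind == "hybrid"]
        if not hybrids:
            continue
        for sid, (v, pair) in hybrids:
            div_t, div_b = measure_hybrid(v, pair, tab.wall_field)
            div_t_all.append(div_t)
            div_b_all.append(div_b)
            records.append(MeasurementRecord(
                tab.tab_id, sid, "hybrid", "tangent_divergence_deg",
                div_t, is_control=False))
            records.append(MeasurementRecord(
                tab.tab_id, sid, "hybrid", "bisection_divergence_deg",
                div_b, is_control=False))
    if not records:
        raise ExperimentError("no hybrid stimuli found")
    n = len(div_t_all)
    n_tangent = int(sum(t < b for t, b in zip(div_t_all, div_b_all)))
    if paired:
        res = signed_rank_test(div_t_all, div_b_all,
                               experiment="experiment 4 (hybrids)",
                               metric="tangent vs bisection divergence")
    else:
        res = rank_sum_test(div_t_all, div_b_all,
                            experiment="experiment 4 (hybrids)",
                            metric="tangent vs bisection divergence")
    res.extras["n_closer_to_tangent"] = n_tangent
    res.extras["n_closer_to_bisection"] = n - n_tangent
    res.extras["preference_fraction"] = n_tangent / n
    results = [res]
    if exp2_divergences is not None and len(exp2_divergences):
        results.append(rank_sum_test(
            div_t_all, exp2_divergences,
            experiment="experiment 4 vs experiment 2",
            metric="tangent_divergence_deg"))
    if exp3_divergences is not None and len(exp3_divergences):
        results.append(rank_sum_test(
            div_b_all, exp3_divergences,
            experiment="experiment 4 vs experiment 3",
            metric="bisection_divergence_deg"))
    return ExperimentOutput("experiment4", records, results,
                            extras={"preference_fraction": n_tangent / n,
                                    "n": n, "n_closer_to_tangent": n_tangent})


RUNNERS = {
    "pit": run_experiment1,
    "pit_pair": run_experiment2,
    "v_form": run_experiment3,
    "hybrid": run_experiment4,
}


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class BiasRecovery:
    """Outcome of running the full pipeline on synthetic tabs."""

    sigma_hat_deg: float
    comparison: ComparisonResult
    n_real: int

    def summary(self) -> str:
        return (f"recovered angular noise sigma = {self.sigma_hat_deg:.2f} deg "
                f"from n = {self.n_real} measurements\n" + self.comparison.summary())


def recover_bias(tabs, seed=0, kind: str = "pit_pair") -> BiasRecovery:
    """Full pipeline on synthetic tabs: estimate angular noise, test vs controls.

    The angular-noise sd is recovered as sqrt(mean(divergence^2)) over the
    real (non-excluded) divergence measurements — the root-mean-square of a
    half-normal sample estimates the underlying normal sd.
    """
    if kind == "pit_pair":
        out = run_experiment2(tabs, seed=seed)
        metric = "tangent_divergence_deg"
    elif kind == "v_form":
        out = run_experiment3(tabs, seed=seed)
        metric = "bisection_divergence_deg"
    else:
        raise ExperimentError(f"bias recovery supports pit_pair or v_form, not {kind!r}")
    real = np.asarray(_values(out.records, metric, False))
    if not len(real):
        raise ExperimentError("no real measurements survived exclusion")
    sigma_hat = float(np.sqrt(np.mean(real ** 2)))
    comparison = next(r for r in out.results if r.metric == metric)
    return BiasRecovery(sigma_hat_deg=sigma_hat, comparison=comparison,
                        n_real=len(real))


__all__ = [
    "ExperimentError", "WallField", "AlignedTab", "align_tab",
    "measure_pit", "measure_pair", "measure_v", "measure_hybrid",
    "ExperimentOutput", "run_experiment1", "run_experiment2",
    "run_experiment3", "run_experiment4", "RUNNERS", "BiasRecovery",
    "recover_bias", "DEFAULT_CONTROL_MARGIN_MM",
]
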