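# combmetrics

Geometric measurement and statistical inference for honeycomb construction
experiments.

Honeybees begin a comb cell as a shallow circular depression and only later
raise walls around it. A stigmergic account of comb building predicts that
small wax features — a pit, a pair of pits, a V-shaped ridge — should steer
where the first walls appear: wax deposition should start at a pit's rim, a
wall between two pits should lie along their *common tangent* (the line
orthogonal to the centre–centre axis), and a wall at the apex of a V should
lie along the V's internal bisector. Experiments testing these predictions
photograph small wax sheets ("tabs", 25 × 40 mm) before and after bees build
on them, mark stimulus and wall landmarks on the photograph pair, and compare
each geometric measurement against the same measurement taken on randomly
placed *virtual* stimuli.

`combmetrics` is the measurement-and-inference half of such a study, built
for researchers who have (or want to simulate) landmark annotations:

* **Registration** — the before image is mapped onto the after image by the
  plane homography determined exactly by four landmark correspondences,
  removing scale, displacement, rotation and perspective change between the
  photographs.
* **Four metrics** relating stimuli to built walls, computed in world
  millimetres (≈9 px/mm calibration), angles clockwise from horizontal,
  undirected orientations mod 180°:
  * rim overlap — total arc (degrees) of a pit's 4.0 mm gauge circle lying
    within a tolerance band (default 0.35 mm) of any wall, computed
    analytically as circle–capsule arc intersections;
  * tangent divergence — angle in [0°, 90°] between a wall and a pit pair's
    common tangent, with the exclusion rule that drops walls whose line does
    not pass between the pit centres;
  * bisection divergence — angle between a wall and a V's internal bisector;
  * proximity ratio — P = d₁/(d₁+d₂) for the distances from the V apex to
    the nearest and next-nearest wall corners; P ∈ (0, 0.5], small P means
    the wall sits at the apex.
* **Virtual controls** — seeded random stimuli with the study's placement
  laws: virtual pits uniform within 10.0 mm of the real pit, virtual pairs
  with separation uniform on [5.0, 6.0] mm, virtual Vs with splay uniform on
  [90°, 152.2°].
* **Statistics** — unpaired two-tailed t test (Welch or pooled), rank-sum
  (Mann–Whitney) and paired signed-rank tests, Spearman rank correlation,
  and a through-origin orientation-ratio regression after mod-180 unwrapping.
* **Synthetic comb** — a generator that lays stimuli on a tab, surrounds
  them with a jittered hexagonal lattice of distractor walls (worker-cell
  pitch 5.2 mm), plants one response wall per stimulus whose orientation is
  the stimulus-predicted guide plus folded-normal noise (sd σ), and stores
  everything in the same annotation schema with a synthetic before/after
  homography — so the whole pipeline can be exercised and calibrated without
  photographs.

## Worked example

Generate four synthetic pit-pair tabs whose response walls track the common
tangent with σ = 5° of angular noise, then run the pair experiment
end-to-end (align → measure → virtual controls → rank-sum test):

```python
import numpy as np
from combmetrics import SyntheticTabSpec, generate_tab, run_experiment2

rng = np.random.default_rng(7)
spec = SyntheticTabSpec(kind="pit_pair", sigma_deg=5.0)
tabs = [generate_tab(spec, rng, tab_id=f"tab{i}")[0] for i in range(4)]
out = run_experiment2(tabs, seed=99)
print(out.summary())
```

prints

```
experiment 2 (pit pairs) — tangent_divergence_deg
  real    n=24   mean=   2.869  sd=  2.088
  control n=17   mean=  36.497  sd= 21.466
  rank-sum (Mann-Whitney, two-sided): statistic=40  p=1.51e-05
  method = normal-approx
  spearman_r = 0.9974
  spearman_p = 1.296e-26
  excluded: 0 real, 7 control
```

Walls near real pairs diverge from the predicted tangent by ~2.9° on
average (consistent with |N(0, 5°)| noise), while walls near randomly
placed virtual pairs diverge by ~36°; the rank-sum test separates the two
populations decisively, and the built-wall orientations track the predicted
tangent almost one-for-one (Spearman r ≈ 1). Seven control records were
dropped by the between-centres exclusion rule — note that this rule removes
mostly near-90° divergences, which is why the surviving control mean sits
below the 45° expected of a fully uniform null.

The same flow is available from a shell:

```
combmetrics simulate --kind v_form --tabs 6 --sigma 5 --seed 1 --out tabs/
combmetrics run tabs/*.json --seed 2 --out results/
```

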