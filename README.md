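# antwalks

Analysis of desert-ant learning walks, excavation trips and displacement
tests: trajectory metrics, scanning-bout detection, circular statistics of
final headings, and rotational image difference functions (rotIDF) of
panoramic views.

Naive workers of the Australian red honey ant *Melophorus bagoti* perform a
single looping learning walk around the nest before starting work; on
subsequent excavation trips they run straight out, drop sand 5–10 cm from
the entrance, and run straight back. Displaced after their first excavation
trip, they orient toward the nest from 2 m but not from 4 m. This package
provides the full quantitative toolkit for that kind of study, plus a
synthetic-data generator that emulates every input (tracking tables,
heading sets, panoramas) with known ground truth, so the entire pipeline
runs and is testable with no field data.

## What it computes

**Per-walk path metrics** (from 25 fps head/thorax tracking, nest at the
origin): convex-hull area, maximum displacement from the nest, duration,
mean speed with stopping periods excluded, mean orientation angular
velocity |dθ/dt| of the thorax→head axis, and three straightness indices —

- straightness = net displacement / path length ∈ [0, 1];
- sinuosity S = 2 [ p ( (1+c)/(1−c) + b² ) ]^(−1/2), with p the mean step
  length, c the mean cosine of turning angles, b the CV of step length;
- E^a_max = β/(1−β), β the mean cosine of turning angles.

**Scanning bouts**: on-the-spot rotation with ≥ 2 held head directions,
detected from stationarity of the thorax plus a fixation analysis of the
smoothed body-axis angle.

**Circular statistics** of final headings (nest direction = 0°): mean
vector (µ, r̄) with 95% CI, Rayleigh test (Z = n r̄²), V test toward a
prespecified direction (u = r̄ cos(µ−θ₀)·√(2n)), CI-inclusion of the nest
direction, Watson–Williams two-sample comparison, and a single-sample von
Mises likelihood-ratio test of the mean direction (χ², κ̂).

**rotIDF**: root-mean-square pixel difference between a nest panorama and a
test panorama for every 1° rotation; its minimum gives the best-matching
heading and depth = mean − min measures how sharp that minimum is.

**Group statistics**: planned Helmert contrasts across the four walk
conditions (LW, E1, E2, E3) evaluated exactly within ants (each ant
contributes one contrast value; one-sample t test), Welch's one-way ANOVA,
Welch t tests, Tukey-adjusted within-ant pairwise comparisons, and seeded
bootstrap mean-difference intervals.

## Worked example

```bash
python examples/full_experiment.py
```

simulates the default study (20 ants × {1 learning walk + 3 excavation
trips}, four displacement conditions) and runs the full pipeline. Output:

```
          metric       contrast  estimate  statistic      p  significant
convex_hull_area LW vs E1+E2+E3   66.7653    22.9836 0.0000         True
convex_hull_area    E1 vs E2+E3    0.0720     1.0081 0.3261        False
convex_hull_area       E2 vs E3    0.1715     1.8347 0.0823        False
        duration LW vs E1+E2+E3   15.5480    21.9663 0.0000         True
        duration    E1 vs E2+E3    0.2400     1.4928 0.1519        False
        duration       E2 vs E3    0.2000     1.0453 0.3090        False
      mean_speed LW vs E1+E2+E3   -2.3806   -40.5439 0.0000         True
      mean_speed    E1 vs E2+E3    0.0117     0.1597 0.8748        False
      mean_speed       E2 vs E3   -0.0357    -0.4292 0.6726        False

Rayleigh p per displacement condition:
2mE    0.0000
2mN    0.0000
4mE    0.8024
4mN    0.2669
```

Reading it: the learning walk differs from the three excavation trips
(contrast 1) in area covered, time outside and walking speed — larger,
longer and slower — while the three excavation trips do not differ from
each other (contrasts 2–3); headings are clustered toward the nest at the
2 m sites (Rayleigh p < 0.05) but uniform at 4 m. The other examples
(`learning_walk_metrics.py`, `scanning_bouts.py`,
`displacement_headings.py`, `panorama_rotidf.py`) each exercise one
capability and print what the numbers mean.

There is also a thin CLI:

```bash
antwalks simulate --seed 1 --n-ants 20 --out study/
antwalks all --config study/config.yaml --out reports/
```

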