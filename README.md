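# airwaykit

Quantitative upper-airway analysis for rodent micro-CT studies: airway
segmentation, centerline-anchored cross-sectional morphometry, craniofacial
landmark distances, steady incompressible airflow simulation with segment-wise
pressure decomposition, whole-body plethysmography breath analysis, and
two-group Welch statistics.

The package targets the workflow used to characterize upper-airway narrowing
in mouse models of obstructive sleep apnea (OSA) — e.g. the Dp(16)1Yey
Down-syndrome model, whose craniofacial hypoplasia shrinks the skeletal
enclosure of the airway. Because the underlying animal imaging in such
studies is typically not deposited, every algorithm here is validated
against synthetic phantoms with analytic ground truth, and published group
summary tables (mean, SD, n) are treated as first-class inputs that can be
re-analyzed directly.

## What it computes

* **Segmentation** (`segmentation`): the airway lumen is the most negative
  structure in a head CT, so the mask is obtained by intensity inversion,
  a fixed or automatic (Otsu) threshold, and the seeded 26-connected
  component, with slice-wise hole filling.
* **Geometry** (`centerline`, `geometry`): a skeleton-based centerline
  parameterized by arclength *s*; cross-sections on planes perpendicular to
  the local tangent (curved multiplanar reformation) at nine stations,
  +3 … −5 mm around the caudal edge of the hard palate (positive = rostral);
  the three-segment partition (nasal cavity | hard palate | soft palate)
  at the meatus merge and hard-palate landmarks; per-segment volumes out to
  5 mm caudal of the hard palate; and the pharyngeal length from the hard
  palate to the arytenoid.
* **Airflow** (`flow`, `solver3d`): steady, Newtonian, homogeneous,
  incompressible flow at a constant inspiratory flow rate *Q* (default
  5.28 ml/s, a cohort mean of peak inspiratory flow) with nostril pressure
  fixed at 0 Pa. Two solvers share this contract — a quasi-1-D model along
  the centerline,

      P(s) = P(0) − ½ρ[(Q/A(s))² − (Q/A(0))²] − 8πμQ ∫₀ˢ du/A(u)²,

  (Bernoulli exchange + circular-equivalent Poiseuille loss), and a
  marker-and-cell voxel-grid Navier–Stokes solver (pseudo-transient
  projection) validated against the Hagen–Poiseuille law
  ΔP = 8 μLQ/(πR⁴). Summaries report Vmax per region, Pmax at the
  epiglottis, and the telescoping segment drops P_nasal + P_hard + P_soft = Pmax.
* **Plethysmography** (`plethysmography`): quiet-wakefulness epochs (≥ 5 s
  without movement), hysteresis-guarded breath detection, exclusion of
  breaths with tidal volume outside [0.05, 2.0] ml, and the seven standard
  parameters (TV, RR, MV = TV·RR, Ti, Te, PIF, PEF), with
  RR = breaths / extracted time.
* **Morphometry + statistics** (`morphometry`, `stats`): the 26-measure
  linear-distance battery (a–w skull/mandible, x–z hyoid position) over
  landmarks 1–28, per-measure missing-data exclusion, and Welch's
  unequal-variance t-test (Welch–Satterthwaite df) from raw samples **or**
  printed summary rows — the published P values of a summary table can be
  recomputed exactly from the table itself.
* **Phantoms** (`phantoms`): tubes, venturis, curved tubes and a parametric
  mouse upper airway with the six functional landmarks, plus synthetic
  breathing traces and two-group morphometry cohorts — all pure functions
  of (parameters, seed) with analytic ground truth.

## Worked example

Run the full pipeline on the built-in mouse-airway phantom (80 µm voxels for
speed; the native study resolution is 20 µm):

```python
from airwaykit.pipeline import run_pipeline

paths = run_pipeline({
    "seed": 1,
    "output_dir": "demo_out",
    "phantom": {"spacing_mm": 0.08},
    "flow": {"solver": "1d"},
})
```

`demo_out/area_profile.csv` holds the nine station areas (mm²) — the profile
narrows to a nadir 1 mm caudal to the hard palate, as in real mice:

```
station (mm)   +3     +2     +1      0     -1     -2     -3     -4     -5
area (mm²)   1.971  1.835  1.597  1.205  0.747  0.910  1.072  1.179  1.152
```

`demo_out/flow_summary.json` (quasi-1-D solver at 5.28 ml/s):

```json
{
  "pmax_pa": -27.44, "p_nasal_pa": -1.67, "p_hard_pa": -11.88, "p_soft_pa": -13.89,
  "vmax_nasal_m_s": 2.36, "vmax_pharyngeal_m_s": 7.07,
  "v_nasal_mm3": 18.64, "v_pharyngeal_mm3": 4.96, "pharyngeal_length_mm": 5.80
}
```

The pressure at the epiglottis is −27.4 Pa, and the three segment drops
telescope to it exactly. Re-running with `"phantom": {"scale_factor": 0.8}`
(cross-sections uniformly narrowed to 0.8× linear) at the same flow gives
Pmax = −65.1 Pa — narrowing raises the collapsing pressure, the direction
seen when comparing affected animals with controls. (Absolute pascals
depend on the phantom's area profile; a real mouse airway is far more
resistive.)

`demo_out/respiratory.json` recovers the synthetic breathing trace's
parameters (Ti = 81 ms, PIF = 5.28 ml/s, RR = 180/min), and
`demo_out/stats.csv` recomputes Welch P values from published summary rows,
e.g. expiratory time 254.05 ± 28.25 vs 218.26 ± 33.70 (n = 8/8) →
t = 2.302, df = 13.59, **P = 0.0377**.

A `click` CLI mirrors the stages (`airwaykit phantom | segment | centerline |
areas | morpho | cfd | pleth | stats | run`).

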