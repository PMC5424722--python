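# thermoseed

Seed viability assessment from infrared thermography.

During imbibition — the water-uptake phase that opens a germination test
— a seed's surface temperature changes measurably relative to the wet
filter paper it sits on. Viable, aged (partially deteriorated) and
non-viable pea seeds differ in the depth and timing of that cooling:
aged seeds cool deepest, non-viable seeds start their sharp decline
earliest and cool least. `thermoseed` turns paired visible/thermal image
sequences of a germination tray (one frame pair every 5 min over 5 days)
into per-seed relative-temperature curves, reduces each curve to
characteristic parameters, compares the viability groups statistically,
and classifies seeds with a pairwise SVM voting ensemble — including an
*early-decision* model that predicts viability from the first three
hours only, while seeds can still be redried and stored.

It is written for seed-technology and plant-phenotyping researchers who
have (or want to simulate) thermographic germination assays.

## Method

1. **Segmentation** (visible channel): background subtraction by grey
   opening removes uneven illumination and specular reflection points;
   Canny edge extraction plus tolerance-bounded region growing finds
   each seed. A central disk of ~1/3 of the seed area is the
   measurement region; a surrounding filter-paper annulus (1.2–1.6
   equivalent radii, minus all seed masks) is the environment
   reference. Masks are carried into thermal-pixel space by an affine
   (scale + offset) registration transform.
2. **Thermography**: 8-bit thermal grays map linearly onto the preset
   calibration window, `T = T_min + g/255 · (T_max − T_min)` (defaults
   21–27 °C, so one gray step ≈ 0.0235 °C). The relative temperature
   `rT(t) = T_seed(t) − T_env(t)` cancels ambient drift and the
   evaporation baseline.
3. **Curve parameters**: each curve is reduced to 13 scalars — the
   smoothed extrema inside the imbibition window and their times
   (`rT_max`, `trT_max`, `rT_min`, `trT_min`), the sharp-decline onset
   (`rT_drop`, `trT_drop`; earliest sustained slope below
   −θ = −0.005 °C/min), and the values at 0 h, 20 h, …, 120 h — or to
   the 19-value early vector (rT every 10 min over the first 3 h).
4. **Statistics**: per-group mean ± SD summaries and Fisher LSD
   multiple comparisons after one-way ANOVA,
   `SE(i,j) = sqrt(MS_e (1/n_i + 1/n_j))`, tested against
   `t_{α/2}(df_e)` with `df_e = N − k`.
5. **Classification**: three soft-margin RBF-SVMs (C = 2, γ = 2), one
   per class pair, each trained only on its two classes; votes are
   weighted by normalized training accuracies `w_i = p_i / Σ p_j` and
   the largest weight sum wins. Evaluation is 5-fold cross-validation
   with random fold assignment.

A **phantom generator** renders synthetic tray scenes — bright
elliptical seeds on darker filter paper, reflection artifacts,
class-conditional rT kinetics quantized into thermal frames with
ambient drift and sensor noise — with full ground truth, so every stage
is testable without proprietary imagery.

## Worked example

Classify a 120-seed phantom cohort (41 viable / 32 aged / 47
non-viable, the canonical cohort shape) from its full 5-day curves:

```python
from thermoseed import workflow

config = workflow.RunConfig(
    out_dir="example_run", mode="whole_curve", rng_seed=1, render=False,
    cohort={"n_viable": 41, "n_aged": 32, "n_nonviable": 47},
    scene={"grid_rows": 12, "grid_cols": 10, "seed_radius_px": 12.0})
result = workflow.run_experiment(config)
print(result.cv.class_table())
```

prints the pooled 5-fold confusion table (rows = predicted class,
columns = true class):

```
                   viable     aged non_viable
viable                 38        3          1
aged                    2       29          2
non_viable              1        0         44
misjudged/total      3/41     3/32       3/47
accuracy         0.926829  0.90625    0.93617
```

92.5% of seeds are assigned their root-length-verified class; the aged
group, intermediate between viable and dead, is the hardest. The run
directory also gains `group_summary.csv` (e.g. the minimum relative
temperature `rT_min`: viable −1.058 ± 0.192 °C, aged −1.480 ± 0.297 °C,
non-viable −0.631 ± 0.321 °C — aged seeds cool deepest), `lsd.csv` with
the pairwise comparisons, and per-fold tables. Setting
`mode="first_3h"` switches to the 19-value early vector, and
`render=True` exercises the full imaging path (frames → segmentation →
fused curves) instead of feeding ground-truth curves directly.

The same pipeline is scriptable from the shell:

```bash
thermoseed simulate --out sim --seed 2 --viable 8 --aged 6 --nonviable 6
thermoseed run --out run --mode first3h --seed 2
```

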