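# rombergsway

Quantitative analysis of IMU-instrumented Romberg and tandem Romberg
balance tests.

Clinicians screen for vestibular hypofunction (VH) — reduced inner-ear
balance function, unilateral (UVH) or bilateral (BVH) — with static balance
tests judged by eye. Strapping tri-axial accelerometers to the head, pelvis
and both ankles turns those tests into numbers: per-axis sway summaries
that separate patients from healthy controls (HC), with bilateral deficits
surfacing mainly as medio-lateral sway once vision is removed.

`rombergsway` implements that pipeline end to end:

1. **Simulation** (`rombergsway.simulate`) — cohorts of quiet-standing
   recordings (128 Hz, 30 s per condition, four sensor sites, Romberg and
   tandem Romberg, eyes open/closed) with band-limited Gaussian sway,
   gravity expressed in a tilted sensor frame, body-generated
   high-frequency noise, and group-dependent amplitude inflation.
2. **Preprocessing** (`rombergsway.preprocess`) — centred 5-point moving
   average; verticalized anatomical frame (antero-posterior AP,
   medio-lateral ML, cranio-caudal CC) aligned to the measured gravity
   vector; whole-trial baseline-offset removal per anatomical axis.
3. **Kinematic metrics** (`rombergsway.metrics`) — per axis and body part,
   on the baseline-removed acceleration a(t):
   - maximum ACC: `max_t |a(t)|` (m/s²)
   - mean ACC: `mean_t |a(t)|` (m/s²)
   - RMS of ACC: `sqrt(mean_t a(t)²)` (m/s²)
   - MV, mean sway velocity: `mean_t |v(t)|` with `v(t) = ∫ a dt` (m/s)

   That is 4 metrics × 3 axes × 3 body parts (head, pelvis, averaged
   ankles) = 36 parameters per condition, 144 per subject.
4. **Statistics** (`rombergsway.stats`) — pooled-variance Student *t* tests
   with Cohen's *d* for VH vs HC; one-way ANOVA with η² for HC/UVH/BVH;
   Bonferroni correction with family factor 12 (3 axes × 4 metrics);
   Scheffé post hoc pairwise tests gated on the corrected ANOVA; α = 0.05.

## Worked example

```python
import rombergsway as rs

config = rs.CohortConfig(n_per_group=31, seed=42)   # HC, UVH, BVH
cohort, table = rs.simulate_and_extract(config)     # 93 subjects, 1488 trials
results = rs.compare_groups(table, "three-group")
frame = rs.comparison_frame(results)
print(frame[frame.significant].head(3).to_string(index=False))
```

The run above finds 49 of 144 parameters significant after correction, all
in the eyes-closed Romberg and eyes-open tandem conditions (the eyes-closed
tandem destabilises every group about equally, so nothing survives there).
The strongest separations are medio-lateral, e.g.:

```
   test eye_condition body_part axis  metric mean_HC mean_BVH F_stat eta_squared p_anova_bonferroni scheffe_p_HC_BVH
romberg        closed      head   ML max_acc  0.1253   0.3192   91.9      0.6713          2.169e-21        2.130e-19
romberg        closed      head   ML rms_acc  0.0407   0.1000   98.5      0.6864          2.600e-22        3.454e-20
 tandem          open      head   ML max_acc  0.1737   0.4056   84.9      0.6535          2.330e-20        1.691e-18
```

Read: healthy controls' head ML maximum acceleration averages 0.125 m/s²
in the eyes-closed Romberg; bilateral-hypofunction subjects average
0.319 m/s²; the ANOVA (F = 91.9, η² = 0.67) survives the factor-12
Bonferroni correction, and Scheffé confirms the BVH–HC pair. The pooled
VH-vs-HC *t* tests on the same table flag 26 parameters (e.g. head ML
max ACC: t = 4.64, d = 1.02, corrected p = 1.4 × 10⁻⁴). No UVH-vs-HC
comparison survives correction.

The same pipeline runs from the shell:

```sh
rombergsway simulate --seed 42 --out cohort/          # CSV trials + manifest
rombergsway extract  --manifest cohort/manifest.csv --out parameters.csv
rombergsway compare  --parameters parameters.csv --design both --out reports/
# or all at once:
rombergsway run-all --seed 42 --out run/
```

`compare` writes `comparison_two_group.csv` and `comparison_subgroup.csv`
(group mean ± SD, statistic, raw and corrected p, effect size per
parameter).

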