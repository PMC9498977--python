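# hapticube

Analysis pipeline for haptic-exploration recordings from a sensorized cube
(iCube-style device: 6 faces × 16 capacitive cells plus an orientation
quaternion, streamed at an irregular ~5 Hz). It is written for studies that
ask how people explore objects by touch — e.g., how congenitally blind (CB),
late blind (LB) and sighted (SI) participants differ when memorizing and
recognizing pin patterns on the cube — and turns raw touch/orientation
streams into per-trial exploration metrics and group-level statistics.

Because such recordings are not always shareable, the package ships a
synthetic exploration-trace generator whose group presets carry published
group-level targets; every stage of the pipeline is testable against the
generator's scripted ground truth.

## The measures

Each trial is resampled to a constant 0.2 s grid (zero-order hold for the
binary tactile maps, SLERP for the quaternions) and trimmed to the touched
interval (leading/trailing samples with fewer than two active cells are
cut). Explorative touches are separated from holding touches with the
simple matching coefficient between consecutive maps of a face,

    SMC = (M00 + M11) / (M00 + M01 + M10 + M11),

the face with the lowest SMC (ties: all tied faces; all-ones: none) being
the explored face at that instant. Rotation is quantified from the angle
each body axis traverses per grid step,

    Δangle_axis(t) = atan2(‖axis(t) × axis(t−1)‖, axis(t)·axis(t−1)) · 180/π,

with the amount of rotation the maximum per-axis cumulative sum and the
rotation speed the cross-axis mean over instants in motion (> 1 °/s).
Episode sequences of explored faces yield 6×6 transition matrices over
egocentric orientation labels (up/down/front/rear/left/right) with three
scores: maximum diagonal, number of different transitions, number of
returns. Twelve per-trial variables plus recognition accuracy feed the
statistics stage: Box-Cox + BIC Bayes factor for accuracy, MANOVA (Roy's
largest root), Fisher LDA with normalized coefficients, univariate ANOVAs
with Welch post-hocs under Benjamini–Hochberg FDR, and one-tailed Pearson
correlations.

## Worked example

```
python analysis/01_simulate_cohort.py            # 6 CB / 10 LB / 16 SI, seed 42
python analysis/02_extract_metrics.py
python analysis/03_group_statistics.py
python analysis/04_plot_discriminants.py
```

The second step prints the measured group means of the key variables:

```
       mean_active_cells  mean_smc  amount_of_rotation  exploration_duration
group
CB                 5.309     0.746             599.218                57.811
LB                 4.381     0.790             527.851                57.853
SI                 4.214     0.780             734.256                58.017
```

CB participants touch more cells per sample and change them faster (lower
SMC) than LB and SI — the planted group structure — and SI rotate the cube
the most. The statistics step then reports

```
MANOVA Roy = 3.978, F(12, 179) = 59.34, p = 7.7e-56
LDA separation: LD1 74.2% / LD2 25.8%
LD1 group centroids (trial level):
CB    2.15
LB    1.87
SI   -1.98
accuracy BF01 = 13.32 (> 1 favors no group effect)
```

i.e., the haptic profile separates the groups strongly (most of the
separation on the first discriminant, with CB at one extreme and SI at the
other) while recognition accuracy shows no group effect — accuracy is
generated independently of the haptic style, and the Bayes factor correctly
favors the null. Tables land in `results/`, the discriminant scatter in
`scratch/figures/`.

The same operations are scriptable through the CLI:

```
hapticube simulate --n-per-group 6 10 16 --seed 42 --out cohort/
hapticube metrics --session cohort/CB01.jsonl --out metrics.csv
hapticube analyze --metrics metrics.csv --out report/
```

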