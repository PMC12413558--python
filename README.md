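# planeqc

Quality control of midsagittal-plane capture in dynamic transperineal
pelvic-floor ultrasound, driven by the per-frame probability maps of an
upstream organ-segmentation CNN.

## The problem

Transperineal pelvic-floor ultrasound is standardized on the midsagittal
plane, which must show eight structures at once: pubic symphysis, urethra,
urinary bladder, vagina, uterus, anus, rectum and levator ani muscle.
Capturing and holding that plane through a Valsalva maneuver is
operator-dependent; an anteroposterior probe displacement or an image
rotation silently drops organs from the view and corrupts every downstream
measurement.  `planeqc` judges, from a segmenter's per-frame confidence maps,
whether each organ was correctly visualized in a video — and, by conjunction,
whether the midsagittal plane itself was correctly captured — and provides
the agreement statistics used to validate such a judge against human
examiners.

## Method

For every frame and organ, 17 features are computed from the probability map
p ∈ [0,1]^(H×W):

* full-map mean, SD, max, min of p;
* the same four statistics restricted to {p > 0.5} (absolute confidence in
  the detected organ, contrasted with the diffuse full-map confidence), plus
  an empty-set flag;
* the bounding box of {p > 0.5}: row/col bounds, box centroid, width,
  height, area (location/size/aspect consistency).

Frame features are aggregated over windows of N = 60 frames by mean, SD, max
and min, giving 68-feature rows, one per (patient, organ, window) — several
rows per video, a data-augmentation effect.  One XGBoost binary classifier
per organ is selected by random search under patient-grouped 5-fold
cross-validation (no patient's rows ever cross a fold or the train/test
split) and refitted on the full training split.  Per video, window
probabilities are averaged per organ and thresholded at 0.5; the plane
verdict is the AND of the eight organ verdicts.

Agreement between two raters (model vs. reference, or examiner vs. examiner)
is measured with Cohen's kappa κ = (p_o − p_e)/(1 − p_e) with
Fleiss–Cohen–Everitt asymptotic SE, 95% CI and the usual bands (≤0.20 poor,
≤0.40 weak, ≤0.60 moderate, ≤0.80 good, >0.80 very good), the exact binomial
McNemar test on discordant pairs, and t-based CIs for descriptive summaries.

Because no clinical videos or CNN weights ship with the package, a
first-class simulator renders synthetic segmenter output: elliptical
high-confidence blobs in a fixed anatomical layout with per-frame jitter,
slow Valsalva drift, per-video segmenter-quality variation, and the two
defect modes (displacement removes anus/rectum/levator ani; rotation also
removes the uterus and inflates background noise).

## Worked example

`python examples/train_and_evaluate.py` runs the reduced-scale pipeline
(24 videos of 20 frames, 16 train / 8 test patients) and prints:

```
dataset rows: 192 (128 train / 64 test)

test-set agreement with ground truth (kappa undefined when both
the truth and the model are constant, e.g. never-lost organs):
             plane: kappa 0.714 (good), McNemar p = 1.000
             pubis: kappa —      (not estimable)
           urethra: kappa —      (not estimable)
   urinary_bladder: kappa —      (not estimable)
            vagina: kappa —      (not estimable)
            uterus: kappa 1.000 (very good), McNemar p = 1.000
              anus: kappa 1.000 (very good), McNemar p = 1.000
            rectum: kappa 0.714 (good), McNemar p = 1.000
       levator_ani: kappa 1.000 (very good), McNemar p = 1.000
```

Each kappa is the chance-corrected agreement between the model's test-set
verdicts and the ground truth for one endpoint; "not estimable" marks organs
that are never lost under either defect mode, so both the truth and the
model rate every video "correct" and chance agreement is already perfect.
The plane row aggregates all eight organ models through the AND, which is
why it is the hardest endpoint.  At the full study scale (90 videos, 60/30
split) the plane kappa reaches 0.93 ("very good") in the separable regime —
see the reproduction script below.

Other examples: `examples/frame_features.py` (the 17 features on one map),
`examples/simulate_cohort.py` (cohort structure and defect modes),
`examples/concordance_statistics.py` (kappa/McNemar/CI machinery).

There is also a thin CLI mirroring the stages:

```
planeqc simulate --n-correct 45 --n-incorrect 45 --frames 60 --seed 7 --out cohort/
planeqc featurize --videos cohort/ --labels cohort/labels.csv --window 60 --out ds.csv
planeqc train --dataset ds.csv --out model/ --n-iter 50 --seed 7
planeqc predict --model model/ --dataset ds.csv --out verdicts.csv
planeqc concordance --reference ref.csv --rater verdicts.csv --out table.csv
planeqc run --out results/ --seed 7
```

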