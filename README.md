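# falldetect

Per-frame human fall detection from fixed-camera surveillance video, for
researchers and engineers building monitoring systems for hospitals, care
homes and rehabilitation centres, where a missed fall means delayed help.

## Method

The pipeline classifies every frame as `fall` / `sitting` / `no_fall`:

1. **Segmentation** — a clean background image (supplied, or the temporal
   median of early frames) is subtracted from each frame; pixels changed by
   more than 15% of the background pixel value are foreground. A distance
   transform, erosion and hole filling clean the mask, and connected
   components smaller than the minimum person size are discarded. The
   largest survivor is the person blob.
2. **Features** — six blob measurements per frame: bounding-box aspect
   ratio `ar`, body-axis angle `pa` (from the fitted moment ellipse, 90°
   upright → 0° lying), oriented ellipse axis ratio `er`, upper-half
   bounding-box area `sd`, boundary-pixel geometric center `gc`, and
   centroid motion magnitude `|mv|`. Each is summarised by its variance
   over the trailing k = 30-frame window (1 s at 30 fps),
   σ² = (1/k) Σᵢ (v(i) − μ)², giving a 7-dimensional feature vector
   (σ²ar, σ²pa, σ²mv, σ²sd, σ²gcx, σ²gcy, σ²er). Falling makes all of them
   spike at once; walking and sitting do not.
3. **Classification** — boosted C4.5-style trees: splits maximise the gain
   ratio Gain/SplitInfo over midpoint thresholds, and discrete AdaBoost
   (SAMME for three classes) combines K = 10 trees into
   F(x) = Σₖ αₖ·φₖ(x), the frame label being sign{F(x)} (or the argmax
   vote). Boosted full trees are the stronger configuration; boosted
   depth-1 stumps (classic AdaBoost) are also provided.

A built-in simulator renders walking, falling (rapid 10-frame rotation of
the body axis), sitting (the same rotation over 45 frames) and crouching
scenarios with per-frame ground truth, so the whole chain is testable with
no external video data.

## Worked example

End-to-end on synthetic data — simulate 12 balanced fall/walk sequences,
segment, extract windows, 10-fold cross-validate the boosted tree ensemble:

```bash
$ falldetect run --seed 1 --out out/
{
 "accuracy": 1.0,
 "sensitivity": 1.0,
 "specificity": 1.0,
 "auc": 1.0
}
```

Every fall window was caught (sensitivity 1.0) with no false alarms
(specificity 1.0). The harder three-class task, where sitting differs from
falling only in rotation speed:

```python
>>> from falldetect.experiments import three_class_experiment, fall_sit_confusion
>>> report = three_class_experiment(seed=1)
>>> round(report.accuracy, 4)
0.9803
>>> round(fall_sit_confusion(report), 4)
0.0354
```

98% of windows are labelled correctly and only ~3.5% of fall/sitting
windows are confused with each other — the temporal-variance features
separate a rapid fall from a gradual sit-down.

Stage-by-stage CLI verbs (`simulate`, `segment`, `extract`, `train`,
`predict`, `evaluate`) read and write each other's files:

```bash
falldetect simulate --scenario fall --seed 1 --out seq/
falldetect extract  --frames seq/ --background seq/background.png --out features.csv
falldetect train    --features features.csv --model model.json --seed 1
falldetect predict  --model model.json --features features.csv --out preds.csv
```

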