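# uqseg

Bayesian UNet semantic segmentation with Monte-Carlo-dropout uncertainty
quantification, a depthwise-separable efficiency variant, and a full
segmentation + uncertainty evaluation suite — exercisable end to end on a
bundled synthetic lesion-image generator.

The network is implemented in pure numpy (explicit forward/backward passes
and an Adam optimizer), so the package has no deep-learning framework
dependency and runs on a single CPU at desk scale.

## What's inside

| Module | Purpose |
| --- | --- |
| `uqseg.synthetic` | Reproducible synthetic lesion images: irregular diffuse-border blobs on textured skin-toned backgrounds, exact binary masks, PNG + manifest I/O |
| `uqseg.model` | Configurable UNet (depth, base channels, conventional vs depthwise-separable convolutions, dropout placement), analytic MAC-cost formulas, parameter counting, checkpoints |
| `uqseg.training` | Flip/rotate/zoom/brightness/gamma augmentation, Adam training with validation-loss checkpointing, k-fold cross-validation |
| `uqseg.inference` | MC-dropout sampling, posterior-mean probabilities, per-pixel variance uncertainty, [0,1] normalization, map export (PNG + npz) |
| `uqseg.evaluation` | Pixel accuracy, per-class/mean/weighted IoU, Dice; 2×2-patch nac/nau/nic/niu tallies, p(accurate\|certain), p(uncertain\|inaccurate), PAvPU; threshold sweeps; uncertainty-guided pixel-removal curves |
| `uqseg.cli` | `uqseg` command-line workflow tying the stages together |

Key conventions:

* Images are H×W×3 float arrays in [0,1]; masks are H×W in {0,1} (1 = lesion).
* MC uncertainty is the per-class population variance of σ softmax samples,
  averaged over classes, then min-max normalized per image (a constant map
  normalizes to zeros). Dataset-wide normalization is available via
  `normalize_uncertainty(v, vmin=..., vmax=...)`.
* A patch is *accurate* iff its pixel accuracy is strictly greater than 0.5
  and *uncertain* iff its mean uncertainty is strictly greater than the
  threshold; undefined quotients are reported as NaN.

## CLI

```bash
# synthetic dataset: PNG image/mask pairs + manifest.csv
uqseg generate --n 200 --positive-fraction 0.8 --image-size 64 --seed 1 --out data/

# single training run (train/val split, best-val-loss checkpoint)
uqseg train --config config.yaml --data data/ --out run/

# MC-dropout prediction for one image (label, uncertainty, heatmap, npz)
uqseg predict --model run/model.npz --image data/sample_0000_image.png \
              --sigma 100 --seed 0 --out pred/

# pooled metrics / patch-metric threshold sweep over exported predictions
uqseg evaluate --pred pred/ --gt data/ --out report.csv
uqseg sweep --pred pred/ --gt data/ --uncertainty pred/ --thresholds 0:1:0.05 --out sweep.csv

# full pipeline: generate -> k-fold CV -> MC predict -> evaluate/sweep
uqseg run-experiment --config experiment.yaml --out exp/
```

Example `experiment.yaml`:

```yaml
experiment: {seed: 1, out: exp}
data: {n_samples: 200, positive_fraction: 0.8, image_size: 64}
model: {depth: 2, base_channels: 8, conv_kind: conventional,
        dropout_placement: both, dropout_rate: 0.5}
compare: {dropout_placement: [contracting, expansive, both]}  # optional
train: {epochs: 15, batch_size: 16, learning_rate: 0.002,
        augment_factor: 1, k_folds: 2}
inference: {sigma: 25}
evaluation: {thresholds: "0:1:0.05"}
```

`run-experiment` writes per-fold checkpoints and histories, per-image
prediction maps, a metric summary CSV (mean and sd across folds),
removal-curve and sweep CSVs, parameter counts per variant, and a
`manifest.json` recording the config, seeds and stage timestamps. Full-scale
settings (300 epochs, 10 folds, σ=100) are plain config values; the defaults
are desk-scale.

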