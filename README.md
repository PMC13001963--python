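# skelmotion

Occlusion-robust 2D→3D skeleton pose lifting and adaptive-graph skeleton
classification, exercised end-to-end on synthetic skeleton motion.

The toolkit has two learned pipelines plus the supporting machinery to
test them without any external datasets:

* **Pose lifting** — a dual-stage temporal network that takes 2D keypoint
  sequences with per-joint confidences (possibly with randomly missing
  joints per frame) and regresses 3D joint positions. Its input stage
  combines confidence- and distance-weighted interpolation of missing
  keypoints (TLSI) with trend-extrapolated boundary padding (TTEP); the
  encoder fuses two residual feature streams by cross-attention, crops
  back to the original length, and models multiple temporal scales whose
  outputs are blended by learned sigmoid scale weights before a
  convolutional 3D regression head.
* **Skeleton classification** — a graph network that fuses the static
  skeleton adjacency with a per-frame attention-derived dynamic
  adjacency, applies graph convolution and a residual per-node channel
  MLP, pools over time and joints, and classifies with a two-layer head.
  Gradient- and perturbation-based saliency attribute decisions to
  individual joints.

Everything runs on a small numpy reverse-mode autodiff engine
(`skelmotion.nn`), so there is no deep-learning framework dependency.

## Layout

| module | contents |
| --- | --- |
| `skelmotion.skeleton_io` | joint layouts, pose-sequence types, HDF5/CSV/YAML I/O, model config |
| `skelmotion.synthetic_motion` | synthetic 3D/2D motion, occlusion patterns, two-class datasets |
| `skelmotion.oate` | TLSI imputation and TTEP padding |
| `skelmotion.datp_core` | the lifting network, training/evaluation, ablations |
| `skelmotion.pose_metrics` | MPJPE, PCK, threshold-integrated AUC |
| `skelmotion.agtm` | adjacency fusion, graph classifier, classification metrics |
| `skelmotion.explain` | gradient and perturbation joint saliency |
| `skelmotion.benchmarks` | desk-scale experiment protocols (robustness curve, ablations, recovery) |
| `skelmotion.cli` | `skelmotion` command-line entry point |
| `skelmotion.nn` | the autograd engine, layers, optimizers |

## CLI

All subcommands take `--seed` and write a `manifest.json` describing the
run next to their outputs.

```bash
# one synthetic 3D/2D pair with 4 missing joints per frame
skelmotion simulate --frames 81 --n-missing 4 --seed 1 --out out/sim

# impute missing keypoints, then pad boundaries
skelmotion impute --in out/sim/seq_2d.h5 --out out/imputed.h5 --window 3 --lambda-t 1.0
skelmotion pad --in out/imputed.h5 --out out/padded.h5 --k 3 --pad 5

# train and evaluate the lifting network on synthetic pairs
skelmotion train-pose --synthetic 8 --frames 24 --epochs 30 --seed 1 --out-dir out/pose
skelmotion eval-pose --model out/pose/datp_model.h5 --test-dir <dir-of-pairs> --out-dir out/eval

# two-class dataset, classifier, metrics, saliency
skelmotion simulate --frames 24 --effect-size 3.0 --n-per-class 20 --seed 1 --out out/ds
skelmotion train-clf --data-dir out/ds --epochs 60 --seed 1 --out-dir out/clf
skelmotion eval-clf --model out/clf/agtm_model.h5 --data-dir out/ds --out-dir out/clfeval
skelmotion explain --model out/clf/agtm_model.h5 --seq out/ds/sample_0000.h5 \
    --method perturbation --top-k 5 --out-dir out/sal
```

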