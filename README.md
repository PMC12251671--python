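# cogpose

Physics-constrained whole-body 2D→3D human pose lifting: an
anthropometric center-of-gravity engine, bone-vector pose encoding,
physics-constrained loss functions, a dual-branch cross-attention
Transformer lifter, and MPJPE evaluation — all testable end to end on
synthetic skeleton/camera data, with no GPU and no external datasets.

## Who this is for

Researchers and engineers in biomechanics and human movement analysis who
need (a) a clean reference implementation of center-of-gravity moment
synthesis over body segments, (b) a monocular 2D→3D lifting pipeline for
the 133-keypoint COCO-WholeBody layout whose training enforces physical
structure, or (c) a reproducible synthetic benchmark for studying how
such constraints behave under keypoint noise and occlusion.

## The model in brief

**Center of gravity by moment synthesis.** The body is divided into 15
rigid segments with gender-specific relative masses `k_i` and centroid
positions (`Les`/`Lex` splits of segment length, from the "Inertial
Parameters of Adult Human Body" tables, shipped as package data). A
segment centroid is `P_prox·Lex + P_dist·Les`, and the whole-body CoG is

    X_CoG = Σ_i k_i x_i   (likewise Y, Z),

which collapses to a single per-keypoint weight vector `w` with
`CoG = w·P` for any pose `P`.

**Physics-constrained lifting.** A dual-branch Transformer embeds each 2D
keypoint (coordinate tokens) and each skeleton bone `b/‖b‖ ⊕ log(‖b‖+ε)`
(bone tokens), fuses the streams with cross-attention, and regresses the
root-relative 3D pose. Training minimizes

    L_total = w_pos·L + w_cog·L_gd + w_bone·L_bone

with `L` the mean per-joint Euclidean distance,
`L_gd = mean_i (g_i − ĝ_i)²` comparing every keypoint's distance to its
pose's own CoG against ground truth, and
`L_bone = mean_e (1 − cos(b_e, b̂_e)) + λ‖b_e − b̂_e‖` enforcing limb
orientation and length. Evaluation is MPJPE (mm), reported for the
whole body and the body/face/hands groups.

The network, its AdamW training loop, and all loss gradients run on a
small reverse-mode autodiff engine over numpy included in the package, so
everything works on one CPU.

## Worked example

```python
import numpy as np
from cogpose import (SynthConfig, make_benchmark, desk_model_config,
                     desk_train_config, fit, evaluate, load_table,
                     body_cog, Pose3D)

# 1. a reproducible synthetic benchmark (2,000 train / 400 val / 400 test)
data = make_benchmark(SynthConfig(seed=11))

# 2. train the small CPU profile for a few epochs
model, history = fit(data["train"], data["val"],
                     desk_model_config(), desk_train_config(epochs=8, seed=0))
print(f"val MPJPE after training: {history[-1]['val_mpjpe_mm']:.1f} mm")
report = evaluate(model, data["test"])
print({k: round(v, 1) for k, v in report.items()})

# 3. center of gravity of one ground-truth pose
pose = Pose3D(coords=data["test"]["kp3d"][0], frame="root_relative")
print("CoG (mm):", np.round(body_cog(pose, load_table("M")).coords, 1))
```

Output from this exact script (seeds fixed as shown):

```
val MPJPE after training: 182.4 mm
{'whole_body': 180.0, 'body': 195.9, 'face': 67.5, 'hands': 353.4}
CoG (mm): [-19.  -77.3  -3.1]
```

The whole-body validation MPJPE falls from 224 mm after the first epoch
to 182 mm by the eighth; face keypoints (rigid, well-observed) are easy
while hands (small, articulated, depth-ambiguous) dominate the error.
The CoG is a point inside the trunk a few centimetres above the mid-hip
root (the camera frame has y pointing down), as expected for an upright
pose.
Absolute errors at this scale are far above the paper-scale regime — the
desk profile is two orders of magnitude smaller than the reference
configuration (6 layers, 8 heads, width 256, 210 epochs), which is also
expressible via `ModelConfig()`/`TrainConfig()` defaults.

## Command line

```bash
cogpose synth --config config.yaml --out-dir data/        # benchmark
cogpose train --config config.yaml --dataset data/        # checkpoint
cogpose eval runs/train/checkpoint.npz data/ --split test # MPJPE report
cogpose cog poses.json                                    # CoG trajectory
cogpose check-tables                                      # table invariants
```

Every command writes its resolved configuration and seed next to its
outputs; exit codes are 0 (ok), 2 (usage), 3 (data error), 4 (numerical
failure).

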