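# t1moco

Groupwise, multi-scale deformable motion correction for cardiac
inversion-recovery T1 mapping, together with everything needed to exercise
it end to end without scanner data:

- **`t1moco.phantom`** — synthetic short-axis cardiac slices (blood pool,
  myocardial ring, body, liver-like structure) and their 7
  inversion-recovery-weighted (IRW) frames from a magnitude signal model
  `|A − B·exp(−TI/T1*)|`, with optional Rician-surrogate noise and a
  point-spread blur.
- **`t1moco.dvf`** — displacement-vector-field algebra: smooth random
  topology-preserving fields (positive-Jacobian certificate), per-pixel
  frame-mean removal, backward bilinear warping, composition and
  fixed-point numerical inversion.
- **`t1moco.moconet`** — the registration network: a shared-weight
  per-frame encoder (3×3 conv → batch norm → leaky ReLU → max-pool per
  level) and a coarse-to-fine decoder with warping layers at each of 4
  scales, emitting per-scale sets of 7 inverse displacement fields
  (zero-initialised heads, so the untrained network is an identity
  corrector). Implemented on a small NumPy layer library
  (`t1moco.nn`) with hand-written backprop and an Adam optimiser — no deep
  learning framework required.
- **`t1moco.training`** — synthetic-deformation training pairs (deform
  clean stacks with mean-removed random fields, regress their numerical
  inverses), quantile normalisation + centred zero-padding, and the
  training loop (Adam lr 1e-3, batch 4, reduce-on-plateau scheduler, early
  stopping on the validation multi-scale loss).
- **`t1moco.t1map`** — per-pixel 3-parameter inversion-recovery fitting
  with polarity search and Look-Locker correction, T1/R² map
  reconstruction, and an R²-based motion-severity proxy.
- **`t1moco.evalstats`** — inverse-variance observer-score pooling and its
  standard error, intra-observer SD from duplicates, Wilcoxon signed-rank
  comparison, and endpoint-error metrics against synthetic ground truth.
- **`t1moco.io_container` / `t1moco.pipeline` / `t1moco.cli`** — fixture
  container (single-file `.npz`), thin NIfTI (+TI sidecar) and optional
  DICOM readers, provenance-stamped pipelines.

## CLI

```bash
# 1. generate clean phantom stacks
t1moco simulate --n 200 --out data/clean --seed 0

# 2. train the registration network
t1moco train --data data/clean --out run1 --epochs 12 --patience 12 --seed 7

# 3. generate motion-corrupted test stacks (ground truth stored alongside)
t1moco simulate --n 20 --motion-amplitude 3 --out data/motion --seed 1

# 4. correct one stack: corrected frames, predicted fields, pre/post T1+R² maps
t1moco correct --stack data/motion/stack_0000.npz \
               --checkpoint run1/checkpoint.npz --out out/case0

# 5. score a whole directory against the ground truth
t1moco evaluate --data data/motion --checkpoint run1/checkpoint.npz --out out/eval
```

Every artifact directory contains `provenance.json` (effective config,
seed, package version, input checksums).

Conventions, stated once: row-major arrays, 0-based indexing, displacement
fields stored in pixels as `(H, W, 2)` with `(row, col)` components,
backward-map warping `out(x) = image(x + u(x))` with bilinear
interpolation.

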