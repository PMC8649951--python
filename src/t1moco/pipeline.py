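"""End-to-end pipelines behind the CLI subcommands.

Kept importable (no CLI dependencies) so tests drive the exact code paths
the command line uses. Every pipeline writes an artifact directory with the
effective configuration, seed, package version and input checksums.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from . import dvf as dvfmod
from . import io_container as ioc
from . import moconet, t1map, training
from .errors import ContractError, FormatError
from .evalstats import dvf_recovery_metrics, paired_wilcoxon
from .phantom import IRWStack, LABELS, make_phantom, simulate_irw

__all__ = ["simulate_dataset", "run_train", "run_correct", "run_evaluate"]


def _write_provenance(out_dir: Path, config: dict, seed, inputs: list[Path]):
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = {
        "t1moco_version": __version__,
        "seed": seed,
        "config": config,
        "input_checksums": {str(p): ioc.file_checksum(p) for p in inputs if Path(p).is_file()},
    }
    (out_dir / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))


def simulate_dataset(
    out_dir,
    n_stacks: int,
    shape=(64, 64),
    noise_sigma: float = 1.0,
    motion_amplitude_px: float = 0.0,
    smoothness_px: float = 8.0,
    jitter_px: float = 2.0,
    blur_sigma_px: float = 1.0,
    seed: int = 0,
) -> list[Path]:
    """Generate phantom stacks; with ``motion_amplitude_px > 0`` each stack
    is synthetically deformed and its ground-truth inverse fields stored."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = []
    for i in range(n_stacks):
        stack_seed = int(rng.integers(2**31))
        scale = min(shape) / 64.0
        tm = make_phantom(shape=shape, r_inner=8.0 * scale, r_outer=14.0 * scale,
                          jitter_px=jitter_px * scale, seed=stack_seed)
        stack = simulate_irw(tm, noise_sigma=noise_sigma, seed=stack_seed + 1,
                             blur_sigma_px=blur_sigma_px)
        gt_inverse = None
        if motion_amplitude_px > 0:
            pair = training.make_training_pair(
                stack, motion_amplitude_px, smoothness_px, seed=stack_seed + 2
            )
            stack = pair.deformed_stack
            gt_inverse = pair.gt_inverse
        paths.append(
            ioc.save_stack_fixture(out_dir / f"stack_{i:04d}.npz", stack, gt_inverse=gt_inverse)
        )
    _write_provenance(
        out_dir,
        {
            "n_stacks": n_stacks, "shape": list(shape), "noise_sigma": noise_sigma,
            "motion_amplitude_px": motion_amplitude_px, "smoothness_px": smoothness_px,
            "jitter_px": jitter_px, "blur_sigma_px": blur_sigma_px,
        },
        seed,
        [],
    )
    return paths


def run_train(
    data_dir,
    out_dir,
    net_config: moconet.NetworkConfig | None = None,
    train_config: training.TrainConfig | None = None,
    seed: int = 0,
) -> Path:
    """Train on every fixture stack in ``data_dir``; write checkpoint and
    tabular history."""
    data_dir = Path(data_dir)
    out_dir = Path(out_dir)
    paths = sorted(data_dir.glob("*.npz"))
    stacks = [ioc.load_stack_fixture(p) for p in paths]
    net_config = net_config or moconet.NetworkConfig()
    train_config = train_config or training.TrainConfig()
    train_config.seed = seed
    model = moconet.build_network(net_config, seed=seed)
    model, history = training.train(model, stacks, train_config)

    out_dir.mkdir(parents=True, exist_ok=True)
    ckpt = out_dir / "checkpoint.npz"
    moconet.save_checkpoint(ckpt, model, extra={"history_best_epoch": history["best_epoch"]})
    import pandas as pd

    pd.DataFrame(
        {
            "epoch": np.arange(1, len(history["train_loss"]) + 1),
            "train_loss": history["train_loss"],
            "val_loss": history["val_loss"],
            "lr": history["lr"],
        }
    ).to_csv(out_dir / "history.csv", index=False)
    _write_provenance(
        out_dir,
        {"network": asdict(net_config), "training": asdict(train_config)},
        seed,
        paths,
    )
    return ckpt


def _prepare_for_inference(stack: IRWStack, model: moconet.RegistrationModel):
    d = model.config.divisor
    H, W = stack.frame_shape
    PH = int(np.ceil(H / d) * d)
    PW = int(np.ceil(W / d) * d)
    norm = training.quantile_normalize(stack.images)
    padded, offsets = training.pad_to_size(norm, (PH, PW))
    return padded.astype(np.float32), offsets


def correct_stack(stack: IRWStack, model: moconet.RegistrationModel):
    """Predict inverse fields for a stack and warp its frames by them.

    Normalisation/padding is applied for inference only and inverted around
    it; the returned frames are in the stack's original intensity units.
    Returns ``(corrected_stack, predicted DVFSet)`` at the original size.
    """
    padded, offsets = _prepare_for_inference(stack, model)
    pred_padded = moconet.predict_dvfs(model, padded)
    H, W = stack.frame_shape
    fields = pred_padded.as_array()  # (7, PH, PW, 2)
    r0, c0 = offsets
    fields = fields[:, r0:r0 + H, c0:c0 + W, :]
    pred = dvfmod.DVFSet.from_array(fields)
    corrected = np.stack(
        [np.clip(dvfmod.warp(frame, f, fill_value=0.0), 0.0, None)
         for frame, f in zip(stack.images, pred)]
    )
    return stack.copy_with(images=corrected, corrected_by=f"t1moco {__version__}"), pred


def run_correct(stack_path, checkpoint_path, out_dir, seed: int = 0) -> dict:
    """The `correct` pipeline: motion-corrected frames, predicted fields and
    pre/post T1 + R^2 maps."""
    stack_path = Path(stack_path)
    checkpoint_path = Path(checkpoint_path)
    out_dir = Path(out_dir)
    if not checkpoint_path.is_file():
        raise FormatError(
            f"checkpoint not found: {checkpoint_path} — train one with 't1moco train' "
            "or pass --checkpoint pointing at an existing checkpoint.npz"
        )
    stack = ioc.read_irw_stack(stack_path)
    model = moconet.load_checkpoint(checkpoint_path)

    t0 = time.perf_counter()
    corrected, pred = correct_stack(stack, model)
    elapsed = time.perf_counter() - t0

    t1_pre, r2_pre = t1map.reconstruct_maps(stack)
    t1_post, r2_post = t1map.reconstruct_maps(corrected)

    out_dir.mkdir(parents=True, exist_ok=True)
    ioc.save_stack_fixture(out_dir / "corrected.npz", corrected)
    np.savez_compressed(out_dir / "predicted_dvfs.npz", dvfs=pred.as_array())
    for name, arr in (
        ("t1_pre", t1_pre.t1_ms), ("t1_post", t1_post.t1_ms),
        ("r2_pre", r2_pre.r2), ("r2_post", r2_post.r2),
    ):
        ioc.write_nifti(out_dir / f"{name}.nii", arr, stack.pixel_spacing)
    implied = float(np.sqrt((pred.as_array() ** 2).sum(axis=-1)).mean())
    summary = {
        "registration_seconds": elapsed,
        "mean_implied_displacement_px": implied,
        "stack": str(stack_path),
        "checkpoint": str(checkpoint_path),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    _write_provenance(out_dir, {"subcommand": "correct"}, seed, [stack_path, checkpoint_path])
    return summary


def run_evaluate(data_dir, checkpoint_path, out_dir, r2_threshold: float = 0.95, seed: int = 0) -> dict:
    """Score a directory of fixtures (with ground-truth inverse fields)
    against a checkpoint: per-case endpoint error and myocardial R^2 proxy
    before/after correction, plus Wilcoxon signed-rank comparisons."""
    import pandas as pd

    data_dir = Path(data_dir)
    checkpoint_path = Path(checkpoint_path)
    if not checkpoint_path.is_file():
        raise FormatError(f"checkpoint not found: {checkpoint_path}")
    model = moconet.load_checkpoint(checkpoint_path)
    rows = []
    paths = sorted(data_dir.glob("stack_*.npz"))
    if not paths:
        raise FormatError(f"no stack fixtures found in {data_dir}")
    for p in paths:
        stack = ioc.load_stack_fixture(p)
        corrected, pred = correct_stack(stack, model)
        row = {"case": p.name}
        gt = stack.meta.get("gt_inverse_dvfs")
        if gt is not None:
            gt_set = dvfmod.DVFSet.from_array(np.asarray(gt))
            zero = np.zeros_like(gt_set.as_array())
            row["epe_before_px"] = dvf_recovery_metrics(zero, gt_set)["mean_epe_px"]
            row["epe_after_px"] = dvf_recovery_metrics(pred, gt_set)["mean_epe_px"]
        labels = stack.meta.get("labels")
        if labels is not None:
            myo = np.asarray(labels) == LABELS["myocardium"]
            _, r2_pre = t1map.reconstruct_maps(stack, mask=myo)
            _, r2_post = t1map.reconstruct_maps(corrected, mask=myo)
            row["r2_proxy_before"] = t1map.motion_severity_proxy(r2_pre, myo, r2_threshold)
            row["r2_proxy_after"] = t1map.motion_severity_proxy(r2_post, myo, r2_threshold)
        rows.append(row)
    df = pd.DataFrame(rows)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_dir / "report.csv", index=False)

    summary: dict = {"n_cases": len(df)}
    for before, after, key in (
        ("epe_before_px", "epe_after_px", "epe"),
        ("r2_proxy_before", "r2_proxy_after", "r2_proxy"),
    ):
        if before in df and df[before].notna().any():
            b = df[before].to_numpy(dtype=float)
            a = df[after].to_numpy(dtype=float)
            summary[f"median_{key}_before"] = float(np.median(b))
            summary[f"median_{key}_after"] = float(np.median(a))
            try:
                res = paired_wilcoxon(b, a)
                summary[f"wilcoxon_p_{key}"] = None if res.no_test else res.p_value
            except ContractError:
                summary[f"wilcoxon_p_{key}"] = None
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    _write_provenance(out_dir, {"subcommand": "evaluate", "r2_threshold": r2_threshold},
                      seed, [checkpoint_path, *paths])
    return summary
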