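"""Training, patch-wise inference and dataset evaluation.

Training follows the patch-based protocol: enhanced single-channel images
are cut into overlapping windows, 10 % of the *source images* are held out
for validation (splitting by image, not by patch, so overlapping windows
never leak across the split), the deep-supervision loss is optimised with
Adam (beta1 0.9, beta2 0.99, initial learning rate 5e-4, decayed x0.1
every 50 epochs) and the checkpoint with the highest validation AUC is
kept.  Inference predicts every window of an edge-complete grid and
averages overlapping predictions into a full-image probability map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import _autodiff as ad
from . import losses, metrics, patchwork, preprocess
from .layers import Adam
from .network import MFAUNet, ModelConfig, build_model
from .synthfundus import SynthConfig, generate_sample


@dataclass
class TrainConfig:
    lr: float = 5e-4
    betas: tuple[float, float] = (0.9, 0.99)
    lr_decay: float = 0.1
    lr_decay_every: int = 50
    batch_size: int = 32
    epochs: int = 100
    val_fraction: float = 0.10
    selection_metric: str = "auc"
    augment: bool = True
    dice_smooth: float = 1.0
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    window: int = 128
    stride: int = 15
    max_patches: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class EpochStats:
    epoch: int
    lr: float
    train_loss: float
    val_loss: float
    val_acc: float
    val_auc: float
    val_dsc: float


@dataclass
class RunRecord:
    """Learning curves plus the best-checkpoint bookkeeping of one run."""
    epochs: list[EpochStats] = field(default_factory=list)
    best_epoch: int = -1
    best_val_auc: float = -np.inf
    seed: int = 0
    model_config: dict = field(default_factory=dict)
    train_config: dict = field(default_factory=dict)
    checkpoint_path: str | None = None

    def as_dict(self) -> dict:
        return {"epochs": [asdict(e) for e in self.epochs],
                "best_epoch": self.best_epoch,
                "best_val_auc": self.best_val_auc,
                "seed": self.seed,
                "model_config": self.model_config,
                "train_config": self.train_config,
                "checkpoint_path": self.checkpoint_path}


# ---------------------------------------------------------------------------
# data handling
# ---------------------------------------------------------------------------

def load_dataset(path) -> list[dict]:
    """Read an images/ + masks/ (+ fov/) directory tree into memory."""
    root = Path(path)
    img_dir = root / "images"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"no images/ directory under {root}")
    samples = []
    for img_path in sorted(img_dir.iterdir()):
        stem = img_path.stem
        mask_path = _find_sibling(root / "masks", stem)
        if mask_path is None:
            continue
        fov_path = _find_sibling(root / "fov", stem)
        img = iio.imread(img_path)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        samples.append({
            "id": stem,
            "image": img[..., :3],
            "mask": (np.asarray(iio.imread(mask_path)) > 127).astype(np.uint8),
            "fov": None if fov_path is None else
                   (np.asarray(iio.imread(fov_path)) > 127).astype(np.uint8),
        })
    if not samples:
        raise ValueError(f"no aligned image/mask pairs found under {root}")
    return samples


def _find_sibling(directory: Path, stem: str) -> Path | None:
    if not directory.is_dir():
        return None
    for p in directory.iterdir():
        if p.stem == stem:
            return p
    return None


def prepare_patches(samples: list[dict], pre_cfg: preprocess.PreprocessConfig,
                    window: int, stride: int, rng: np.random.Generator,
                    max_patches: int | None = None):
    """Preprocess images and cut the training patch pool.

    Returns ``(X, Y, groups)`` with X, Y of shape (n, 1, w, w) and
    ``groups`` the source-image index of every patch.
    """
    xs, ys, gs = [], [], []
    for gi, s in enumerate(samples):
        gray = preprocess.preprocess(s["image"], pre_cfg)
        grid = patchwork.plan_grid(*gray.shape, window=window, stride=stride)
        pset = patchwork.extract_patches(gray, s["mask"], grid)
        xs.append(pset.images)
        ys.append(pset.masks)
        gs.append(np.full(len(pset), gi))
    x = np.concatenate(xs)[:, None].astype(np.float32)
    y = np.concatenate(ys)[:, None].astype(np.float32)
    g = np.concatenate(gs)
    if max_patches is not None and len(x) > max_patches:
        keep = rng.choice(len(x), size=max_patches, replace=False)
        keep.sort()
        x, y, g = x[keep], y[keep], g[keep]
    return x, y, g


def split_by_image(groups: np.ndarray, val_fraction: float,
                   rng: np.random.Generator,
                   forced_val_images=None):
    """Train/val patch indices with no source image in both splits."""
    if forced_val_images is not None:
        val_images = set(int(v) for v in forced_val_images)
    else:
        image_ids = np.unique(groups)
        order = rng.permutation(image_ids)
        target = val_fraction * len(groups)
        val_images, n_val = [], 0
        for gid in order:
            if n_val >= target:
                break
            val_images.append(gid)
            n_val += int(np.sum(groups == gid))
        val_images = set(int(v) for v in val_images)
    val_idx = np.flatnonzero([g in val_images for g in groups])
    train_idx = np.flatnonzero([g not in val_images for g in groups])
    if len(val_idx) == 0 or len(train_idx) == 0:
        raise ValueError("validation split failed: too few source images")
    return train_idx, val_idx


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _forward_probs(model: MFAUNet, x: np.ndarray) -> np.ndarray:
    """Fusion-branch probabilities without building a gradient tape."""
    model.eval()
    out = model.predict_proba(x)
    model.train()
    return out


def _validate(model: MFAUNet, x: np.ndarray, y: np.ndarray,
              smooth: float, batch: int) -> dict:
    probs = np.concatenate([_forward_probs(model, x[i:i + batch])
                            for i in range(0, len(x), batch)])
    val_loss = losses.bce_loss(probs, y) + losses.dice_loss(probs, y, smooth)
    rep = metrics.evaluate_probability_map(probs, y > 0.5)
    auc = rep.auc if rep.auc is not None else 0.5
    dsc = losses.soft_dice(probs, y, smooth)
    return {"loss": float(val_loss), "acc": rep.acc, "auc": float(auc),
            "dsc": dsc, "probs": probs}


def train(model_cfg: ModelConfig, train_cfg: TrainConfig, data,
          pre_cfg: preprocess.PreprocessConfig | None = None,
          checkpoint_path=None, val_images=None) -> tuple[MFAUNet, RunRecord]:
    """Fit MFA-UNet on a dataset directory, sample list or patch triple.

    ``data`` may be a path to an images/masks tree, a list of sample
    dicts, or a prepared ``(X, Y, groups)`` triple.  Returns the trained
    model (best-AUC weights restored) and the run record.
    """
    pre_cfg = pre_cfg or preprocess.PreprocessConfig()
    rng = np.random.default_rng(train_cfg.seed)
    if isinstance(data, (str, Path)):
        data = load_dataset(data)
    if isinstance(data, list):
        x, y, groups = prepare_patches(data, pre_cfg, train_cfg.window,
                                       train_cfg.stride, rng,
                                       train_cfg.max_patches)
    else:
        x, y, groups = data
    if len(x) == 0:
        raise ValueError("empty training set")
    train_idx, val_idx = split_by_image(groups, train_cfg.val_fraction, rng,
                                        forced_val_images=val_images)
    xt, yt = x[train_idx], y[train_idx]
    xv, yv = x[val_idx], y[val_idx]

    prev_dtype = ad.DTYPE
    ad.set_default_dtype(np.float32)
    try:
        model = build_model(model_cfg)
        opt = Adam(model.parameters(), lr=train_cfg.lr, betas=train_cfg.betas)
        record = RunRecord(seed=train_cfg.seed, model_config=model_cfg.as_dict(),
                           train_config=asdict(train_cfg))
        best_state = None
        for epoch in range(train_cfg.epochs):
            lr = train_cfg.lr * train_cfg.lr_decay ** (
                epoch // train_cfg.lr_decay_every)
            opt.lr = lr
            order = rng.permutation(len(xt))
            losses_seen = []
            for start in range(0, len(order), train_cfg.batch_size):
                sel = order[start:start + train_cfg.batch_size]
                xb, yb = xt[sel], yt[sel]
                if train_cfg.augment:
                    xb, yb = _augment_batch(xb, yb, rng)
                logits = model(xb)
                probs = tuple(ad.sigmoid(o) for o in logits)
                loss = losses.deep_supervision_loss(
                    probs, yb, train_cfg.dice_smooth, train_cfg.loss_weights)
                if not np.isfinite(float(loss.data)):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}: {float(loss.data)}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses_seen.append(float(loss.data))
            val = _validate(model, xv, yv, train_cfg.dice_smooth,
                            train_cfg.batch_size)
            record.epochs.append(EpochStats(
                epoch=epoch, lr=lr, train_loss=float(np.mean(losses_seen)),
                val_loss=val["loss"], val_acc=val["acc"],
                val_auc=val["auc"], val_dsc=val["dsc"]))
            if val["auc"] > record.best_val_auc:
                record.best_val_auc = val["auc"]
                record.best_epoch = epoch
                best_state = {k: v.copy() for k, v in model.state_dict().items()}
        if best_state is not None:
            model.load_state_dict(best_state)
        model.eval()
    finally:
        ad.set_default_dtype(prev_dtype)
    for p in model.state_arrays():
        if isinstance(p, ad.Tensor):
            p.data = p.data.astype(ad.DTYPE)
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path, record)
        record.checkpoint_path = str(checkpoint_path)
    return model, record


def _augment_batch(xb, yb, rng):
    xa = np.empty_like(xb)
    ya = np.empty_like(yb)
    for i in range(len(xb)):
        params = patchwork.draw_augment_params(rng)
        im, mk = patchwork.apply_augment(xb[i, 0], yb[i, 0], params)
        xa[i, 0], ya[i, 0] = im, mk
    return xa, ya


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(model: MFAUNet, path, record: RunRecord | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"version": CHECKPOINT_VERSION, "model_config": model.cfg.as_dict()}
    if record is not None:
        meta["best_epoch"] = record.best_epoch
        meta["best_val_auc"] = float(record.best_val_auc)
    np.savez(path, __meta__=json.dumps(meta), **model.state_dict())


def load_checkpoint(path) -> MFAUNet:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    cfg = ModelConfig(**meta["model_config"])
    model = build_model(cfg)
    model.load_state_dict(arrays)
    model.eval()
    return model


# ---------------------------------------------------------------------------
# inference and evaluation
# ---------------------------------------------------------------------------

def predict_image(model: MFAUNet, img: np.ndarray,
                  pre_cfg: preprocess.PreprocessConfig | None = None,
                  window: int = 64, stride: int = 32,
                  batch_size: int = 16,
                  preprocessed: bool = False) -> np.ndarray:
    """Probability map for one image via edge-complete patch stitching.

    Images smaller than the window are reflect-padded, predicted and
    cropped back.
    """
    model.eval()
    if preprocessed:
        gray = np.asarray(img, dtype=np.float64)
    else:
        gray = preprocess.preprocess(img, pre_cfg or preprocess.PreprocessConfig())
    h0, w0 = gray.shape
    ph = max(0, window - h0)
    pw = max(0, window - w0)
    if ph or pw:
        gray = np.pad(gray, ((0, ph), (0, pw)), mode="reflect")
    grid = patchwork.plan_grid(*gray.shape, window=window, stride=stride,
                               edge_complete=True)
    pset = patchwork.extract_patches(gray, None, grid)
    probs = np.concatenate([
        model.predict_proba(pset.images[i:i + batch_size, None].astype(np.float32))
        for i in range(0, len(pset), batch_size)])[:, 0]
    full = patchwork.stitch(probs, grid)
    return full[:h0, :w0]


def evaluate_dataset(model: MFAUNet, data, threshold: float = 0.5,
                     pre_cfg: preprocess.PreprocessConfig | None = None,
                     window: int = 64, stride: int = 32,
                     use_fov: bool = False) -> dict:
    """Predict and score every image; report per-image and pooled metrics.

    The pooled row aggregates confusion counts over all images; mSen/mSp
    are the per-image means of sensitivity and specificity.
    """
    if isinstance(data, (str, Path)):
        data = load_dataset(data)
    per_image = []
    pooled = metrics.ConfusionCounts(0, 0, 0, 0)
    all_probs, all_truth = [], []
    for s in data:
        if s["mask"] is None:
            continue
        prob = predict_image(model, s["image"], pre_cfg, window, stride)
        domain = s["fov"] if use_fov else None
        rep = metrics.evaluate_probability_map(prob, s["mask"], threshold, domain)
        per_image.append({"id": s["id"], **_report_row(rep)})
        pooled = pooled + rep.counts
        sel = slice(None) if domain is None else np.asarray(domain).astype(bool)
        all_probs.append(prob[sel].ravel() if domain is not None else prob.ravel())
        all_truth.append((s["mask"][sel] if domain is not None
                          else s["mask"]).ravel())
    pooled_rep = metrics.compute_metrics(pooled, threshold,
                                         "fov" if use_fov else "full")
    probs = np.concatenate(all_probs)
    truth = np.concatenate(all_truth).astype(bool)
    if truth.any() and not truth.all():
        pooled_rep.auc = metrics.roc_auc(probs, truth)
    return {
        "per_image": per_image,
        "pooled": _report_row(pooled_rep),
        "msen": float(np.mean([r["se"] for r in per_image])),
        "msp": float(np.mean([r["sp"] for r in per_image])),
        "threshold": threshold,
    }


def _report_row(rep: metrics.MetricsReport) -> dict:
    return {"acc": rep.acc, "dsc": rep.dsc, "se": rep.se, "sp": rep.sp,
            "auc": rep.auc}


def cross_evaluate(model_or_checkpoint, dataset_path, **kwargs) -> dict:
    """Evaluate a trained model on another dataset without retraining."""
    if isinstance(model_or_checkpoint, (str, Path)):
        model = load_checkpoint(model_or_checkpoint)
    else:
        model = model_or_checkpoint
    return evaluate_dataset(model, dataset_path, **kwargs)


# ---------------------------------------------------------------------------
# the miniature study protocol
# ---------------------------------------------------------------------------

def make_miniature_patches(seed: int, n_train: int = 300, n_val: int = 60,
                           window: int = 64,
                           synth_cfg: SynthConfig | None = None):
    """Synthetic 64x64 patch pools for CPU-scale training studies.

    Draws enough synthetic fundus images to cover ``n_train + n_val``
    patches on a half-window-stride grid, designates whole source images
    as validation and trims both splits to the requested sizes.  Returns
    ``(X, Y, groups, val_image_ids)``.
    """
    base = synth_cfg or SynthConfig()
    stride = window // 2
    per_image = (1 + (base.image_size - window) // stride) ** 2
    n_images = int(np.ceil((n_train + n_val) / per_image))
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n_images):
        cfg = SynthConfig(**{**base.__dict__, "seed": seed * 1000 + i})
        img, mask, fov, _ = generate_sample(cfg)
        samples.append({"id": f"synth_{i}", "image": img, "mask": mask,
                        "fov": fov})
    pre = preprocess.PreprocessConfig()
    x, y, g = prepare_patches(samples, pre, window, stride, rng)
    # designate whole source images as validation, then trim both splits to
    # exactly the requested patch counts
    val_images = set(int(v) for v in np.unique(g)[:max(1, int(np.ceil(
        len(np.unique(g)) * n_val / (n_train + n_val))))])
    val_sel = np.flatnonzero([gi in val_images for gi in g])[:n_val]
    train_sel = np.flatnonzero([gi not in val_images for gi in g])[:n_train]
    keep = np.concatenate([train_sel, val_sel])
    return x[keep], y[keep], g[keep], sorted(val_images)


def miniature_train_config(seed: int, epochs: int = 10) -> TrainConfig:
    """Short-run protocol: small batches and a raised learning rate give
    enough optimiser steps for convergence within a few hundred updates."""
    return TrainConfig(lr=3e-3, batch_size=8, epochs=epochs,
                       val_fraction=0.167, window=64, stride=32,
                       augment=False, seed=seed)


def run_miniature_experiment(seed: int, model_cfg: ModelConfig | None = None,
                             epochs: int = 10) -> tuple[MFAUNet, RunRecord, dict]:
    """Train a slim model on the miniature synthetic study.

    Returns ``(model, record, scores)`` where ``scores`` holds the
    held-out ``soft_dice`` (on probabilities) and hard ``dsc`` (at
    threshold 0.5) of the best-AUC checkpoint.
    """
    from .network import slim_config

    cfg = model_cfg or slim_config(seed=seed)
    tcfg = miniature_train_config(seed, epochs)
    x, y, g, val_images = make_miniature_patches(seed)
    model, record = train(cfg, tcfg, (x, y, g), val_images=val_images)
    # score the held-out images with the best checkpoint
    val_idx = np.flatnonzero([gi in set(val_images) for gi in g])
    probs = np.concatenate([
        model.predict_proba(x[val_idx][i:i + 16].astype(np.float32))
        for i in range(0, len(val_idx), 16)])
    scores = {
        "soft_dice": losses.soft_dice(probs, y[val_idx]),
        "dsc": metrics.evaluate_probability_map(probs, y[val_idx] > 0.5).dsc,
    }
    return model, record, scores
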