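"""Training protocol: mixed loss, stratified cross-validation, fit loop.

The translation network is trained with the L1-L2-SSIM mixed loss

    L = a1 * L1 + a2 * L2 + a3 * (1 - SSIM),

default weights (1, 0, 1). SSIM uses the standard Gaussian window (11x11,
sigma 1.5) with stabilizers C1 = (0.01 R)^2, C2 = (0.03 R)^2 for data range
R (default 3.0, the PiB SUVr ceiling — fixed rather than per-batch for
training stability).

Subjects are stratified by diagnosis into five folds; FTD subjects are
regrouped as elderly controls for stratification (frontotemporal dementia is
not an amyloid pathology). In cross-validation step k, fold k is the test
fold, fold (k+1) mod 5 the validation fold, and the remaining three folds
train the model; the checkpoint with the best validation loss is kept and
the test fold never enters a training batch.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .nn import autodiff as ad
from .nn import Adam, Tensor
from .network import Model, ModelConfig, build_model
from .phantom import VolumeImage
from .preprocess import (DEFAULT_KEEP_RANGE, AugmentParams, SlicePair,
                         augment_pair, downsample_pair, extract_slices,
                         unpad_slice)

__all__ = ["LossWeights", "TrainConfig", "FoldSplit", "ssim", "mixed_loss",
           "make_folds", "train_fold", "predict_volume", "gaussian_window"]


@dataclass
class LossWeights:
    alpha1: float = 1.0   # L1
    alpha2: float = 0.0   # L2
    alpha3: float = 1.0   # 1 - SSIM

    def __post_init__(self):
        if self.alpha1 < 0 or self.alpha2 < 0 or self.alpha3 < 0:
            raise ValueError("loss weights must be non-negative")
        if self.alpha1 == self.alpha2 == self.alpha3 == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 8
    lr: float = 3e-3
    lr_schedule: str = "cosine"   # "cosine" decay to lr/10, or "constant"
    optimizer: str = "adam"
    seed: int = 0
    with_mr: bool = True
    keep_range: tuple = DEFAULT_KEEP_RANGE
    slice_step: int = 1          # use every k-th kept slice
    downsample: int = 1          # spatial pooling factor (1 = 128x128)
    weights: LossWeights = field(default_factory=LossWeights)
    data_range: float = 3.0
    # fixed affine target standardization y' = (y - shift) / scale; the
    # network regresses y' and predictions are mapped back at inference.
    # LayerNorm-terminated decoders learn absolute intensities slowly when
    # the head must span the raw SUVr range from unit-scale features.
    target_shift: float = 0.5
    target_scale: float = 0.5
    augment: AugmentParams | None = None

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


# ---------------------------------------------------------------------------
# SSIM and the mixed loss
# ---------------------------------------------------------------------------

def gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    r = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(r ** 2) / (2.0 * sigma ** 2))
    w = np.outer(g, g)
    return w / w.sum()


def _ssim_tensor(x: Tensor, y: Tensor, data_range: float,
                 win_size: int = 11, sigma: float = 1.5) -> Tensor:
    """Mean local SSIM of two (N, H, W, 1) tensors (differentiable)."""
    dt = x.dtype
    w = ad.const(gaussian_window(win_size, sigma).astype(dt)[:, :, None, None])
    c1 = ad.const(np.asarray((0.01 * data_range) ** 2, dtype=dt))
    c2 = ad.const(np.asarray((0.03 * data_range) ** 2, dtype=dt))
    two = ad.const(np.asarray(2.0, dtype=dt))

    mu_x = ad.conv2d(x, w)
    mu_y = ad.conv2d(y, w)
    mu_xx = ad.mul(mu_x, mu_x)
    mu_yy = ad.mul(mu_y, mu_y)
    mu_xy = ad.mul(mu_x, mu_y)
    var_x = ad.sub(ad.conv2d(ad.mul(x, x), w), mu_xx)
    var_y = ad.sub(ad.conv2d(ad.mul(y, y), w), mu_yy)
    cov = ad.sub(ad.conv2d(ad.mul(x, y), w), mu_xy)

    num = ad.mul(ad.add(ad.mul(two, mu_xy), c1), ad.add(ad.mul(two, cov), c2))
    den = ad.mul(ad.add(ad.add(mu_xx, mu_yy), c1), ad.add(ad.add(var_x, var_y), c2))
    return ad.mean_(ad.div(num, den))


def _as_nhw1(a: np.ndarray) -> np.ndarray:
    if a.ndim == 2:
        return a[None, :, :, None]
    if a.ndim == 3:
        return a[None]
    return a


def ssim(x, y, data_range: float = 3.0, win_size: int = 11,
         sigma: float = 1.5) -> float:
    """Mean structural similarity of two 2D images (Gaussian window)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    return float(_ssim_tensor(Tensor(_as_nhw1(x)), Tensor(_as_nhw1(y)),
                              data_range, win_size, sigma).data)


def mixed_loss(pred, target, weights: LossWeights = None, data_range: float = 3.0):
    """The a1*L1 + a2*L2 + a3*(1 - SSIM) mixed loss.

    Accepts Tensors (returns a scalar Tensor on the tape, for training) or
    arrays (returns a float).
    """
    weights = weights or LossWeights()
    tensor_in = isinstance(pred, Tensor)
    if not tensor_in:
        pred = Tensor(_as_nhw1(np.asarray(pred, dtype=np.float64)))
        target = Tensor(_as_nhw1(np.asarray(target, dtype=np.float64)))
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")

    dt = pred.dtype
    diff = ad.sub(pred, target)
    terms = []
    if weights.alpha1 > 0:
        terms.append(ad.mul(ad.const(np.asarray(weights.alpha1, dt)),
                            ad.mean_(ad.abs_(diff))))
    if weights.alpha2 > 0:
        terms.append(ad.mul(ad.const(np.asarray(weights.alpha2, dt)),
                            ad.mean_(ad.mul(diff, diff))))
    if weights.alpha3 > 0:
        one = ad.const(np.asarray(1.0, dt))
        terms.append(ad.mul(ad.const(np.asarray(weights.alpha3, dt)),
                            ad.sub(one, _ssim_tensor(pred, target, data_range))))
    out = terms[0]
    for t in terms[1:]:
        out = ad.add(out, t)
    return out if tensor_in else float(out.data)


# ---------------------------------------------------------------------------
# cross-validation protocol
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    folds: list                 # list of lists of subject ids
    diagnosis: dict             # id -> original diagnosis

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def test_ids(self, step: int) -> list:
        return list(self.folds[step % self.n_folds])

    def val_ids(self, step: int) -> list:
        return list(self.folds[(step + 1) % self.n_folds])

    def train_ids(self, step: int) -> list:
        skip = {step % self.n_folds, (step + 1) % self.n_folds}
        out = []
        for k, fold in enumerate(self.folds):
            if k not in skip:
                out.extend(fold)
        return out


def make_folds(subjects, seed: int = 0, n_folds: int = 5) -> FoldSplit:
    """Diagnosis-stratified fold assignment (FTD regrouped as EHC).

    Within each regrouped diagnosis, subjects are shuffled by ``seed`` and
    dealt round-robin starting at the currently least-filled fold, so fold
    sizes and per-diagnosis counts differ by at most one.
    """
    recs = [(s.id, s.diagnosis) if hasattr(s, "id") else (s[0], s[1])
            for s in subjects]
    if len(recs) < n_folds:
        raise ValueError(f"need at least {n_folds} subjects, got {len(recs)}")
    rng = np.random.default_rng(seed)
    groups: dict = {}
    for sid, dx in recs:
        groups.setdefault("EHC" if dx == "FTD" else dx, []).append(sid)

    folds = [[] for _ in range(n_folds)]
    for dx in sorted(groups, key=lambda d: (-len(groups[d]), d)):
        members = sorted(groups[dx])
        rng.shuffle(members)
        order = sorted(range(n_folds), key=lambda k: (len(folds[k]), k))
        for i, sid in enumerate(members):
            folds[order[i % n_folds]].append(sid)
    return FoldSplit(folds=folds, diagnosis=dict(recs))


# ---------------------------------------------------------------------------
# fitting and prediction
# ---------------------------------------------------------------------------

def subject_slice_pairs(subject, config: TrainConfig) -> list:
    pairs = extract_slices(subject, keep_range=config.keep_range,
                           with_mr=config.with_mr)
    pairs = pairs[::config.slice_step]
    return [downsample_pair(p, config.downsample) for p in pairs]


def _stack_batch(pairs, dtype, config: TrainConfig | None = None):
    x = np.stack([p.input for p in pairs]).astype(dtype)
    y = np.stack([p.target for p in pairs]).astype(dtype)
    if config is not None:
        y = (y - config.target_shift) / config.target_scale
    return x, y


def _loss_range(config: TrainConfig) -> float:
    return config.data_range / config.target_scale


def _eval_loss(model: Model, pairs, config: TrainConfig) -> float:
    losses = []
    for i in range(0, len(pairs), config.batch_size):
        chunk = pairs[i:i + config.batch_size]
        x, y = _stack_batch(chunk, model.config.np_dtype, config)
        pred = model.forward(x).data
        losses.append(mixed_loss(pred, y, config.weights, _loss_range(config))
                      * len(chunk))
    return float(np.sum(losses) / len(pairs))


def train_fold(subjects, split: FoldSplit, step: int, config: TrainConfig,
               model_config: ModelConfig | None = None):
    """Fit one cross-validation step; returns (model, log, info).

    ``log`` is a list of per-epoch dicts (epoch, train_loss, val_loss); the
    returned model carries the parameters of the best-validation epoch. The
    test fold of ``step`` is never touched.
    """
    if model_config is None:
        model_config = ModelConfig(in_channels=2 if config.with_mr else 1)
    if model_config.in_channels != (2 if config.with_mr else 1):
        raise ValueError("model in_channels inconsistent with with_mr")

    by_id = {s.id: s for s in subjects}
    train_ids = split.train_ids(step)
    val_ids = split.val_ids(step)
    if not train_ids:
        raise ValueError("empty training set")

    train_pairs = [p for sid in train_ids
                   for p in subject_slice_pairs(by_id[sid], config)]
    val_pairs = [p for sid in val_ids
                 for p in subject_slice_pairs(by_id[sid], config)]

    rng = np.random.default_rng(config.seed)
    model = build_model(model_config, seed=config.seed)
    opt = Adam(model.parameters(), lr=config.lr)
    dtype = model_config.np_dtype

    log = []
    best = (np.inf, None)
    seen_ids: set = set()
    for epoch in range(1, config.epochs + 1):
        if config.lr_schedule == "cosine":
            lo = config.lr / 10.0
            opt.lr = lo + 0.5 * (config.lr - lo) * (
                1.0 + np.cos(np.pi * (epoch - 1) / max(config.epochs - 1, 1)))
        order = rng.permutation(len(train_pairs))
        epoch_losses = []
        for i in range(0, len(order), config.batch_size):
            chunk = [train_pairs[j] for j in order[i:i + config.batch_size]]
            if config.augment is not None:
                chunk = [augment_pair(p, config.augment, rng) for p in chunk]
            seen_ids.update(p.subject_id for p in chunk)
            x, y = _stack_batch(chunk, dtype, config)
            pred = model.forward(x)
            loss = mixed_loss(pred, Tensor(y), config.weights, _loss_range(config))
            loss.backward()
            opt.step()
            opt.zero_grad()
            epoch_losses.append(float(loss.data))
        val_loss = _eval_loss(model, val_pairs, config) if val_pairs else np.nan
        log.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                    "val_loss": val_loss, "lr": float(opt.lr)})
        if val_pairs and val_loss < best[0]:
            best = (val_loss, copy.deepcopy(model.state_dict()))

    if best[1] is not None:
        model.load_state_dict(best[1])
    info = {"trained_subject_ids": seen_ids,
            "train_ids": set(train_ids), "val_ids": set(val_ids),
            "test_ids": set(split.test_ids(step)),
            "best_val_loss": best[0] if val_pairs else None}
    return model, log, info


def write_log(log, path) -> None:
    import pandas as pd
    pd.DataFrame(log).to_csv(path, index=False)


def predict_volume(model, subject, config: TrainConfig) -> VolumeImage:
    """Translate a subject's PiB (+MR) volume into an FBB-like volume.

    Runs the network slice-by-slice over the kept range, unpads each output
    back to the template in-plane grid, stacks into a volume (slices outside
    the kept range are zero) and applies the subject head mask. ``model`` may
    be a trained :class:`Model` (whose outputs are mapped back from the
    standardized target space and clipped at zero) or any callable mapping
    (N, H, W, C) arrays to (N, H, W, 1) in volume units.
    """
    from scipy.ndimage import zoom

    pairs = extract_slices(subject, keep_range=config.keep_range,
                           with_mr=config.with_mr)
    ds_pairs = [downsample_pair(p, config.downsample) for p in pairs]

    if isinstance(model, Model):
        fwd = lambda a: np.clip(  # noqa: E731
            np.asarray(model.predict(a)) * config.target_scale
            + config.target_shift, 0.0, None)
        dtype = model.config.np_dtype
    else:
        fwd = model
        dtype = np.float64

    out = np.zeros(subject.pib.data.shape, dtype=np.float64)
    bs = 16
    for i in range(0, len(ds_pairs), bs):
        chunk = ds_pairs[i:i + bs]
        x = np.stack([p.input for p in chunk]).astype(dtype)
        pred = np.asarray(fwd(x))
        for p, sl in zip(chunk, pred):
            img = sl[:, :, 0].astype(np.float64)
            if config.downsample > 1:
                img = zoom(img, config.downsample, order=1)
            out[:, :, p.slice_index] = unpad_slice(img, p.pad_offsets)
    out *= subject.mask.data > 0
    return VolumeImage(out, subject.pib.voxel_mm, "FBB-SUVr-pred")
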