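"""Patch-based 2D U-net placenta segmentation of T2* maps.

Training protocol: 64x64 in-plane patches, z-score normalization by the mean
and SD of the training data set (the statistics are stored with the model),
binary cross-entropy loss, Adam with learning rate 1e-4 and batch size 5, and
augmentation by spatial cropping (random patch placement), mirroring and
small in-plane rotations. Half of the sampled patches are forced to contain
foreground to counter class imbalance.

Inference tiles each slice with patches overlapping by 30% (edge patches are
shifted inward to stay in bounds), averages the predicted probabilities over
overlapping patches, and binarizes at 0.5 (ties count as foreground).

The network itself (:mod:`placentaging._unet`) is a compact CPU U-net whose
depth and width are configurable; the defaults are sized for CPU training on
phantom data rather than for a full clinical cohort.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

from placentaging._unet import UNet, Adam, bce_with_logits

__all__ = ["SegTrainConfig", "UNetSegmenter", "make_folds", "patch_origins"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegTrainConfig:
    """Training hyperparameters for :class:`UNetSegmenter`.

    ``n_iterations`` counts optimizer steps (batches). The reference protocol
    uses 50,000 steps on GPU hardware; the default here (2,000) is a
    CPU-friendly setting adequate for phantom data.
    """

    patch_size: int = 64
    batch_size: int = 5
    learning_rate: float = 1e-4
    n_iterations: int = 2000
    loss: str = "binary_cross_entropy"
    augment_crop: bool = True
    augment_mirror: bool = True
    augment_rotate: bool = True
    rotate_max_deg: float = 15.0
    fg_patch_fraction: float = 0.5
    seed: int = 0
    folds: int = 5
    depth: int = 3
    base_filters: int = 16

    def validate(self) -> None:
        if self.patch_size % 2 ** (self.depth - 1) != 0:
            raise ValueError("patch_size must be divisible by 2**(depth-1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.loss != "binary_cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")


def make_folds(cohort, k: int, seed: int = 0) -> dict[str, int]:
    """Subject-exclusive stratified fold assignment.

    Stratifies on the risk group so each fold's group proportions match the
    cohort's to within one subject; every subject lands in exactly one fold
    (no train/test leakage at the subject level). Deterministic per seed.
    """
    subjects = np.asarray(cohort["subject_id"])
    groups = np.asarray(cohort["group"])
    if k > subjects.size:
        raise ValueError(f"cannot make {k} folds from {subjects.size} subjects")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(subjects, groups)):
        for i in test_idx:
            assignment[str(subjects[i])] = fold
    return assignment


def patch_origins(dim: int, patch: int, overlap: float = 0.30) -> list[int]:
    """Origins of overlapping patches along one axis.

    Stride is ``round(patch * (1 - overlap))``; patches that would extend past
    the end are shifted inward so every position is covered by at least one
    patch. For ``dim < patch`` a single origin 0 is returned (caller pads).
    """
    if dim <= patch:
        return [0]
    stride = max(1, round(patch * (1.0 - overlap)))
    origins = []
    pos = 0
    while True:
        origins.append(min(pos, dim - patch))
        if pos >= dim - patch:
            break
        pos += stride
    return sorted(set(origins))


def _augment_patch(img, msk, cfg: SegTrainConfig, rng: np.random.Generator):
    if cfg.augment_mirror:
        if rng.random() < 0.5:
            img, msk = img[::-1], msk[::-1]
        if rng.random() < 0.5:
            img, msk = img[:, ::-1], msk[:, ::-1]
    if cfg.augment_rotate:
        angle = rng.uniform(-cfg.rotate_max_deg, cfg.rotate_max_deg)
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="reflect")
        msk = ndimage.rotate(
            msk.astype(np.float32), angle, reshape=False, order=0, mode="reflect"
        )
    return np.ascontiguousarray(img), np.ascontiguousarray(msk >= 0.5)


class UNetSegmenter(BaseEstimator):
    """Scikit-learn style patch-based U-net segmenter for 3D T2* maps.

    Parameters mirror :class:`SegTrainConfig`; ``overlap`` controls the tiled
    inference. Fitted attributes:

    ``net_`` : the trained network,
    ``train_mean_``, ``train_scale_`` : mean and SD of all finite voxels of
    the training maps; inputs are normalised to ``(x - mean) / SD`` at train
    and test time,
    ``loss_trace_`` : per-iteration training BCE.
    """

    def __init__(
        self,
        patch_size: int = 64,
        batch_size: int = 5,
        learning_rate: float = 1e-4,
        n_iterations: int = 2000,
        augment_crop: bool = True,
        augment_mirror: bool = True,
        augment_rotate: bool = True,
        rotate_max_deg: float = 15.0,
        fg_patch_fraction: float = 0.5,
        depth: int = 3,
        base_filters: int = 16,
        overlap: float = 0.30,
        seed: int = 0,
    ):
        self.patch_size = patch_size
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.n_iterations = n_iterations
        self.augment_crop = augment_crop
        self.augment_mirror = augment_mirror
        self.augment_rotate = augment_rotate
        self.rotate_max_deg = rotate_max_deg
        self.fg_patch_fraction = fg_patch_fraction
        self.depth = depth
        self.base_filters = base_filters
        self.overlap = overlap
        self.seed = seed

    def _config(self) -> SegTrainConfig:
        return SegTrainConfig(
            patch_size=self.patch_size,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            n_iterations=self.n_iterations,
            augment_crop=self.augment_crop,
            augment_mirror=self.augment_mirror,
            augment_rotate=self.augment_rotate,
            rotate_max_deg=self.rotate_max_deg,
            fg_patch_fraction=self.fg_patch_fraction,
            seed=self.seed,
            depth=self.depth,
            base_filters=self.base_filters,
        )

    # -- training ------------------------------------------------------------

    def _sample_patch(self, maps, masks, cfg, rng):
        p = cfg.patch_size
        while True:
            s = rng.integers(len(maps))
            vol, msk = maps[s], masks[s]
            z = rng.integers(vol.shape[2])
            sl, ml = vol[:, :, z], msk[:, :, z]
            h, w = sl.shape
            want_fg = rng.random() < cfg.fg_patch_fraction
            if want_fg and ml.any():
                fg = np.argwhere(ml)
                cx, cy = fg[rng.integers(fg.shape[0])]
                ox = int(np.clip(cx - p // 2 + rng.integers(-p // 4, p // 4 + 1), 0, max(h - p, 0)))
                oy = int(np.clip(cy - p // 2 + rng.integers(-p // 4, p // 4 + 1), 0, max(w - p, 0)))
            elif cfg.augment_crop:
                ox = rng.integers(max(h - p, 0) + 1)
                oy = rng.integers(max(w - p, 0) + 1)
            else:
                ox = oy = 0
            img = sl[ox : ox + p, oy : oy + p]
            m = ml[ox : ox + p, oy : oy + p]
            if img.shape != (p, p):
                img = _pad_to(img, p)
                m = _pad_to(m, p)
            return _augment_patch(img.astype(np.float32), m, cfg, rng)

    def fit(self, maps, masks):
        """Train on lists of 3D T2* maps and matching binary masks."""
        cfg = self._config()
        cfg.validate()
        maps = [np.asarray(m, dtype=np.float32) for m in maps]
        masks = [np.asarray(m, dtype=bool) for m in masks]
        if len(maps) == 0 or len(maps) != len(masks):
            raise ValueError("need equal, non-zero numbers of maps and masks")
        for a, b in zip(maps, masks):
            if a.shape != b.shape:
                raise ValueError("map/mask grid mismatch")
        if not any(m.any() for m in masks):
            raise ValueError("all training masks are empty")

        finite_vals = np.concatenate([m[np.isfinite(m)].ravel() for m in maps])
        self.train_mean_ = float(finite_vals.mean())
        self.train_scale_ = float(finite_vals.std()) or 1.0
        self.net_ = UNet(depth=cfg.depth, base=cfg.base_filters, seed=cfg.seed)
        opt = Adam(self.net_.params, lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed)

        demeaned = [(m - self.train_mean_) / self.train_scale_ for m in maps]
        trace = []
        for _ in range(cfg.n_iterations):
            X = np.empty((cfg.batch_size, 1, cfg.patch_size, cfg.patch_size), np.float32)
            Y = np.empty_like(X)
            for b in range(cfg.batch_size):
                img, m = self._sample_patch(demeaned, masks, cfg, rng)
                X[b, 0], Y[b, 0] = img, m
            logits, tape = self.net_.forward(X)
            loss, dl = bce_with_logits(logits, Y)
            grads = self.net_.backward(tape, dl)
            opt.step(self.net_.params, grads)
            trace.append(loss)
        self.loss_trace_ = np.asarray(trace)
        return self

    # -- inference -----------------------------------------------------------

    def predict_proba(self, t2s_map: np.ndarray) -> np.ndarray:
        """Per-voxel foreground probability via overlap-averaged tiling."""
        self._check_fitted()
        vol = (np.asarray(t2s_map, dtype=np.float32) - self.train_mean_) / self.train_scale_
        p = self.patch_size
        h, w, nz = vol.shape
        ph, pw = max(h, p), max(w, p)
        if (ph, pw) != (h, w):
            log.warning(
                "slice (%d, %d) smaller than patch %d: zero-padding for inference", h, w, p
            )
        prob = np.zeros((h, w, nz), dtype=np.float32)
        ox_list = patch_origins(ph, p, self.overlap)
        oy_list = patch_origins(pw, p, self.overlap)
        for z in range(nz):
            sl = np.zeros((ph, pw), np.float32)
            sl[:h, :w] = np.nan_to_num(vol[:, :, z])
            acc = np.zeros((ph, pw), np.float32)
            cnt = np.zeros((ph, pw), np.float32)
            patches = [(ox, oy) for ox in ox_list for oy in oy_list]
            X = np.stack([sl[ox : ox + p, oy : oy + p] for ox, oy in patches])[:, None]
            logits, _ = self.net_.forward(X)
            probs = expit(logits[:, 0])
            for k, (ox, oy) in enumerate(patches):
                acc[ox : ox + p, oy : oy + p] += probs[k]
                cnt[ox : ox + p, oy : oy + p] += 1.0
            prob[:, :, z] = (acc / cnt)[:h, :w]
        return prob

    def predict(self, t2s_map: np.ndarray) -> np.ndarray:
        """Binary placenta mask; probability >= 0.5 is foreground (ties in)."""
        return self.predict_proba(t2s_map) >= 0.5

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("UNetSegmenter is not fitted")

    # -- persistence ---------------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self._check_fitted()
        np.savez(d / "weights.npz", **self.net_.state_dict())
        meta = {
            "params": self.get_params(),
            "train_mean": self.train_mean_,
            "train_scale": self.train_scale_,
        }
        (d / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "UNetSegmenter":
        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        est = cls(**meta["params"])
        est.train_mean_ = float(meta["train_mean"])
        est.train_scale_ = float(meta.get("train_scale", 1.0))
        est.net_ = UNet(depth=est.depth, base=est.base_filters, seed=est.seed)
        with np.load(d / "weights.npz") as state:
            est.net_.load_state_dict(dict(state))
        est.loss_trace_ = np.asarray([])
        return est


def _pad_to(a: np.ndarray, p: int) -> np.ndarray:
    out = np.zeros((p, p), dtype=a.dtype)
    out[: a.shape[0], : a.shape[1]] = a
    return out
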