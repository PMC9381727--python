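"""Per-plane fluid segmentation from sparse labels and majority-vote fusion.

For each of the three orthogonal planes, a segmenter is learned from the
sparsely labeled frames (one model per plane per eye) and then applied to
every frame of that plane. The input to the model is a 3-channel stack of
the frame before, the frame of interest and the frame after (edge frames
replicate their only neighbor); prediction probabilities are binarized at
0.5. Labeled frames are re-predicted like any other frame, so the output
mask is a pure function of the trained model.

The three plane masks are fused by voxelwise majority: a voxel is fluid iff
at least two of the three planes mark it.

Two segmenters share the contract:

* :func:`train_plane_segmenter` — a residual encoder-decoder CNN trained on
  the labeled frames (filter depth 32 and learning rate 2e-4 by default);
* :func:`threshold_segment_fallback` — a deterministic intensity-threshold
  baseline (fluid is hyporeflective) that needs no training, used for fast
  exact-reproducibility runs and as a cross-check on easy phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from ._nn import Adam, ResUNet2D, bce_with_logits, sigmoid
from .types import FusedMask, OCTVolume, PlaneMask, SparseLabelSet, check_plane

__all__ = [
    "TrainingConfig",
    "PlaneSegmenter",
    "extract_frame_stacks",
    "train_plane_segmenter",
    "predict_plane",
    "threshold_segment_fallback",
    "fuse_majority",
    "dice",
]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    s = int(a.sum()) + int(b.sum())
    if s == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / s


@dataclass
class TrainingConfig:
    """Hyperparameters of the per-plane CNN.

    Defaults follow the reduced-complexity regime: constant convolutional
    filter depth 32 and learning rate 2e-4 for slow, smooth convergence.
    """

    filter_depth: int = 32
    learning_rate: float = 2e-4
    epochs: int = 120
    batch_size: int = 4
    loss: str = "bce"
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.filter_depth < 1:
            raise ValueError("filter depth must be >= 1")
        if not 0.0 <= self.validation_fraction <= 0.5:
            raise ValueError("validation fraction must lie in [0, 0.5]")
        if self.loss != "bce":
            raise ValueError(f"unsupported loss {self.loss!r}")


def _normalize(volume: OCTVolume) -> np.ndarray:
    data = volume.intensities.astype(np.float32)
    lo, hi = float(data.min()), float(data.max())
    return (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)


def _frames(data: np.ndarray, axis: int) -> np.ndarray:
    """Move the plane axis first: (n_frames, H, W)."""
    return np.moveaxis(data, axis, 0)


def extract_frame_stacks(
    volume: OCTVolume, plane: str, indices: Optional[Sequence[int]] = None
) -> np.ndarray:
    """3-channel (previous, current, next) stacks for the given frames.

    Returns an (N, 3, H, W) array; at the plane boundaries the missing
    neighbor is the edge frame itself (nearest-frame replication).
    """
    axis = check_plane(plane)
    frames = _frames(_normalize(volume), axis)
    n = frames.shape[0]
    if n < 1:
        raise ValueError("volume has no frames in this plane")
    if indices is None:
        indices = range(n)
    stacks = np.empty((len(list(indices)), 3, *frames.shape[1:]), dtype=np.float32)
    for row, k in enumerate(indices):
        if not 0 <= k < n:
            raise ValueError(f"frame index {k} outside [0, {n})")
        stacks[row, 0] = frames[max(k - 1, 0)]
        stacks[row, 1] = frames[k]
        stacks[row, 2] = frames[min(k + 1, n - 1)]
    return stacks


@dataclass
class PlaneSegmenter:
    """A trained per-plane CNN with its training record."""

    plane: str
    net: ResUNet2D
    config: TrainingConfig
    train_loss: float = float("nan")
    val_loss: Optional[float] = None
    history: List[Dict[str, float]] = field(default_factory=list)

    def predict_proba(self, stacks: np.ndarray, batch: int = 8) -> np.ndarray:
        out = np.empty((stacks.shape[0], *stacks.shape[2:]), dtype=np.float32)
        for i in range(0, stacks.shape[0], batch):
            logits = self.net.forward(stacks[i : i + batch])
            out[i : i + batch] = sigmoid(logits[:, 0])
        return out

    def save(self, path) -> None:
        state = self.net.state_dict()
        np.savez(
            path,
            plane=self.plane,
            filters=self.net.filters,
            train_loss=self.train_loss,
            **state,
        )

    @classmethod
    def load(cls, path) -> "PlaneSegmenter":
        data = np.load(path, allow_pickle=False)
        net = ResUNet2D(filters=int(data["filters"]))
        net.load_state({k: data[k] for k in data.files if k.startswith("p")})
        cfg = TrainingConfig(filter_depth=int(data["filters"]))
        return cls(
            plane=str(data["plane"]),
            net=net,
            config=cfg,
            train_loss=float(data["train_loss"]),
        )


def train_plane_segmenter(
    volume: OCTVolume, labels: SparseLabelSet, cfg: Optional[TrainingConfig] = None
) -> PlaneSegmenter:
    """Train the residual encoder-decoder on the labeled frames of one plane.

    Every fifth labeled frame is held out for validation when at least five
    labels exist; the parameters returned are the best-so-far checkpoint
    under the monitored (validation, else training) loss, so lengthening
    training can never worsen the returned model. Fully reproducible given
    ``cfg.seed``.
    """
    if cfg is None:
        cfg = TrainingConfig()
    labels.validate_against(volume)
    idx = sorted(labels.labeled_frames)
    if len(idx) < 2:
        raise ValueError(f"need at least 2 labeled frames, got {len(idx)}")

    stacks = extract_frame_stacks(volume, labels.plane, idx)
    targets = np.stack([labels.labeled_frames[k] for k in idx]).astype(np.float32)
    targets = targets[:, None]  # (N, 1, H, W)

    if len(idx) >= 5 and cfg.validation_fraction > 0:
        val_sel = np.zeros(len(idx), dtype=bool)
        val_sel[::5] = True
    else:
        val_sel = np.zeros(len(idx), dtype=bool)
    x_tr, y_tr = stacks[~val_sel], targets[~val_sel]
    x_va, y_va = stacks[val_sel], targets[val_sel]

    rng = np.random.default_rng(cfg.seed)
    net = ResUNet2D(in_channels=3, filters=cfg.filter_depth, seed=cfg.seed)
    opt = Adam(net.params(), lr=cfg.learning_rate)

    best_loss = np.inf
    best_state = {k: v.copy() for k, v in net.state_dict().items()}
    history: List[Dict[str, float]] = []
    best_train = np.inf
    best_val: Optional[float] = None

    n_tr = x_tr.shape[0]
    batch = max(1, min(cfg.batch_size, n_tr))
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_tr)
        ep_loss = 0.0
        for i in range(0, n_tr, batch):
            sel = order[i : i + batch]
            logits = net.forward(x_tr[sel])
            loss, dlogits = bce_with_logits(logits, y_tr[sel])
            net.backward(dlogits)
            opt.step()
            ep_loss += loss * len(sel)
        train_loss = ep_loss / n_tr
        record = {"epoch": float(epoch), "train_loss": train_loss}
        if x_va.shape[0]:
            va_logits = net.forward(x_va)
            val_loss, _ = bce_with_logits(va_logits, y_va)
            record["val_loss"] = val_loss
            monitored = val_loss
        else:
            val_loss = None
            monitored = train_loss
        history.append(record)
        if monitored < best_loss:
            best_loss = monitored
            best_state = {k: v.copy() for k, v in net.state_dict().items()}
            best_train = train_loss
            best_val = val_loss

    net.load_state(best_state)
    return PlaneSegmenter(
        plane=labels.plane,
        net=net,
        config=cfg,
        train_loss=best_train,
        val_loss=best_val,
        history=history,
    )


def predict_plane(
    segmenter: PlaneSegmenter, volume: OCTVolume, plane: str, threshold: float = 0.5
) -> PlaneMask:
    """Annotate every frame of one plane with the trained segmenter."""
    axis = check_plane(plane)
    if plane != segmenter.plane:
        raise ValueError(
            f"segmenter was trained for plane {segmenter.plane!r}, not {plane!r}"
        )
    stacks = extract_frame_stacks(volume, plane)
    proba = segmenter.predict_proba(stacks)
    mask_frames = proba >= threshold
    mask = np.moveaxis(mask_frames, 0, axis)
    return PlaneMask(plane=plane, mask=mask, provenance="trained")


# --------------------------------------------------------------------------
# deterministic threshold fallback


def _labels_depth_band(
    volume: OCTVolume, labels: SparseLabelSet, margin: int
) -> Optional[Tuple[int, int]]:
    """Depth (axis-2) index range touched by any label, padded by *margin*."""
    axis = check_plane(labels.plane)
    zs: List[int] = []
    for idx, mask in labels.labeled_frames.items():
        if not mask.any():
            continue
        if axis == 2:  # coronal: frame index IS the depth index
            zs.extend([idx])
        else:  # axial / sagittal frames are (en-face, depth) images
            z_cols = np.nonzero(mask.any(axis=0))[0]
            zs.extend([int(z_cols.min()), int(z_cols.max())])
    if not zs:
        return None
    nz = volume.shape[2]
    return max(0, min(zs) - margin), min(nz - 1, max(zs) + margin)


def threshold_segment_fallback(
    volume: OCTVolume,
    labels: SparseLabelSet,
    n_thresholds: int = 256,
    band_margin: int = 8,
) -> PlaneMask:
    """Deterministic intensity-threshold segmentation tuned on the labels.

    Scans ``n_thresholds`` quantiles of the labeled frames' intensities for
    the cut maximizing Dice against the labels (fluid is hyporeflective, so
    the candidate mask is intensity < threshold), then applies the winning
    threshold to every frame. Per frame, connected regions that do not
    overlap the depth band spanned by the labels (padded by ``band_margin``
    voxels) are discarded, suppressing dark detections far from the
    posterior vitreous. Same inputs always give the same mask.
    """
    axis = check_plane(labels.plane)
    labels.validate_against(volume)
    if not labels.labeled_frames:
        raise ValueError("fallback segmentation needs at least one labeled frame")
    data = _normalize(volume)
    frames = _frames(data, axis)
    idx = sorted(labels.labeled_frames)
    lab_stack = np.stack([labels.labeled_frames[k] for k in idx])
    img_stack = np.stack([frames[k] for k in idx])

    if not lab_stack.any():
        mask = np.zeros(volume.shape, dtype=bool)
        return PlaneMask(plane=labels.plane, mask=mask, provenance="fallback")

    qs = np.linspace(0.0, 1.0, n_thresholds)
    cands = np.unique(np.quantile(img_stack, qs))
    lab_sum = int(lab_stack.sum())
    best_t, best_d = cands[0], -1.0
    for t in cands:
        pred = img_stack < t
        inter = int((pred & lab_stack).sum())
        d = 2.0 * inter / (int(pred.sum()) + lab_sum) if (pred.any() or lab_sum) else 1.0
        if d > best_d:
            best_d, best_t = d, t

    full = data < best_t
    band = _labels_depth_band(volume, labels, band_margin)
    if band is not None:
        full = _filter_band(full, axis, band)
    return PlaneMask(plane=labels.plane, mask=full, provenance="fallback")


def _filter_band(mask: np.ndarray, axis: int, band: Tuple[int, int]) -> np.ndarray:
    """Keep, per frame, only 2D components overlapping the depth band."""
    lo, hi = band
    out = np.zeros_like(mask)
    frames = _frames(mask, axis)
    out_frames = _frames(out, axis)
    if axis == 2:
        # en-face frames: the whole frame is in or out of the band
        out_frames[lo : hi + 1] = frames[lo : hi + 1]
        return out
    for k in range(frames.shape[0]):
        fr = frames[k]
        if not fr.any():
            continue
        lab, n = ndimage.label(fr)
        in_band = np.unique(lab[:, lo : hi + 1])
        keep = np.zeros(n + 1, dtype=bool)
        keep[in_band[in_band > 0]] = True
        out_frames[k] = keep[lab]
    return out


# --------------------------------------------------------------------------
# fusion


def fuse_majority(
    axial: PlaneMask, sagittal: PlaneMask, coronal: PlaneMask
) -> FusedMask:
    """Voxelwise 2-of-3 majority vote over the three plane masks."""
    masks = {"axial": axial, "sagittal": sagittal, "coronal": coronal}
    shapes = {m.mask.shape for m in masks.values()}
    if len(shapes) != 1:
        raise ValueError(
            "plane masks must share one grid shape, got "
            + ", ".join(f"{k}: {v.mask.shape}" for k, v in masks.items())
        )
    votes = sum(m.mask.astype(np.uint8) for m in masks.values())
    return FusedMask(mask=votes >= 2, votes=votes)
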