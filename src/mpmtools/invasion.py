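"""Cancer invasion depth from Z-stacks.

A binary classifier scores each Z-plane for the presence of in-focus
(invaded) cells; a plane with probability >= 0.5 (inclusive, by
convention) is called *invaded*.  Invasion depth is the distance from
the top plane (index 0, where cancer cells are seeded) to the deepest
invaded plane:

    depth_um = deepest_invaded_index * z_step_um

and 0 when no plane is invaded.  The reference classifier of the method
this package automates is a 50-layer residual network; here the
architecture is configurable and defaults to a small residual CNN whose
adequacy is judged behaviourally on ground-truthed fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from mpmtools.errors import EmptyInputError, LabelError
from mpmtools.imaging_io import ZStack
from mpmtools.nn import Adam, ResidualCNN, bce_with_logits, sigmoid


@dataclass
class InvasionTrainConfig:
    """Desk-scale training configuration for the invasion classifier."""

    input_size: int = 32
    stage_channels: tuple[int, ...] = (8, 16)
    blocks_per_stage: int = 1
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 3e-3
    val_fraction: float = 0.2
    augment: bool = True   # random 90-degree rotations + flips


@dataclass
class InvasionClassifier:
    """A trained per-plane invasion classifier with its preprocessing stats."""

    model: ResidualCNN
    input_size: int
    norm_mean: float
    norm_std: float
    val_accuracy: float | None = None
    config: InvasionTrainConfig | None = None

    def preprocess(self, planes: list[np.ndarray]) -> np.ndarray:
        s = self.input_size
        out = np.empty((len(planes), 1, s, s), dtype=np.float32)
        for i, p in enumerate(planes):
            img = np.asarray(p, dtype=np.float64)
            if img.shape != (s, s):
                img = resize(img, (s, s), anti_aliasing=True, preserve_range=True)
            out[i, 0] = (img - self.norm_mean) / self.norm_std
        return out

    def predict_proba(self, planes: list[np.ndarray]) -> np.ndarray:
        """Invasion probability in [0, 1] for each plane."""
        return sigmoid(self.model.forward(self.preprocess(planes)))


@dataclass
class InvasionCall:
    """Per-plane probabilities and thresholded calls, top plane first."""

    probabilities: np.ndarray
    threshold: float = 0.5

    @property
    def classifications(self) -> np.ndarray:
        return (self.probabilities >= self.threshold).astype(np.int8)


@dataclass
class InvasionDepthResult:
    deepest_invaded_index: int | None
    depth_um: float


@dataclass
class ConfusionCounts:
    """Binary confusion counts; the positive class is *invaded*."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class ClassificationMetrics:
    """Accuracy/sensitivity/specificity; an undefined ratio is None, never 0."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    undefined: tuple[str, ...] = field(default_factory=tuple)


_DIHEDRAL = [(k, f) for k in range(4) for f in (False, True)]


def _apply_dihedral(x: np.ndarray, k: int, flip: bool) -> np.ndarray:
    out = np.rot90(x, k, axes=(-2, -1))
    if flip:
        out = out[..., ::-1]
    return np.ascontiguousarray(out)


def train_invasion_classifier(
    labeled_planes: list[tuple[np.ndarray, int]],
    config: InvasionTrainConfig | None = None,
    seed: int = 0,
) -> InvasionClassifier:
    """Train the per-plane invasion classifier on (image, label) pairs.

    Labels are 1 = invaded, 0 = not invaded; both classes must be
    present.  A stratified fraction of the data is held out and the
    held-out accuracy stored on the returned classifier.  Training
    augments each sampled batch with random flips and 90-degree
    rotations (the dihedral group), seeded for reproducibility.
    """
    config = config or InvasionTrainConfig()
    labels = np.array([int(lab) for _, lab in labeled_planes])
    if len(set(labels.tolist())) < 2:
        raise LabelError("training data must contain both invaded and not-invaded planes")

    s = config.input_size
    imgs = np.empty((len(labeled_planes), 1, s, s), dtype=np.float32)
    for i, (img, _) in enumerate(labeled_planes):
        arr = np.asarray(img, dtype=np.float64)
        if arr.shape != (s, s):
            arr = resize(arr, (s, s), anti_aliasing=True, preserve_range=True)
        imgs[i, 0] = arr

    rng = np.random.default_rng(seed)
    # stratified split
    val_idx: list[int] = []
    for cls in (0, 1):
        members = np.flatnonzero(labels == cls)
        n_val = max(1, int(round(config.val_fraction * members.size)))
        val_idx.extend(rng.permutation(members)[:n_val].tolist())
    val_mask = np.zeros(len(labels), dtype=bool)
    val_mask[val_idx] = True

    mean = float(imgs[~val_mask].mean())
    std = float(imgs[~val_mask].std()) or 1.0
    imgs = (imgs - mean) / std
    x_tr, y_tr = imgs[~val_mask], labels[~val_mask].astype(np.float32)
    x_va, y_va = imgs[val_mask], labels[val_mask].astype(np.float32)

    model = ResidualCNN(
        input_size=s,
        stage_channels=config.stage_channels,
        blocks_per_stage=config.blocks_per_stage,
        seed=seed,
    )
    opt = Adam(model.params(), lr=config.learning_rate)
    steps = max(1, x_tr.shape[0] // config.batch_size)
    for _ in range(config.epochs):
        for _ in range(steps):
            idx = rng.integers(0, x_tr.shape[0], size=config.batch_size)
            xb = x_tr[idx]
            if config.augment:
                k, f = _DIHEDRAL[rng.integers(0, len(_DIHEDRAL))]
                xb = _apply_dihedral(xb, k, f)
            logits = model.forward(xb)
            _, dlogits = bce_with_logits(logits, y_tr[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()

    val_probs = sigmoid(model.forward(x_va))
    val_acc = float(np.mean((val_probs >= 0.5) == (y_va >= 0.5)))
    return InvasionClassifier(
        model=model, input_size=s, norm_mean=mean, norm_std=std,
        val_accuracy=val_acc, config=config,
    )


def classify_stack(classifier: InvasionClassifier, stack: ZStack, threshold: float = 0.5) -> InvasionCall:
    """Score every plane of a Z-stack, top plane first."""
    if len(stack) == 0:
        raise EmptyInputError("cannot classify an empty stack")
    probs = classifier.predict_proba(stack.planes)
    return InvasionCall(probabilities=probs, threshold=threshold)


def compute_invasion_depth(call: InvasionCall, z_step_um: float) -> InvasionDepthResult:
    """Depth of the deepest invaded plane below the top plane, in um."""
    yhat = call.classifications
    if yhat.size == 0:
        raise EmptyInputError("empty invasion call")
    invaded = np.flatnonzero(yhat)
    if invaded.size == 0:
        return InvasionDepthResult(deepest_invaded_index=None, depth_um=0.0)
    deepest = int(invaded[-1])
    return InvasionDepthResult(deepest_invaded_index=deepest, depth_um=deepest * z_step_um)


def classification_metrics(counts: ConfusionCounts) -> ClassificationMetrics:
    """Accuracy, sensitivity and specificity from confusion counts.

    Ratios with an empty denominator (no positives for sensitivity, no
    negatives for specificity) are reported as None and listed in
    ``undefined`` rather than silently coerced to 0.
    """
    if counts.total <= 0:
        raise EmptyInputError("confusion counts are all zero")
    accuracy = (counts.tp + counts.tn) / counts.total
    undefined: list[str] = []
    if counts.tp + counts.fn > 0:
        sensitivity = counts.tp / (counts.tp + counts.fn)
    else:
        sensitivity = None
        undefined.append("sensitivity")
    if counts.tn + counts.fp > 0:
        specificity = counts.tn / (counts.tn + counts.fp)
    else:
        specificity = None
        undefined.append("specificity")
    return ClassificationMetrics(
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        undefined=tuple(undefined),
    )
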