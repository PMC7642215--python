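"""Multiple-instance learning of tumour/normal patch classifiers.

Each domain (HE, Ki-67) gets one binary classifier trained from weak
bag-level labels only. Training alternates two steps per iteration:

* evaluation — the current classifier scores every small patch in every bag
  with its tumour-class probability; the top-scoring instance of each bag is
  selected and inherits the bag's weak label (so NORMAL bags contribute their
  hardest negatives);
* training — the selected, now-labelled instances are used for a few epochs
  of Adam / cross-entropy updates.

Bag-level validation accuracy (bag called TUMOR iff its max instance tumour
probability >= 0.5) picks the best iteration's weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field

from . import nn
from .config import NORMAL_LABEL, TUMOR_LABEL, logger
from .preprocess import Bag, SmallPatch, otsu_foreground, tile_small_patches

SMALL_CNN = "SMALL_CNN"
RESNET34 = "RESNET34"

#: class indices: NORMAL = 0, TUMOR = 1
CLASSES = (NORMAL_LABEL, TUMOR_LABEL)


class MILConfig(BaseModel):
    iterations: int = Field(default=10, ge=0)
    learning_rate: float = Field(default=1e-4, gt=0)
    epochs_per_iteration: int = Field(default=10, ge=1)
    batch_size: int = Field(default=16, ge=1)
    backbone: str = SMALL_CNN
    input_size: int = Field(default=32, ge=8)
    seed: int = 0
    restart_each_iteration: bool = False


def _build_small_cnn(input_size: int, rng: np.random.Generator) -> nn.Sequential:
    # 3 conv blocks + global average pool + linear head
    return nn.Sequential(
        nn.Conv2d(3, 16, k=3, s=2, p=1, rng=rng, init="he"), nn.ReLU(),
        nn.Conv2d(16, 32, k=3, s=2, p=1, rng=rng, init="he"), nn.ReLU(),
        nn.Conv2d(32, 64, k=3, s=2, p=1, rng=rng, init="he"), nn.ReLU(),
        nn.GlobalAvgPool2d(),
        nn.Linear(64, 2, rng=rng, init="he"),
    )


@dataclass
class PatchClassifier:
    """Binary tumour/normal classifier over small patches."""

    backbone: str
    input_size: int
    net: nn.Sequential
    seed: int = 0

    @classmethod
    def create(cls, backbone: str = SMALL_CNN, input_size: int = 32,
               seed: int = 0) -> "PatchClassifier":
        if backbone == RESNET34:
            raise NotImplementedError(
                "RESNET34 requires a GPU deep-learning framework not available "
                "in this environment; use SMALL_CNN")
        if backbone != SMALL_CNN:
            raise ValueError(f"unknown backbone {backbone!r}")
        rng = np.random.default_rng(seed)
        return cls(backbone=backbone, input_size=input_size,
                   net=_build_small_cnn(input_size, rng), seed=seed)

    def _normalize(self, batch: np.ndarray) -> np.ndarray:
        """uint8 (n, h, w, 3) -> float32 (n, 3, h, w) in [-1, 1]."""
        x = batch.astype(nn.DTYPE) / 127.5 - 1.0
        return np.transpose(x, (0, 3, 1, 2))

    def predict_proba(self, batch: np.ndarray, chunk: int = 512) -> np.ndarray:
        """Per-class probabilities (n, 2), rows summing to 1."""
        if batch.ndim != 4 or batch.shape[3] != 3:
            raise ValueError(f"expected (n, h, w, 3) uint8 batch, got {batch.shape}")
        if batch.shape[1] != self.input_size or batch.shape[2] != self.input_size:
            raise ValueError(f"expected {self.input_size}x{self.input_size} patches, "
                             f"got {batch.shape[1]}x{batch.shape[2]}")
        out = []
        for i in range(0, len(batch), chunk):
            logits = self.net.forward(self._normalize(batch[i:i + chunk]))
            out.append(nn.softmax(logits))
        self.net.clear_cache()
        return np.concatenate(out, axis=0)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net.state_arrays())
        meta = {"backbone": self.backbone, "input_size": self.input_size,
                "classes": list(CLASSES), "seed": self.seed}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "PatchClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        clf = cls.create(backbone=meta["backbone"], input_size=meta["input_size"],
                         seed=meta["seed"])
        with np.load(path.with_suffix(".npz")) as data:
            clf.net.load_state_arrays({k: data[k] for k in data.files})
        return clf


@dataclass
class SelectedInstance:
    bag_id: str
    instance_index: int
    assigned_label: str
    score: float
    pixels: np.ndarray = field(repr=False, default=None)


@dataclass
class MILState:
    iteration: int
    classifier: PatchClassifier
    selection_history: list[list[SelectedInstance]]
    validation_metric_history: list[float]
    best_iteration: int = -1
    best_weights: dict = field(default_factory=dict, repr=False)

    def restore_best(self) -> None:
        if self.best_weights:
            self.classifier.net.load_state_arrays(self.best_weights)


def evaluation_step(bags: list[Bag], classifier: PatchClassifier) -> list[SelectedInstance]:
    """Select each bag's top instance by tumour-class probability.

    Ties break to the lowest instance index; the selected instance inherits
    the bag's weak label.
    """
    selected = []
    for bag in bags:
        if not bag.instances:
            raise ValueError(f"bag {bag.bag_id} is empty")
        probs = classifier.predict_proba(bag.instance_array())
        scores = probs[:, 1]           # TUMOR-class probability for both bag types
        idx = int(np.argmax(scores))   # argmax takes the lowest index on ties
        selected.append(SelectedInstance(
            bag_id=bag.bag_id, instance_index=idx,
            assigned_label=bag.weak_label, score=float(scores[idx]),
            pixels=bag.instances[idx].pixels))
    return selected


def training_step(selected: list[SelectedInstance], classifier: PatchClassifier,
                  config: MILConfig,
                  optimizer: nn.Adam | None = None,
                  rng: np.random.Generator | None = None) -> PatchClassifier:
    """Cross-entropy / Adam epochs over the selected-instance dataset."""
    if not selected:
        raise ValueError("empty selection")
    labels = np.array([CLASSES.index(s.assigned_label) for s in selected])
    if len(set(labels.tolist())) < 2:
        logger.warning("single-class selection (%s only); training proceeds",
                       selected[0].assigned_label)
    X = np.stack([s.pixels for s in selected])
    optimizer = optimizer or nn.Adam([classifier.net], lr=config.learning_rate,
                                     betas=(0.9, 0.999))
    rng = rng or np.random.default_rng(config.seed)
    n = len(selected)
    for _ in range(config.epochs_per_iteration):
        order = rng.permutation(n)
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            x = classifier._normalize(X[idx])
            logits = classifier.net.forward(x)
            loss, grad = nn.softmax_cross_entropy(logits, labels[idx])
            if not np.isfinite(loss):
                raise RuntimeError("NaN loss in MIL training step")
            classifier.net.backward(grad)
            optimizer.step()
            optimizer.zero_grad()
    return classifier


def bag_validation_accuracy(bags: list[Bag], classifier: PatchClassifier) -> float:
    """Bag predicted TUMOR iff its max instance tumour probability >= 0.5."""
    correct = 0
    for bag in bags:
        probs = classifier.predict_proba(bag.instance_array())
        pred = TUMOR_LABEL if probs[:, 1].max() >= 0.5 else NORMAL_LABEL
        correct += int(pred == bag.weak_label)
    return correct / len(bags)


def train_mil(bags_train: list[Bag], bags_val: list[Bag],
              config: MILConfig | None = None) -> MILState:
    """Iterative evaluation/training MIL loop with best-iteration checkpointing."""
    config = config or MILConfig()
    if not bags_train or not bags_val:
        raise ValueError("both bag splits must be non-empty")
    classifier = PatchClassifier.create(config.backbone, config.input_size,
                                        seed=config.seed)
    rng = np.random.default_rng(config.seed + 1)
    optimizer = nn.Adam([classifier.net], lr=config.learning_rate,
                        betas=(0.9, 0.999))
    state = MILState(iteration=0, classifier=classifier,
                     selection_history=[], validation_metric_history=[])
    best_acc = -1.0
    for it in range(config.iterations):
        if config.restart_each_iteration and it > 0:
            classifier = PatchClassifier.create(config.backbone, config.input_size,
                                                seed=config.seed)
            optimizer = nn.Adam([classifier.net], lr=config.learning_rate,
                                betas=(0.9, 0.999))
            state.classifier = classifier
        selected = evaluation_step(bags_train, classifier)
        training_step(selected, classifier, config, optimizer=optimizer, rng=rng)
        acc = bag_validation_accuracy(bags_val, classifier)
        state.selection_history.append(selected)
        state.validation_metric_history.append(acc)
        state.iteration = it + 1
        if acc > best_acc:
            best_acc = acc
            state.best_iteration = it
            state.best_weights = classifier.net.copy_state()
        logger.info("MIL iteration %d: bag validation accuracy %.3f", it + 1, acc)
    return state


def classify_patch(patch: SmallPatch | np.ndarray,
                   classifier: PatchClassifier) -> tuple[str, float]:
    """Argmax class for one small patch; probability ties resolve to NORMAL."""
    pixels = patch.pixels if isinstance(patch, SmallPatch) else patch
    probs = classifier.predict_proba(pixels[None])[0]
    idx = int(np.argmax(probs))  # lowest index on exact tie -> NORMAL
    return CLASSES[idx], float(probs[idx])


def render_heatmap(image, classifier: PatchClassifier,
                   small_size: int | None = None, alpha: float = 0.45,
                   min_fg_fraction: float = 0.1) -> np.ndarray:
    """Red (tumour) / blue (normal) tile overlay on the tissue foreground.

    Background tiles are left uncoloured. Pure visualization; returns the
    blended RGB image.
    """
    small_size = small_size or classifier.input_size
    fg = otsu_foreground(image)
    patches = tile_small_patches(image.pixels, small_size, domain=image.domain)
    out = image.pixels.astype(np.float64).copy()
    red, blue = np.array([220.0, 40.0, 40.0]), np.array([40.0, 60.0, 220.0])
    if patches:
        batch = np.stack([p.pixels for p in patches])
        probs = classifier.predict_proba(batch)
        for p, prob in zip(patches, probs):
            r, c = p.origin
            if fg.mask[r:r + small_size, c:c + small_size].mean() < min_fg_fraction:
                continue
            colour = red if prob[1] >= 0.5 else blue
            out[r:r + small_size, c:c + small_size] = (
                (1 - alpha) * out[r:r + small_size, c:c + small_size] + alpha * colour)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)
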