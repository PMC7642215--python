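"""Conditional CycleGAN training loop and full-image translation.

Two generators (HE->Ki67, Ki67->HE) and two discriminators train
adversarially on *unpaired* small-patch pools: each step draws an HE batch
and a Ki-67 batch from independent shuffles, so even when the synthetic data
are pixel-aligned the networks never see aligned pairs together. When
conditioning is on, every real patch is labelled tumour/normal by its
domain's MIL classifier and the label is appended as a constant input plane;
the fake patch re-entering the reverse generator carries the SAME label as
its source patch.

Losses follow the reference configuration: binary cross-entropy for the
discriminators (real -> 1, fake -> 0), least-squares (MSE to 1) for the
generator's adversarial term, plus an L1 cycle-consistency term weighted by
``cycle_weight`` (default 10, the canonical value; the weight itself is not
specified by the reference). Optimizer is Adam at learning rate 1e-4,
betas (0.5, 0.999). A ``--symmetric-lsgan`` style flag swaps the
discriminator loss to MSE for the conventional LSGAN objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from pydantic import BaseModel, Field

from . import nn
from .config import logger
from .mil import PatchClassifier
from .preprocess import tile_small_patches
from .synthetic_slides import KI67, SlideImage
from .translation_models import (TranslationNets, condition_batch, denormalize,
                                 normalize, strip_label_channel)


class GanConfig(BaseModel):
    learning_rate: float = Field(default=1e-4, gt=0)
    epochs: int = Field(default=100, ge=0)
    batch_size: int = Field(default=8, ge=1)
    cycle_weight: float = Field(default=10.0, ge=0.0)
    seed: int = 0
    conditioned: bool = True
    width: float = Field(default=1.0, gt=0.0)
    betas: tuple[float, float] = (0.5, 0.999)
    steps_per_epoch: int | None = Field(
        default=None, description="override; default = pool size // batch size")
    cycle_loss_kind: str = Field(default="l1", pattern="^(l1|l2)$")
    symmetric_lsgan: bool = False
    identity_weight: float = Field(
        default=0.0, ge=0.0,
        description="weight of the identity term ||G_A2B(b) - b||_1; 0 = off. "
                    "Uses only same-domain images, so the data stay unpaired; "
                    "stabilizes palette learning at toy scale.")
    adv_weight: float = Field(
        default=1.0, ge=0.0,
        description="weight of the generator's adversarial term. The "
                    "adversarial per-pixel gradient dwarfs the L1 terms at "
                    "toy scale; < 1 rebalances them.")
    residual: bool = False
    val_fraction: float = Field(default=0.1, gt=0.0, lt=1.0)


@dataclass
class StepRecord:
    epoch: int
    step: int
    adv_g: float
    adv_d: float
    cycle: float
    he_indices: list[int]
    ki67_indices: list[int]


@dataclass
class CycleState:
    nets: TranslationNets
    epoch: int
    loss_history: list[dict]                    # per-epoch means
    step_log: list[StepRecord] = field(default_factory=list, repr=False)
    best_checkpoint: int = -1
    best_weights: dict = field(default_factory=dict, repr=False)

    def restore_best(self) -> None:
        if self.best_weights:
            self.nets.g_he_to_ki67.load_state_arrays(self.best_weights["g_he_to_ki67"])
            self.nets.g_ki67_to_he.load_state_arrays(self.best_weights["g_ki67_to_he"])


# ---------------------------------------------------------------------------
# Loss operations (scalar + gradient; oracle-checkable closed forms)
# ---------------------------------------------------------------------------

def discriminator_loss(d_real_scores: np.ndarray, d_fake_scores: np.ndarray,
                       symmetric_lsgan: bool = False,
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """BCE with target 1 on real and 0 on fake scores (mean of the two terms).

    Returns (loss, grad_wrt_real, grad_wrt_fake).
    """
    if symmetric_lsgan:
        lr, gr = nn.mse_to(d_real_scores, 1.0)
        lf, gf = nn.mse_to(d_fake_scores, 0.0)
    else:
        lr, gr = nn.bce_with_logits(d_real_scores, 1.0)
        lf, gf = nn.bce_with_logits(d_fake_scores, 0.0)
    return 0.5 * (lr + lf), 0.5 * gr, 0.5 * gf


def generator_adv_loss(d_fake_scores: np.ndarray) -> tuple[float, np.ndarray]:
    """Least-squares adversarial term: mean((score - 1)^2)."""
    return nn.mse_to(d_fake_scores, 1.0)


def cycle_loss(original: np.ndarray, reconstructed: np.ndarray,
               kind: str = "l1") -> tuple[float, np.ndarray]:
    """Pixel reconstruction penalty between an image and its round trip.

    Operates on 3-channel normalized arrays (label channels are excluded by
    the caller). Returns (loss, grad_wrt_reconstructed).
    """
    if original.shape != reconstructed.shape:
        raise ValueError(f"shape mismatch {original.shape} vs {reconstructed.shape}")
    if kind == "l1":
        loss, grad = nn.l1(reconstructed, original)
    elif kind == "l2":
        loss, grad = nn.mse_to(reconstructed - original, 0.0)
    else:
        raise ValueError(f"unknown cycle loss kind {kind!r}")
    return loss, grad


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _as_pool(patches) -> np.ndarray:
    """Accept (n, h, w, 3) uint8 arrays or lists of SmallPatch."""
    if isinstance(patches, np.ndarray):
        return patches
    return np.stack([p.pixels for p in patches])


def _classify_pool(pool: np.ndarray, classifier: PatchClassifier) -> list[str]:
    from .mil import CLASSES
    probs = classifier.predict_proba(pool)
    return [CLASSES[i] for i in np.argmax(probs, axis=1)]


class _Shuffler:
    """Endless independent index stream over a pool (reshuffled each pass)."""

    def __init__(self, n: int, rng: np.random.Generator) -> None:
        self.n = n
        self.rng = rng
        self.order: list[int] = []

    def take(self, k: int) -> list[int]:
        out: list[int] = []
        while len(out) < k:
            if not self.order:
                self.order = list(self.rng.permutation(self.n))
            out.append(int(self.order.pop()))
        return out


def train_cyclegan(he_patches, ki67_patches,
                   he_classifier: PatchClassifier | None,
                   ki67_classifier: PatchClassifier | None,
                   config: GanConfig | None = None,
                   generator_input_hook: Callable[[str, np.ndarray], None] | None = None,
                   ) -> CycleState:
    """Adversarial training of the two translation cycles.

    ``generator_input_hook(name, batch)`` — optional instrumentation called
    with every batch entering a generator (used by tests to verify the
    conditioning contract).
    """
    config = config or GanConfig()
    he_pool = _as_pool(he_patches)
    ki_pool = _as_pool(ki67_patches)
    if len(he_pool) == 0 or len(ki_pool) == 0:
        raise ValueError("both patch pools must be non-empty")
    if config.conditioned and (he_classifier is None or ki67_classifier is None):
        raise ValueError("conditioned training requires both domain classifiers")

    nets = TranslationNets.create(conditioned=config.conditioned,
                                  width=config.width, seed=config.seed,
                                  residual=config.residual)
    state = CycleState(nets=nets, epoch=0, loss_history=[])
    if config.epochs == 0:
        return state

    # Pre-compute labels once: classifier weights are fixed during GAN training.
    if config.conditioned:
        he_labels = _classify_pool(he_pool, he_classifier)
        ki_labels = _classify_pool(ki_pool, ki67_classifier)
    else:
        he_labels = ki_labels = None

    rng = np.random.default_rng(config.seed)
    he_stream = _Shuffler(len(he_pool), np.random.default_rng(rng.integers(2**31)))
    ki_stream = _Shuffler(len(ki_pool), np.random.default_rng(rng.integers(2**31)))
    # held-out validation indices for checkpoint selection (cycle loss)
    n_val_he = max(1, int(len(he_pool) * config.val_fraction))
    n_val_ki = max(1, int(len(ki_pool) * config.val_fraction))
    val_he = rng.permutation(len(he_pool))[:n_val_he]
    val_ki = rng.permutation(len(ki_pool))[:n_val_ki]

    opt_g = nn.Adam([nets.g_he_to_ki67, nets.g_ki67_to_he],
                    lr=config.learning_rate, betas=config.betas)
    opt_d = nn.Adam([nets.d_he, nets.d_ki67],
                    lr=config.learning_rate, betas=config.betas)

    steps = config.steps_per_epoch or max(1, min(len(he_pool), len(ki_pool))
                                          // config.batch_size)
    best_val = np.inf
    for epoch in range(config.epochs):
        sums = {"adv_g": 0.0, "adv_d": 0.0, "cycle": 0.0}
        for step in range(steps):
            idx_he = he_stream.take(config.batch_size)
            idx_ki = ki_stream.take(config.batch_size)
            a = normalize(he_pool[idx_he])
            b = normalize(ki_pool[idx_ki])
            la = [he_labels[i] for i in idx_he] if he_labels else None
            lb = [ki_labels[i] for i in idx_ki] if ki_labels else None

            def gin(x, labels):
                return condition_batch(x, labels) if config.conditioned else x

            # ---- generator phase -------------------------------------------
            a_in = gin(a, la)
            b_in = gin(b, lb)
            if generator_input_hook:
                generator_input_hook("g_he_to_ki67", a_in)
                generator_input_hook("g_ki67_to_he", b_in)
            fake_b = nets.g_he_to_ki67.forward(a_in)          # pass 1 of G_AB
            rec_a_in = gin(fake_b, la)                        # same label carried
            if generator_input_hook:
                generator_input_hook("g_ki67_to_he", rec_a_in)
            rec_a = nets.g_ki67_to_he.forward(rec_a_in)       # pass 1 of G_BA
            fake_a = nets.g_ki67_to_he.forward(b_in)          # pass 2 of G_BA
            rec_b_in = gin(fake_a, lb)
            if generator_input_hook:
                generator_input_hook("g_he_to_ki67", rec_b_in)
            rec_b = nets.g_he_to_ki67.forward(rec_b_in)       # pass 2 of G_AB
            if config.identity_weight > 0:
                idt_b = nets.g_he_to_ki67.forward(b_in)       # pass 3 of G_AB
                idt_a = nets.g_ki67_to_he.forward(a_in)       # pass 3 of G_BA
            s_fake_b = nets.d_ki67.forward(fake_b)
            s_fake_a = nets.d_he.forward(fake_a)

            adv_b, g_adv_b = generator_adv_loss(s_fake_b)
            adv_a, g_adv_a = generator_adv_loss(s_fake_a)
            cyc_a, g_cyc_a = cycle_loss(a, rec_a, config.cycle_loss_kind)
            cyc_b, g_cyc_b = cycle_loss(b, rec_b, config.cycle_loss_kind)
            adv_g = adv_a + adv_b
            cyc = cyc_a + cyc_b
            if not np.isfinite(adv_g + cyc):
                raise RuntimeError(f"NaN generator loss at epoch {epoch} step {step}")

            lam = config.cycle_weight
            # Backward in LIFO order of the forwards above.
            if config.identity_weight > 0:
                _, g_idt_b = cycle_loss(b, idt_b, config.cycle_loss_kind)
                _, g_idt_a = cycle_loss(a, idt_a, config.cycle_loss_kind)
                nets.g_ki67_to_he.backward(config.identity_weight * g_idt_a)
                nets.g_he_to_ki67.backward(config.identity_weight * g_idt_b)
            wa = config.adv_weight
            g_fake_a = strip_label_channel(
                nets.g_he_to_ki67.backward(lam * g_cyc_b)) if config.conditioned \
                else nets.g_he_to_ki67.backward(lam * g_cyc_b)      # pops G_AB pass 2
            g_fake_a = g_fake_a + wa * nets.d_he.backward(g_adv_a)
            nets.g_ki67_to_he.backward(g_fake_a)                    # pops G_BA pass 2
            g_fake_b = strip_label_channel(
                nets.g_ki67_to_he.backward(lam * g_cyc_a)) if config.conditioned \
                else nets.g_ki67_to_he.backward(lam * g_cyc_a)      # pops G_BA pass 1
            g_fake_b = g_fake_b + wa * nets.d_ki67.backward(g_adv_b)
            nets.g_he_to_ki67.backward(g_fake_b)                    # pops G_AB pass 1
            opt_g.step()
            opt_g.zero_grad()
            # discriminator grads accumulated during the generator phase are noise
            nets.d_he.zero_grad()
            nets.d_ki67.zero_grad()

            # ---- discriminator phase ---------------------------------------
            s_real_b = nets.d_ki67.forward(b)
            s_fake_b2 = nets.d_ki67.forward(fake_b)   # fakes treated as constants
            loss_db, gr_b, gf_b = discriminator_loss(s_real_b, s_fake_b2,
                                                     config.symmetric_lsgan)
            nets.d_ki67.backward(gf_b)                # pops fake pass
            nets.d_ki67.backward(gr_b)                # pops real pass
            s_real_a = nets.d_he.forward(a)
            s_fake_a2 = nets.d_he.forward(fake_a)
            loss_da, gr_a, gf_a = discriminator_loss(s_real_a, s_fake_a2,
                                                     config.symmetric_lsgan)
            nets.d_he.backward(gf_a)
            nets.d_he.backward(gr_a)
            adv_d = loss_da + loss_db
            if not np.isfinite(adv_d):
                raise RuntimeError(f"NaN discriminator loss at epoch {epoch} step {step}")
            opt_d.step()
            opt_d.zero_grad()

            sums["adv_g"] += adv_g
            sums["adv_d"] += adv_d
            sums["cycle"] += cyc
            state.step_log.append(StepRecord(epoch=epoch, step=step,
                                             adv_g=adv_g, adv_d=adv_d, cycle=cyc,
                                             he_indices=idx_he, ki67_indices=idx_ki))
        state.loss_history.append({k: v / steps for k, v in sums.items()})
        state.epoch = epoch + 1

        val = _validation_cycle_loss(nets, he_pool[val_he], ki_pool[val_ki],
                                     [he_labels[i] for i in val_he] if he_labels else None,
                                     [ki_labels[i] for i in val_ki] if ki_labels else None,
                                     config)
        if val < best_val:
            best_val = val
            state.best_checkpoint = epoch
            state.best_weights = {
                "g_he_to_ki67": nets.g_he_to_ki67.copy_state(),
                "g_ki67_to_he": nets.g_ki67_to_he.copy_state(),
            }
        logger.info("GAN epoch %d: adv_g %.4f adv_d %.4f cycle %.4f val %.4f",
                    epoch + 1, state.loss_history[-1]["adv_g"],
                    state.loss_history[-1]["adv_d"],
                    state.loss_history[-1]["cycle"], val)
    return state


def _validation_cycle_loss(nets: TranslationNets, he_val: np.ndarray,
                           ki_val: np.ndarray, he_labels, ki_labels,
                           config: GanConfig) -> float:
    def gin(x, labels):
        return condition_batch(x, labels) if config.conditioned else x

    a = normalize(he_val)
    b = normalize(ki_val)
    fake_b = nets.g_he_to_ki67.forward(gin(a, he_labels))
    rec_a = nets.g_ki67_to_he.forward(gin(fake_b, he_labels))
    fake_a = nets.g_ki67_to_he.forward(gin(b, ki_labels))
    rec_b = nets.g_he_to_ki67.forward(gin(fake_a, ki_labels))
    la, _ = cycle_loss(a, rec_a, config.cycle_loss_kind)
    lb, _ = cycle_loss(b, rec_b, config.cycle_loss_kind)
    for net in (nets.g_he_to_ki67, nets.g_ki67_to_he):
        net.clear_cache()
    return la + lb


def translate_image(he_image: SlideImage, he_classifier: PatchClassifier | None,
                    generator: nn.Sequential, small_size: int = 224,
                    conditioned: bool = True, batch_size: int = 64,
                    background: int = 248) -> SlideImage:
    """Translate a full HE image tile by tile into a synthetic Ki-67 image.

    The whole image is tiled background included; each tile is classified
    (when conditioned), conditioned, generated and de-normalized, and the
    tiles are stitched back by origin. Any border remainder that does not fit
    a full tile is filled with the background colour, so the output has the
    source's exact dimensions.
    """
    h, w = he_image.shape
    if h < small_size or w < small_size:
        raise ValueError(f"image {h}x{w} smaller than tile {small_size}")
    if conditioned and he_classifier is None:
        raise ValueError("conditioned translation requires the HE classifier")
    patches = tile_small_patches(he_image.pixels, small_size, domain=he_image.domain)
    batch = np.stack([p.pixels for p in patches])
    if conditioned:
        labels = _classify_pool(batch, he_classifier)
    out_tiles = []
    for i in range(0, len(batch), batch_size):
        x = normalize(batch[i:i + batch_size])
        if conditioned:
            x = condition_batch(x, labels[i:i + batch_size])
        y = generator.forward(x)
        generator.clear_cache()
        out_tiles.append(denormalize(y))
    tiles = np.concatenate(out_tiles, axis=0)
    out = np.full((h, w, 3), background, dtype=np.uint8)
    for p, tile in zip(patches, tiles):
        r, c = p.origin
        out[r:r + small_size, c:c + small_size] = tile
    return SlideImage(pixels=out, domain=KI67,
                      slide_id=he_image.slide_id + "_synthetic",
                      ground_truth=he_image.ground_truth)
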