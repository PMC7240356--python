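"""Conditional-GAN staining and destaining models.

A pix2pix-style setup: a U-Net generator translates a nonstained RGB patch
into an H&E-appearance patch (or the reverse for the destaining direction),
and a conditional patch discriminator judges (input, candidate) pairs.  The
generator objective augments the usual adversarial + L1 terms with a Pearson
correlation coefficient (PCC) term that rewards global linear agreement
between the generated and ground-truth images, encouraging tissue-structure
preservation and suppressing per-patch brightness drift that shows up as
tiling seams after stitching:

    L_G = lambda_adv * L_cGAN + lambda_l1 * L1 + lambda_pcc * (1 - PCC)

with defaults lambda_adv=1, lambda_l1=100 (the customary pix2pix weighting)
and lambda_pcc=10.  Setting ``lambda_pcc=0`` recovers the plain pix2pix
objective, which makes the ablation a single flag.

Pixels are normalised to [-1, 1] inside the model and converted back to
8-bit at the boundary (round half away from zero).  Staining and destaining
are two independently trained models.  All randomness — weight
initialisation and batch shuffling — flows from the single seed in
:class:`TrainingConfig`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from .imaging import ImagePatch, RGBImage, RegisteredPair, StainState, patchify, stitch
from .nn import Adam, Discriminator, Generator, Tensor, bce_with_logits

log = logging.getLogger(__name__)

_UNSTAINED_STATES = {StainState.NONSTAINED, StainState.COMP_DESTAINED}


@dataclass
class GeneratorSpec:
    """Architecture of the U-Net generator.

    The canonical configuration (depth 4, two convolutions per level) tracks
    19 convolutional layers for the activation-map analysis; shallower
    desk-scale models track proportionally fewer.
    """

    depth: int = 4
    base_channels: int = 64
    convs_per_level: int = 2
    skip_connections: bool = True

    @property
    def tracked_layer_count(self) -> int:
        return 2 * self.depth * self.convs_per_level + 3


@dataclass
class LossConfig:
    """Weights of the generator objective's three terms."""

    lambda_adv: float = 1.0
    lambda_l1: float = 100.0
    lambda_pcc: float = 10.0
    per_channel_pcc: bool = False

    def __post_init__(self) -> None:
        if min(self.lambda_adv, self.lambda_l1, self.lambda_pcc) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class TrainingConfig:
    direction: str = "stain"  # "stain": nonstained -> stained; "destain" reverses
    epochs: int = 10
    batch_size: int = 8
    lr_generator: float = 2e-3
    lr_discriminator: float = 2e-3
    seed: int = 0
    patch_size: int = 64

    def __post_init__(self) -> None:
        if self.direction not in ("stain", "destain"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


# ---------------------------------------------------------------------------
# pixel <-> model-space conversion
# ---------------------------------------------------------------------------


def to_unit(pixels: np.ndarray) -> np.ndarray:
    """uint8 HxWx3 -> float32 3xHxW in [-1, 1]."""
    x = pixels.astype(np.float32) / 127.5 - 1.0
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def from_unit(x: np.ndarray) -> np.ndarray:
    """float 3xHxW in [-1, 1] -> uint8 HxWx3, rounding half away from zero."""
    v = (np.asarray(x).transpose(1, 2, 0) + 1.0) * 127.5
    return np.clip(np.floor(v + 0.5), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

_EPS = 1e-8


def _as_batch_tensor(x) -> Tensor:
    if not isinstance(x, Tensor):
        x = Tensor(np.asarray(x, dtype=np.float32))
    if x.data.ndim == 3:
        x = x.reshape(1, *x.data.shape)
    if x.data.ndim != 4:
        raise ValueError("expected a (N, C, H, W) batch or a single (C, H, W) image")
    return x


def pcc_loss(predicted, target, per_channel: bool = False) -> Tensor:
    """``1 - PCC`` between prediction and target, averaged over the batch.

    The correlation is computed over all pixels and channels of each image
    jointly (or per channel, then averaged, with ``per_channel=True``).
    Range [0, 2]; differentiable in ``predicted``; invariant to a common
    positive affine rescaling of both arguments.  A zero-variance image is
    assigned correlation 0 (loss contribution 1) and logged.
    """
    p = _as_batch_tensor(predicted)
    t = _as_batch_tensor(target)
    if p.data.shape != t.data.shape:
        raise ValueError("predicted/target shapes differ")
    axes = (2, 3) if per_channel else (1, 2, 3)
    pm = p - p.mean(axis=axes, keepdims=True)
    tm = t - t.mean(axis=axes, keepdims=True)
    num = (pm * tm).sum(axis=axes)
    den = ((pm * pm).sum(axis=axes) * (tm * tm).sum(axes) + _EPS).sqrt()
    if (np.ptp(p.data, axis=axes) == 0).any() or (
        np.ptp(t.data, axis=axes) == 0
    ).any():
        log.warning("pcc_loss: zero-variance image; correlation taken as 0")
    r = num / den
    return 1.0 - r.mean()


def mae_loss(predicted, target) -> Tensor:
    p = _as_batch_tensor(predicted)
    t = _as_batch_tensor(target)
    return (p - t).abs().mean()


def generator_loss(adv_term, predicted, target, cfg: LossConfig) -> Tensor:
    """Weighted sum of adversarial, L1 and PCC terms.

    Reduces to the plain pix2pix objective when ``cfg.lambda_pcc == 0``.
    """
    total = cfg.lambda_adv * (
        adv_term if isinstance(adv_term, Tensor) else Tensor(adv_term)
    )
    total = total + cfg.lambda_l1 * mae_loss(predicted, target)
    if cfg.lambda_pcc != 0.0:
        total = total + cfg.lambda_pcc * pcc_loss(
            predicted, target, per_channel=cfg.per_channel_pcc
        )
    return total


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """A trained translator: weights + architecture + provenance."""

    generator: Generator
    discriminator: Discriminator
    spec: GeneratorSpec
    train_cfg: TrainingConfig
    loss_cfg: LossConfig
    history: list[dict] = field(default_factory=list)

    @property
    def direction(self) -> str:
        return self.train_cfg.direction

    def save(self, path) -> None:
        """Serialise to a single ``.npz`` checkpoint (weights + configs)."""
        arrays = {n: p.data for n, p in self.generator.params}
        arrays.update({n: p.data for n, p in self.discriminator.params})
        meta = json.dumps(
            {
                "spec": asdict(self.spec),
                "train_cfg": asdict(self.train_cfg),
                "loss_cfg": asdict(self.loss_cfg),
                "history": self.history,
            }
        )
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            arrays = {k: data[k] for k in data.files if k != "__meta__"}
        spec = GeneratorSpec(**meta["spec"])
        train_cfg = TrainingConfig(**meta["train_cfg"])
        loss_cfg = LossConfig(**meta["loss_cfg"])
        model = _build_model(spec, train_cfg, loss_cfg)
        model.history = meta["history"]
        for n, p in model.generator.params + model.discriminator.params:
            p.data = arrays[n].astype(np.float32)
        return model


def _build_model(spec: GeneratorSpec, train_cfg: TrainingConfig,
                 loss_cfg: LossConfig) -> TrainedModel:
    rng = np.random.default_rng(train_cfg.seed)
    gen = Generator(spec.depth, spec.base_channels, spec.convs_per_level, rng)
    disc = Discriminator(max(8, spec.base_channels // 2), rng)
    return TrainedModel(gen, disc, spec, train_cfg, loss_cfg)


def _orient(pair: RegisteredPair, direction: str) -> tuple[ImagePatch, ImagePatch]:
    """Return (model input, model output) patches for the given direction."""
    a, b = pair.source, pair.target
    if a.stain_state in _UNSTAINED_STATES and b.stain_state not in _UNSTAINED_STATES:
        unstained, stained = a, b
    elif b.stain_state in _UNSTAINED_STATES and a.stain_state not in _UNSTAINED_STATES:
        unstained, stained = b, a
    else:  # tags do not disambiguate; trust (source -> target) for "stain"
        unstained, stained = a, b
    return (unstained, stained) if direction == "stain" else (stained, unstained)


def train(
    pairs: list[RegisteredPair],
    cfg: TrainingConfig,
    loss_cfg: LossConfig | None = None,
    spec: GeneratorSpec | None = None,
    val_pairs: list[RegisteredPair] | None = None,
) -> TrainedModel:
    """Train a staining or destaining translator on registered pairs.

    Deterministic given (seed, data, configuration) on one machine: weight
    initialisation and shuffling draw from one seeded generator.  Records
    per-epoch means of every loss term; if ``val_pairs`` is given, held-out
    PCC/SSIM/PSNR are evaluated each epoch as well.
    """
    if not pairs:
        raise ValueError("no training pairs")
    loss_cfg = loss_cfg or LossConfig()
    spec = spec or GeneratorSpec(depth=2, base_channels=8, convs_per_level=1)
    sizes = {p.source.patch_size for p in pairs}
    if len(sizes) != 1:
        raise ValueError(f"mixed patch sizes {sorted(sizes)}")
    size = sizes.pop()
    if size != cfg.patch_size:
        raise ValueError(
            f"training pairs are {size}px but cfg.patch_size is "
            f"{cfg.patch_size}"
        )
    if size % (2 ** spec.depth):
        raise ValueError(
            f"patch size {size} not divisible by 2^depth={2 ** spec.depth}"
        )

    xs = np.stack([to_unit(_orient(p, cfg.direction)[0].pixels) for p in pairs])
    ys = np.stack([to_unit(_orient(p, cfg.direction)[1].pixels) for p in pairs])

    model = _build_model(spec, cfg, loss_cfg)
    gen, disc = model.generator, model.discriminator
    opt_g = Adam(gen.params, lr=cfg.lr_generator)
    opt_d = Adam(disc.params, lr=cfg.lr_discriminator)
    rng = np.random.default_rng(cfg.seed + 1)

    n = len(pairs)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        sums = {"total": 0.0, "adv": 0.0, "l1": 0.0, "pcc": 0.0, "disc": 0.0}
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            x = Tensor(xs[idx])
            y = Tensor(ys[idx])

            fake = gen.forward(x)

            # discriminator step (generator output detached)
            opt_d.zero_grad()
            d_loss = 0.5 * (
                bce_with_logits(disc(x, y), 1.0)
                + bce_with_logits(disc(x, Tensor(fake.data)), 0.0)
            )
            d_loss.backward()
            opt_d.step()

            # generator step
            opt_g.zero_grad()
            opt_d.zero_grad()  # discard grads that flow through D below
            adv = bce_with_logits(disc(x, fake), 1.0)
            l1 = mae_loss(fake, y)
            pcc_t = pcc_loss(fake, y, per_channel=loss_cfg.per_channel_pcc)
            total = (
                loss_cfg.lambda_adv * adv
                + loss_cfg.lambda_l1 * l1
                + loss_cfg.lambda_pcc * pcc_t
            )
            total.backward()
            opt_g.step()
            opt_d.zero_grad()

            sums["total"] += float(total.data)
            sums["adv"] += float(adv.data)
            sums["l1"] += float(l1.data)
            sums["pcc"] += float(pcc_t.data)
            sums["disc"] += float(d_loss.data)
            n_batches += 1

        row = {"epoch": epoch + 1}
        row.update({k: v / n_batches for k, v in sums.items()})
        if val_pairs:
            row.update(_validate(model, val_pairs))
        model.history.append(row)
        log.info("epoch %d: %s", epoch + 1,
                 ", ".join(f"{k}={v:.4f}" for k, v in row.items() if k != "epoch"))
    return model


def _validate(model: TrainedModel, val_pairs: list[RegisteredPair]) -> dict:
    from . import metrics as qm

    pccs, ssims, psnrs = [], [], []
    for pair in val_pairs:
        inp, out = _orient(pair, model.direction)
        pred = apply(model, RGBImage(inp.pixels, inp.stain_state, inp.slide_id))
        ref = RGBImage(out.pixels, out.stain_state, out.slide_id)
        try:
            pccs.append(qm.pcc(pred, ref))
        except ValueError:
            pass
        ssims.append(qm.ssim(pred, ref))
        p = qm.psnr(pred, ref)
        if np.isfinite(p):
            psnrs.append(p)
    return {
        "val_pcc": float(np.mean(pccs)) if pccs else float("nan"),
        "val_ssim": float(np.mean(ssims)),
        "val_psnr": float(np.mean(psnrs)) if psnrs else float("inf"),
    }


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def apply(model: TrainedModel, image: RGBImage | ImagePatch,
          batch_size: int = 8) -> RGBImage:
    """Translate an image with a trained model.

    Images other than a single model-sized patch are tiled with
    :func:`virtualstain.imaging.patchify` (reflect padding as needed),
    translated patch by patch and stitched back, so the output always has
    the input's shape.  The result is tagged ``comp_stained`` or
    ``comp_destained`` according to the model direction.
    """
    out_state = (
        StainState.COMP_STAINED
        if model.direction == "stain"
        else StainState.COMP_DESTAINED
    )
    pixels = image.pixels
    if pixels.shape[2] != 3:
        raise ValueError("expected a 3-channel image")
    rgb = RGBImage(
        pixels,
        stain_state=image.stain_state,
        slide_id=getattr(image, "slide_id", ""),
    )
    ps = model.train_cfg.patch_size
    h, w = rgb.shape
    if (h, w) == (ps, ps):
        out = _forward_pixels(model, pixels[None])[0]
        return RGBImage(out, stain_state=out_state, slide_id=rgb.slide_id)
    patches, grid = patchify(rgb, patch_size=ps, stride=ps)
    outputs = []
    for start in range(0, len(patches), batch_size):
        chunk = patches[start : start + batch_size]
        preds = _forward_pixels(model, np.stack([p.pixels for p in chunk]))
        outputs.extend(
            ImagePatch(pred, origin=p.origin, slide_id=p.slide_id,
                       stain_state=out_state)
            for pred, p in zip(preds, chunk)
        )
    stitched = stitch(outputs, grid)
    return RGBImage(stitched.pixels, stain_state=out_state, slide_id=rgb.slide_id)


def _forward_pixels(model: TrainedModel, batch: np.ndarray) -> list[np.ndarray]:
    x = Tensor(np.stack([to_unit(img) for img in batch]))
    y = model.generator.forward(x)
    return [from_unit(img) for img in y.data]
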