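"""Unsupervised training of the preconditioned denoiser on clean patches.

The loop sees *only* clean images: each iteration extracts random patches,
applies label-free flips/rotations, perturbs each patch at a random scale
drawn from the log-normal training distribution, and minimizes

    lambda(sigma) ||D_theta(x; sigma) - y||^2,
    lambda(sigma) = (sigma^2 + sigma_data^2) / (sigma sigma_data)^2,

which equals the field-space perturbation objective up to the per-sigma
weighting (the field and the denoiser are related by an exact algebraic
identity).  With this lambda the loss reduces to a unit-scale regression
on the raw backbone output, so training is well conditioned across sigma.
Adam plus an exponential moving average of the weights; the EMA model is
returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .autodiff import Tensor, add as ad_add, sum_squares, scale as ad_scale
from .backbone import BackboneConfig, build_backbone
from .denoiser import DenoiserModel, HUNormalization, PreconditioningParams
from .pfgmpp import (
    GeometryConfig,
    NoiseScaleDistribution,
    perturb,
    sample_training_scale,
    sigma_equivalent,
)

__all__ = [
    "TrainingConfig",
    "draw_perturbations",
    "weighted_loss",
    "loss_on_batch",
    "train",
    "ema_update",
    "adam_step",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters for one training run.

    Paper-scale values (batch 32, lr 2e-4, 1e5 iterations, patch 256,
    augment 0.15, dropout 0.10) are expressible; desk-scale defaults are
    deliberately tiny so a run finishes on one CPU in minutes.
    """

    geom: GeometryConfig
    patch_size: int = 8
    batch_size: int = 32
    learning_rate: float = 2e-4
    n_iterations: int = 2000
    ema_halflife_images: float = 2000.0
    augment_prob: float = 0.15
    dropout_prob: float = 0.0
    scale_dist: NoiseScaleDistribution = field(default_factory=NoiseScaleDistribution)
    sigma_data: float = 0.5
    hu_offset: float = 0.0
    hu_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.augment_prob <= 1.0:
            raise ValueError("augment_prob must be in [0, 1]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def _augment(patch: np.ndarray, rng: np.random.Generator, prob: float) -> np.ndarray:
    """Label-free flips and 90-degree rotations, each applied with ``prob``."""
    if rng.random() < prob:
        patch = patch[::-1, :]
    if rng.random() < prob:
        patch = patch[:, ::-1]
    if rng.random() < prob:
        patch = np.rot90(patch, k=int(rng.integers(1, 4)))
    return np.ascontiguousarray(patch)


def _sample_batch(
    dataset: Sequence[np.ndarray], cfg: TrainingConfig, rng: np.random.Generator
) -> np.ndarray:
    """Random patches (normalized units) with augmentation; (B, P, P)."""
    ps = cfg.patch_size
    out = np.empty((cfg.batch_size, ps, ps))
    for b in range(cfg.batch_size):
        img = dataset[int(rng.integers(len(dataset)))]
        if img.shape[0] < ps or img.shape[1] < ps:
            raise ValueError(
                f"patch_size {ps} exceeds image shape {img.shape}"
            )
        i = int(rng.integers(img.shape[0] - ps + 1))
        j = int(rng.integers(img.shape[1] - ps + 1))
        out[b] = _augment(img[i : i + ps, j : j + ps], rng, cfg.augment_prob)
    return out


def draw_perturbations(
    clean: np.ndarray, cfg: TrainingConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample noise scales and perturbed versions of a clean batch.

    Returns ``(xs, sigmas)`` where ``sigmas`` are in sigma units regardless
    of the geometry branch (translation applied for finite D).
    """
    xs, sigmas = [], []
    for y in clean:
        scale_r = sample_training_scale(cfg.scale_dist, cfg.geom, rng)
        sigmas.append(sigma_equivalent(scale_r, cfg.geom))
        xs.append(perturb(y, scale_r, cfg.geom, rng).x)
    return np.stack(xs), np.asarray(sigmas)


def weighted_loss(
    model,
    xs: np.ndarray,
    ys: np.ndarray,
    sigmas: np.ndarray,
    sigma_data: float = 0.5,
) -> float:
    """Mean over samples of ``lambda(sigma) * mean_px (D(x; sigma) - y)^2``.

    Works for any object with a ``denoise`` method (including the analytic
    oracle); a symmetric mean, so invariant to permuting the samples.
    """
    p = PreconditioningParams(sigma_data)
    terms = [
        p.loss_weight(float(s)) * float(np.mean((model.denoise(x, float(s)) - y) ** 2))
        for x, y, s in zip(xs, ys, sigmas)
    ]
    return float(np.mean(terms))


def _batch_loss_graph(
    model: DenoiserModel,
    clean: np.ndarray,
    cfg: TrainingConfig,
    rng: np.random.Generator,
    train_mode: bool,
) -> tuple[Tensor, Dict[str, Tensor]]:
    """Build the autodiff graph of the weighted batch loss.

    Written in preconditioned form: with lambda = 1/c_out^2 the per-sample
    term is ||F(c_in x, c_noise) - (y - c_skip x)/c_out||^2, averaged over
    batch and pixels.
    """
    p = model.precond
    xs, sigmas = draw_perturbations(clean, cfg, rng)
    cins = np.array([p.c_in(s) for s in sigmas])
    cnoises = np.array([p.c_noise(s) for s in sigmas])
    targets = np.stack(
        [(y - p.c_skip(s) * x) / p.c_out(s) for x, y, s in zip(xs, clean, sigmas)]
    )
    xb = xs[:, None] * cins[:, None, None, None]
    target = targets[:, None]

    params_t = {k: Tensor(v) for k, v in model.params.items()}
    f = model.backbone.forward_tensor(
        params_t, Tensor(xb), np.asarray(cnoises), train=train_mode, rng=rng
    )
    diff = ad_add(f, Tensor(-target))
    loss = ad_scale(sum_squares(diff), 1.0 / target.size)
    return loss, params_t


def loss_on_batch(
    model: DenoiserModel,
    patches: np.ndarray,
    cfg: TrainingConfig,
    rng: np.random.Generator,
) -> float:
    """Weighted perturbation loss of one batch of clean patches (forward only)."""
    patches = np.asarray(patches, dtype=float)
    if patches.ndim != 3 or patches.shape[1] != patches.shape[2]:
        raise ValueError(f"expected (B, P, P) patches, got {patches.shape}")
    if (patches.shape[1], patches.shape[2]) != tuple(model.data_shape) and \
            model.backbone_config.kind == "mlp":
        raise ValueError(
            f"patches of shape {patches.shape[1:]} do not match model input {model.data_shape}"
        )
    xs, sigmas = draw_perturbations(patches, cfg, rng)
    return weighted_loss(model, xs, patches, sigmas, model.precond.sigma_data)


def adam_step(
    params: Dict[str, np.ndarray],
    grads: Dict[str, np.ndarray],
    state: Dict[str, Dict[str, np.ndarray]],
    lr: float,
    step: int,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> None:
    """In-place Adam update."""
    for k, g in grads.items():
        st = state.setdefault(k, {"m": np.zeros_like(g), "v": np.zeros_like(g)})
        st["m"] = beta1 * st["m"] + (1 - beta1) * g
        st["v"] = beta2 * st["v"] + (1 - beta2) * g * g
        mhat = st["m"] / (1 - beta1**step)
        vhat = st["v"] / (1 - beta2**step)
        params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


def ema_update(
    ema_weights: Dict[str, np.ndarray],
    current_weights: Dict[str, np.ndarray],
    halflife: float,
    images_seen: int,
) -> Dict[str, np.ndarray]:
    """EMA with per-step decay ``0.5 ** (images_seen / halflife)``.

    ``halflife`` is in images-seen units; ``halflife -> 0`` copies the
    current weights.
    """
    if halflife <= 0:
        return {k: np.array(v) for k, v in current_weights.items()}
    decay = 0.5 ** (images_seen / halflife)
    out = {}
    for k, cur in current_weights.items():
        if ema_weights[k].shape != cur.shape:
            raise ValueError(f"shape mismatch for {k}")
        out[k] = decay * ema_weights[k] + (1 - decay) * cur
    return out


def train(
    dataset: Sequence[np.ndarray],
    cfg: TrainingConfig,
    backbone_config: Optional[BackboneConfig] = None,
    log_every: int = 50,
) -> DenoiserModel:
    """Run the unsupervised loop on clean images; returns the EMA model.

    The returned model carries ``history``, a list of dicts
    ``{"iteration", "loss", "ema_decay"}``.  Raises ``RuntimeError`` if the
    loss goes non-finite.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must be nonempty")
    backbone_config = backbone_config or BackboneConfig(
        dropout_prob=cfg.dropout_prob
    )
    norm = HUNormalization(cfg.hu_offset, cfg.hu_scale)
    normed = [norm.to_normalized(np.asarray(img, dtype=float)) for img in dataset]

    rng = np.random.default_rng(cfg.seed)
    data_shape = (cfg.patch_size, cfg.patch_size)
    backbone = build_backbone(backbone_config, data_shape=data_shape)
    params = backbone.init_params(rng)
    model = DenoiserModel(
        backbone_config,
        params,
        cfg.geom,
        PreconditioningParams(cfg.sigma_data),
        norm,
        data_shape,
    )
    ema = {k: np.array(v) for k, v in params.items()}
    adam_state: Dict[str, Dict[str, np.ndarray]] = {}
    history: List[dict] = []
    decay = (
        0.5 ** (cfg.batch_size / cfg.ema_halflife_images)
        if cfg.ema_halflife_images > 0
        else 0.0
    )

    for it in range(1, cfg.n_iterations + 1):
        batch = _sample_batch(normed, cfg, rng)
        loss, params_t = _batch_loss_graph(model, batch, cfg, rng, train_mode=True)
        if not math.isfinite(float(loss.value)):
            raise RuntimeError(
                f"training diverged at iteration {it}: loss={loss.value!r}"
            )
        loss.backward()
        grads = {k: t.grad for k, t in params_t.items() if t.grad is not None}
        adam_step(params, grads, adam_state, cfg.learning_rate, it)
        ema = ema_update(ema, params, cfg.ema_halflife_images, cfg.batch_size)
        if it % log_every == 0 or it == 1:
            history.append({"iteration": it, "loss": float(loss.value), "ema_decay": decay})

    ema_model = DenoiserModel(
        backbone_config,
        ema,
        cfg.geom,
        PreconditioningParams(cfg.sigma_data),
        norm,
        data_shape,
    )
    ema_model.history = history
    return ema_model
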