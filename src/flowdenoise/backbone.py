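"""Trainable backbones: a tiny U-Net and an MLP, in numpy.

Both take a batch of single-channel images plus a per-sample noise
conditioning scalar and return an image-shaped output.  The U-Net is fully
convolutional, so a network trained on patches can be evaluated on
full-size images.  Paper-scale configurations (128 base channels, seven
resolutions, attention) are representable in :class:`BackboneConfig` but
attention layers are not built at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["BackboneConfig", "UNetBackbone", "MLPBackbone", "build_backbone"]


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture hyperparameters.

    ``channel_multipliers`` has one entry per resolution level; spatial size
    halves between levels.  ``attention_resolutions`` is accepted for
    config round-tripping but building a network with attention is
    unsupported here.
    """

    kind: str = "unet"  # "unet" | "mlp"
    base_channels: int = 32
    channel_multipliers: tuple = (1, 2)
    attention_resolutions: tuple = ()
    dropout_prob: float = 0.0
    emb_channels: int = 64
    n_freqs: int = 8
    mlp_hidden: int = 256

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError(f"dropout_prob must be in [0, 1), got {self.dropout_prob}")
        if self.kind not in ("unet", "mlp"):
            raise ValueError(f"unknown backbone kind {self.kind!r}")


def _fourier_features(cnoise: np.ndarray, n_freqs: int) -> np.ndarray:
    """(B,) -> (B, 2*n_freqs) sinusoidal embedding with octave-spaced frequencies."""
    freqs = 2.0 ** np.arange(n_freqs)
    ang = cnoise[:, None] * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)


def _he(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class UNetBackbone:
    """Small encoder-decoder with per-level noise-embedding biases.

    Per level: two 3x3 convs (each followed by SiLU, with an embedding-
    derived per-channel bias added before the nonlinearity); 2x average-pool
    between encoder levels, nearest upsample + skip concatenation in the
    decoder.  The output conv is zero-initialized.
    """

    def __init__(self, cfg: BackboneConfig, in_channels: int = 1):
        if cfg.attention_resolutions:
            raise NotImplementedError(
                "attention layers are config-representable but not built; "
                "use attention_resolutions=()"
            )
        self.cfg = cfg
        self.in_channels = in_channels
        self.level_channels = [cfg.base_channels * m for m in cfg.channel_multipliers]

    # -- parameters ------------------------------------------------------
    def init_params(self, rng: np.random.Generator) -> Dict[str, np.ndarray]:
        cfg = self.cfg
        p: Dict[str, np.ndarray] = {}
        emb_in = 2 * cfg.n_freqs
        p["emb.w"] = _he(rng, (emb_in, cfg.emb_channels), emb_in)
        p["emb.b"] = np.zeros(cfg.emb_channels)

        def conv(name: str, cin: int, cout: int, zero: bool = False) -> None:
            if zero:
                p[f"{name}.w"] = np.zeros((cout, cin, 3, 3))
            else:
                p[f"{name}.w"] = _he(rng, (cout, cin, 3, 3), cin * 9)
            p[f"{name}.b"] = np.zeros(cout)

        def emb_proj(name: str, cout: int) -> None:
            p[f"{name}.w"] = _he(rng, (cfg.emb_channels, cout), cfg.emb_channels)
            p[f"{name}.b"] = np.zeros(cout)

        chans = self.level_channels
        cin = self.in_channels
        for lv, c in enumerate(chans):
            conv(f"enc{lv}.conv0", cin, c)
            conv(f"enc{lv}.conv1", c, c)
            emb_proj(f"enc{lv}.emb0", c)
            emb_proj(f"enc{lv}.emb1", c)
            cin = c
        for lv in range(len(chans) - 2, -1, -1):
            c = chans[lv]
            conv(f"dec{lv}.conv0", chans[lv + 1] + c, c)
            conv(f"dec{lv}.conv1", c, c)
            emb_proj(f"dec{lv}.emb0", c)
            emb_proj(f"dec{lv}.emb1", c)
        conv("out", chans[0], self.in_channels, zero=True)
        return p

    # -- forward ---------------------------------------------------------
    def forward_tensor(
        self,
        params: Dict[str, Tensor],
        x: Tensor,
        cnoise: np.ndarray,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        cfg = self.cfg
        ff = _fourier_features(np.asarray(cnoise, dtype=float), cfg.n_freqs)
        emb = ad.silu(ad.add(ad.matmul(Tensor(ff), params["emb.w"]), params["emb.b"]))

        def block(name: str, h: Tensor) -> Tensor:
            for k in (0, 1):
                h = ad.conv3x3(h, params[f"{name}.conv{k}.w"], params[f"{name}.conv{k}.b"])
                bias = ad.add(
                    ad.matmul(emb, params[f"{name}.emb{k}.w"]), params[f"{name}.emb{k}.b"]
                )
                b, c = bias.shape
                h = ad.silu(ad.add(h, ad.reshape(bias, (b, c, 1, 1))))
                if train and cfg.dropout_prob > 0.0:
                    if rng is None:
                        raise ValueError("dropout requires an rng in training mode")
                    h = ad.dropout(h, cfg.dropout_prob, rng)
            return h

        skips = []
        h = x
        n_levels = len(self.level_channels)
        for lv in range(n_levels):
            h = block(f"enc{lv}", h)
            if lv < n_levels - 1:
                skips.append(h)
                h = ad.avgpool2(h)
        for lv in range(n_levels - 2, -1, -1):
            h = ad.upsample2(h)
            h = ad.concat_channels(h, skips.pop())
            h = block(f"dec{lv}", h)
        return ad.conv3x3(h, params["out.w"], params["out.b"])

    def __call__(
        self, params: Dict[str, np.ndarray], x: np.ndarray, cnoise: np.ndarray
    ) -> np.ndarray:
        pt = {k: Tensor(v) for k, v in params.items()}
        return self.forward_tensor(pt, Tensor(x), cnoise).value


class MLPBackbone:
    """Flat two-hidden-layer net; only valid at one input size.

    Useful at very small patch sizes where a global view of the image is
    required and convolutions buy nothing.
    """

    def __init__(self, cfg: BackboneConfig, in_channels: int = 1, data_shape: tuple = (8, 8)):
        self.cfg = cfg
        self.in_channels = in_channels
        self.data_shape = tuple(data_shape)
        self.n_in = in_channels * int(np.prod(data_shape))

    def init_params(self, rng: np.random.Generator) -> Dict[str, np.ndarray]:
        cfg = self.cfg
        h = cfg.mlp_hidden
        emb_in = 2 * cfg.n_freqs
        p = {
            "emb.w": _he(rng, (emb_in, cfg.emb_channels), emb_in),
            "emb.b": np.zeros(cfg.emb_channels),
            "fc1.w": _he(rng, (self.n_in + cfg.emb_channels, h), self.n_in + cfg.emb_channels),
            "fc1.b": np.zeros(h),
            "fc2.w": _he(rng, (h, h), h),
            "fc2.b": np.zeros(h),
            "out.w": np.zeros((h, self.n_in)),
            "out.b": np.zeros(self.n_in),
        }
        return p

    def forward_tensor(
        self,
        params: Dict[str, Tensor],
        x: Tensor,
        cnoise: np.ndarray,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        cfg = self.cfg
        shape = x.shape
        if int(np.prod(shape[1:])) != self.n_in:
            raise ValueError(f"MLP backbone built for {self.n_in} inputs, got shape {shape}")
        B = shape[0]
        ff = _fourier_features(np.asarray(cnoise, dtype=float), cfg.n_freqs)
        emb = ad.silu(ad.add(ad.matmul(Tensor(ff), params["emb.w"]), params["emb.b"]))
        flat = ad.reshape(x, (B, self.n_in))
        h = ad.concat_channels(flat, emb)  # axis 1 concat works for 2-D too
        h = ad.silu(ad.add(ad.matmul(h, params["fc1.w"]), params["fc1.b"]))
        if train and cfg.dropout_prob > 0.0:
            if rng is None:
                raise ValueError("dropout requires an rng in training mode")
            h = ad.dropout(h, cfg.dropout_prob, rng)
        h = ad.silu(ad.add(ad.matmul(h, params["fc2.w"]), params["fc2.b"]))
        out = ad.add(ad.matmul(h, params["out.w"]), params["out.b"])
        return ad.reshape(out, shape)

    def __call__(
        self, params: Dict[str, np.ndarray], x: np.ndarray, cnoise: np.ndarray
    ) -> np.ndarray:
        pt = {k: Tensor(v) for k, v in params.items()}
        return self.forward_tensor(pt, Tensor(x), cnoise).value


def build_backbone(cfg: BackboneConfig, in_channels: int = 1, data_shape: tuple = (8, 8)):
    if cfg.kind == "unet":
        return UNetBackbone(cfg, in_channels)
    return MLPBackbone(cfg, in_channels, data_shape)
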