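"""Denoiser contract and EDM-style preconditioning.

Anything with a ``denoise(x, sigma) -> x_hat`` method approximating the
posterior mean ``E[y | x at scale sigma]`` can drive the sampler.  Two
implementations live here:

* :class:`DenoiserModel` — a trainable backbone wrapped in the standard
  preconditioning ``D(x; s) = c_skip(s) x + c_out(s) F(c_in(s) x, c_noise(s))``,
* :class:`AnalyticDenoiser` — the exact posterior mean for a discrete
  dataset, backed by the field oracle; no network, used for testing and for
  oracle-driven sampling.

``field_from_denoiser`` converts either into the ODE field
``(x - D(x; sigma)) / sigma`` that plays ``f*/sqrt(D) * dr = f* dt``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Dict, Protocol, Sequence

import numpy as np

from .backbone import BackboneConfig, build_backbone
from .pfgmpp import (
    AugmentedState,
    GeometryConfig,
    INFINITE,
    oracle_denoise,
    sigma_equivalent,
)

__all__ = [
    "PreconditioningParams",
    "Denoiser",
    "DenoiserModel",
    "AnalyticDenoiser",
    "field_from_denoiser",
    "HUNormalization",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1


class Denoiser(Protocol):
    def denoise(self, x: np.ndarray, sigma: float) -> np.ndarray: ...


@dataclass(frozen=True)
class PreconditioningParams:
    """Per-sigma input/output scalings.

    ``c_skip -> 1`` and ``c_out -> 0`` as ``sigma -> 0``, so the wrapper
    degenerates to the identity at vanishing noise.
    """

    sigma_data: float = 0.5

    def c_skip(self, sigma: float) -> float:
        sd2 = self.sigma_data**2
        return sd2 / (sigma**2 + sd2)

    def c_out(self, sigma: float) -> float:
        return sigma * self.sigma_data / math.sqrt(sigma**2 + self.sigma_data**2)

    def c_in(self, sigma: float) -> float:
        return 1.0 / math.sqrt(sigma**2 + self.sigma_data**2)

    def c_noise(self, sigma: float) -> float:
        return 0.25 * math.log(sigma)

    def loss_weight(self, sigma: float) -> float:
        """lambda(sigma) = (sigma^2 + sigma_data^2) / (sigma * sigma_data)^2 = 1 / c_out^2."""
        return (sigma**2 + self.sigma_data**2) / (sigma * self.sigma_data) ** 2


@dataclass(frozen=True)
class HUNormalization:
    """Affine map between HU and the network's roughly-unit working range."""

    offset: float = 0.0
    scale: float = 1.0

    def to_normalized(self, hu: np.ndarray) -> np.ndarray:
        return (np.asarray(hu, dtype=float) - self.offset) / self.scale

    def to_hu(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) * self.scale + self.offset


class DenoiserModel:
    """Preconditioned trainable denoiser.

    Operates in normalized units; HU conversion is the caller's job via
    ``normalization``.  ``geom`` records the augmented dimension the model
    was trained under, so checkpoints can refuse mismatched sampling
    configurations.
    """

    def __init__(
        self,
        backbone_config: BackboneConfig,
        params: Dict[str, np.ndarray],
        geom: GeometryConfig,
        precond: PreconditioningParams = PreconditioningParams(),
        normalization: HUNormalization = HUNormalization(),
        data_shape: tuple = (8, 8),
    ):
        self.backbone_config = backbone_config
        self.backbone = build_backbone(backbone_config, data_shape=data_shape)
        self.params = params
        self.geom = geom
        self.precond = precond
        self.normalization = normalization
        self.data_shape = tuple(data_shape)
        self.n_calls = 0  # network evaluation counter (NFE bookkeeping)

    def denoise(self, x: np.ndarray, sigma: float) -> np.ndarray:
        if sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {sigma}")
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 2
        if squeeze:
            xb = x[None, None]
        elif x.ndim == 3:
            xb = x[:, None]
        else:
            xb = x
        p = self.precond
        cnoise = np.full(xb.shape[0], p.c_noise(sigma))
        f = self.backbone(self.params, p.c_in(sigma) * xb, cnoise)
        self.n_calls += 1
        out = p.c_skip(sigma) * xb + p.c_out(sigma) * f
        if squeeze:
            return out[0, 0]
        if x.ndim == 3:
            return out[:, 0]
        return out


class AnalyticDenoiser:
    """Exact posterior-mean denoiser for a discrete dataset (the oracle)."""

    def __init__(self, dataset: Sequence[np.ndarray], geom: GeometryConfig):
        self.dataset = [np.asarray(y, dtype=float) for y in dataset]
        self.geom = geom
        self.n_calls = 0

    def denoise(self, x: np.ndarray, sigma: float) -> np.ndarray:
        self.n_calls += 1
        return oracle_denoise(x, sigma, self.dataset, self.geom)


def field_from_denoiser(
    model: Denoiser, state: AugmentedState, geom: GeometryConfig
) -> np.ndarray:
    """ODE field ``(x - D(x; sigma)) / sigma`` with ``sigma = r / sqrt(D)``.

    Exact algebraic inverse of the denoiser contract: reconstructing
    ``D = x - sigma * field`` returns the original estimate.
    """
    if state.r <= 0:
        raise ValueError(f"field requires r > 0, got {state.r}")
    sigma = sigma_equivalent(state.r, geom)
    return (state.x - model.denoise(state.x, sigma)) / sigma


# -- checkpoint I/O ------------------------------------------------------

def save_checkpoint(path: str, model: DenoiserModel) -> None:
    """Write config + weights + normalization as a single ``.npz``."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "backbone_config": asdict(model.backbone_config),
        "geom": {
            "data_dim": model.geom.data_dim,
            "aug_dim": "inf" if model.geom.is_infinite else int(model.geom.aug_dim),
        },
        "precond": asdict(model.precond),
        "normalization": asdict(model.normalization),
        "data_shape": list(model.data_shape),
    }
    arrays = {f"param.{k}": v for k, v in model.params.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str) -> DenoiserModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['format_version']}")
        params = {k[len("param."):]: z[k] for k in z.files if k.startswith("param.")}
    g = meta["geom"]
    geom = GeometryConfig(g["data_dim"], INFINITE if g["aug_dim"] == "inf" else g["aug_dim"])
    bc = meta["backbone_config"]
    bc["channel_multipliers"] = tuple(bc["channel_multipliers"])
    bc["attention_resolutions"] = tuple(bc["attention_resolutions"])
    return DenoiserModel(
        BackboneConfig(**bc),
        params,
        geom,
        PreconditioningParams(**meta["precond"]),
        HUNormalization(**meta["normalization"]),
        tuple(meta["data_shape"]),
    )
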