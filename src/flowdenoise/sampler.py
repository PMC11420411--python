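"""Deterministic ODE sampler with hijacking and data-consistency mixing.

The schedule and Heun integrator follow the EDM construction with
``sigma(t) = t``; the augmented-dimension case rides on the same code via
the ``r = sigma * sqrt(D)`` change of variables, differing only in the
prior sample.  Two modifications turn the unconditional generator into a
single-step denoiser:

* **hijacking** — start at step ``tau`` by injecting the condition image
  ``x_tau = c`` (unscaled, no added noise) instead of a prior draw;
* **regularization** — after every solver step mix the iterate with the
  condition, ``x <- w x + (1 - w) c``, the identity data-consistency map.

With ``tau = T - 1`` the single remaining step has ``t_next = 0``, the
second-order correction is skipped, and exactly one network evaluation is
spent (NFE = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .denoiser import Denoiser
from .pfgmpp import GeometryConfig, sample_prior, sigma_to_r

__all__ = [
    "NoiseSchedule",
    "SamplerConfig",
    "SamplingResult",
    "make_schedule",
    "heun_step",
    "sample_unconditional",
    "denoise_posterior",
    "count_nfe",
]

MODES = ("posterior", "unconditional", "hijack_only", "regularize_only")


@dataclass(frozen=True)
class NoiseSchedule:
    """Discrete noise scales ``t_0 = sigma_max > ... > t_{T-1} = sigma_min > t_T = 0``."""

    T: int
    sigma_min: float
    sigma_max: float
    rho: float
    t: np.ndarray = field(repr=False)

    def prior_r_max(self, geom: GeometryConfig) -> float:
        """Prior scale: ``sigma_max`` itself, or ``sigma_max * sqrt(D)`` when finite."""
        return self.sigma_max if geom.is_infinite else sigma_to_r(self.sigma_max, geom)


def make_schedule(
    T: int, sigma_min: float = 0.002, sigma_max: float = 80.0, rho: float = 7.0
) -> NoiseSchedule:
    """Power-law interpolation between sigma_max and sigma_min, terminated at 0.

    ``t_i = (sigma_max^(1/rho) + i/(T-1) (sigma_min^(1/rho) - sigma_max^(1/rho)))^rho``
    for ``i < T``; ``t_T = 0``.  ``T = 1`` degenerates to ``(sigma_max, 0)``.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if not 0 < sigma_min < sigma_max:
        raise ValueError(f"need 0 < sigma_min < sigma_max, got {sigma_min}, {sigma_max}")
    if T == 1:
        t = np.array([sigma_max, 0.0])
    else:
        i = np.arange(T)
        lo, hi = sigma_min ** (1.0 / rho), sigma_max ** (1.0 / rho)
        t = np.append((hi + i / (T - 1) * (lo - hi)) ** rho, 0.0)
    return NoiseSchedule(T=T, sigma_min=sigma_min, sigma_max=sigma_max, rho=rho, t=t)


@dataclass(frozen=True)
class SamplerConfig:
    schedule: NoiseSchedule
    geom: GeometryConfig
    tau: int = 0
    w: float = 0.5
    mode: str = "posterior"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0 <= self.tau < self.schedule.T:
            raise ValueError(f"tau must be in [0, T), got {self.tau}")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must be in [0, 1], got {self.w}")


@dataclass
class SamplingResult:
    output: np.ndarray
    nfe: int
    trajectory: Optional[List[np.ndarray]] = None


def heun_step(
    model: Denoiser, x: np.ndarray, t_cur: float, t_next: float
) -> tuple[np.ndarray, int]:
    """One solver step from ``t_cur`` to ``t_next``.

    Euler predictor with ``d = (x - D(x; t)) / t``; when ``t_next > 0`` a
    trapezoidal corrector re-evaluates the field at the predicted point
    (2 evaluations), otherwise Euler only (1 evaluation).
    """
    if t_cur <= 0:
        raise ValueError(f"t_cur must be > 0, got {t_cur}")
    if t_next == t_cur:
        return x, 0
    d = (x - model.denoise(x, t_cur)) / t_cur
    x_next = x + (t_next - t_cur) * d
    if t_next > 0:
        d2 = (x_next - model.denoise(x_next, t_next)) / t_next
        x_next = x + (t_next - t_cur) * 0.5 * (d + d2)
        return x_next, 2
    return x_next, 1


def _integrate(
    model: Denoiser,
    x: np.ndarray,
    cfg: SamplerConfig,
    start: int,
    condition: Optional[np.ndarray],
    mix: bool,
    record: bool,
) -> SamplingResult:
    t = cfg.schedule.t
    nfe = 0
    traj: Optional[List[np.ndarray]] = [np.array(x)] if record else None
    for i in range(start, cfg.schedule.T):
        x, inc = heun_step(model, x, t[i], t[i + 1])
        nfe += inc
        if mix and condition is not None:
            x = cfg.w * x + (1.0 - cfg.w) * condition
        if record:
            traj.append(np.array(x))
    return SamplingResult(output=x, nfe=nfe, trajectory=traj)


def sample_unconditional(
    model: Denoiser,
    cfg: SamplerConfig,
    shape: tuple,
    rng: np.random.Generator,
    record_trajectory: bool = False,
) -> SamplingResult:
    """Generate from the prior: all ``T`` steps, ``nfe = 2T - 1``."""
    if cfg.mode != "unconditional":
        raise ValueError(f"mode must be 'unconditional', got {cfg.mode!r}")
    x0 = sample_prior(cfg.schedule.prior_r_max(cfg.geom), cfg.geom, rng, shape)
    return _integrate(model, x0, cfg, 0, None, False, record_trajectory)


def denoise_posterior(
    model: Denoiser,
    c: np.ndarray,
    cfg: SamplerConfig,
    rng: Optional[np.random.Generator] = None,
    record_trajectory: bool = False,
) -> SamplingResult:
    """Posterior sampling by hijacking and/or regularization.

    ``posterior``: inject ``x_tau = c``, integrate ``tau .. T-1``, mix with
    weight ``w`` after every step.  ``hijack_only``: same but without
    mixing (equivalent to ``w = 1``).  ``regularize_only``: start from a
    prior draw (needs ``rng``) at step 0 and mix after every step.
    Posterior and hijack modes are pure functions of ``(model, c, cfg)``.
    """
    if cfg.mode not in ("posterior", "hijack_only", "regularize_only"):
        raise ValueError(f"invalid mode for denoise_posterior: {cfg.mode!r}")
    c = np.asarray(c, dtype=float)
    if c.size != cfg.geom.data_dim:
        raise ValueError(
            f"condition has {c.size} pixels, geometry expects {cfg.geom.data_dim}"
        )
    if cfg.mode == "regularize_only":
        if rng is None:
            raise ValueError("regularize_only starts from a prior sample; rng required")
        x0 = sample_prior(cfg.schedule.prior_r_max(cfg.geom), cfg.geom, rng, c.shape)
        return _integrate(model, x0, cfg, 0, c, True, record_trajectory)
    mix = cfg.mode == "posterior"
    return _integrate(model, np.array(c), cfg, cfg.tau, c, mix, record_trajectory)


def count_nfe(cfg: SamplerConfig) -> int:
    """Closed-form network-evaluation count for a configuration."""
    t = cfg.schedule.t
    start = 0 if cfg.mode in ("unconditional", "regularize_only") else cfg.tau
    return int(sum(2 if t[i + 1] > 0 else 1 for i in range(start, cfg.schedule.T)))
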