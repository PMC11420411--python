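"""Configuration, manifests and the command-line interface.

One YAML config file drives every subcommand; CLI flags override config
keys.  Every run writes a ``manifest.json`` next to its outputs recording
the effective config, derived seeds, checksums, NFE counts and timings, so
any output is reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Optional

import click
import numpy as np
import yaml

from . import __version__
from .denoiser import load_checkpoint, save_checkpoint
from .io import DEFAULT_WINDOW, load_hu, load_png16, save_hu, save_windowed_png
from .metrics import GridSearchSpec, evaluate_pairs, grid_search
from .pfgmpp import GeometryConfig, INFINITE, NoiseScaleDistribution
from .sampler import SamplerConfig, count_nfe, denoise_posterior, make_schedule, sample_unconditional
from .synthetic_ct import DegradationConfig, default_head_spec, make_paired_eval_set
from .training import TrainingConfig, train
from .backbone import BackboneConfig

# stable per-component seed salts (derived from the global seed)
_SEED_SALTS = {"data": 101, "train": 211, "sample": 307, "denoise": 401}


def derive_seed(global_seed: int, component: str) -> int:
    ss = np.random.SeedSequence([int(global_seed), _SEED_SALTS[component]])
    return int(ss.generate_state(1)[0])


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, payload: dict) -> None:
    files = sorted(p for p in out_dir.iterdir() if p.is_file() and p.name != "manifest.json")
    payload["version"] = __version__
    payload["checksums"] = {p.name: _sha256(p) for p in files}
    (out_dir / "manifest.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def _geometry(cfg: dict) -> GeometryConfig:
    g = cfg.get("geometry", {})
    aug = g.get("aug_dim", "inf")
    aug_dim = INFINITE if aug in ("inf", "INFINITE", None) else int(aug)
    n = g.get("data_dim")
    if n is None:
        size = cfg.get("training", {}).get("patch_size", cfg.get("data", {}).get("image_size", 64))
        n = int(size) ** 2
    return GeometryConfig(data_dim=int(n), aug_dim=aug_dim)


def _prepare_out(out_dir: Path, force: bool) -> None:
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise click.ClickException(
            f"output directory {out_dir} is not empty; pass --force to overwrite"
        )
    out_dir.mkdir(parents=True, exist_ok=True)


def _load_image(path: Path) -> np.ndarray:
    if path.suffix == ".npy":
        return load_hu(path)
    if path.suffix == ".png":
        return load_png16(path)
    raise click.ClickException(f"unsupported image format: {path}")


# -- operations (importable without the CLI) -----------------------------

def run_make_data(config: dict, out_dir: Path, force: bool = False) -> dict:
    _prepare_out(out_dir, force)
    d = config.get("data", {})
    seed = derive_seed(config.get("seed", 0), "data")
    spec = default_head_spec(int(d.get("image_size", 64)))
    degr = DegradationConfig(
        noise_sd=float(d.get("noise_sd", 50.0)),
        correlation_length=float(d.get("correlation_length", 0.0)),
        seed=seed,
    )
    n_train = int(d.get("n_images", 8))
    n_eval = int(d.get("n_eval_pairs", 4))
    clean, _ = make_paired_eval_set(n_train, spec, degr, seed=seed)
    eval_clean, eval_noisy = make_paired_eval_set(n_eval, spec, degr, seed=seed + 1)
    window = tuple(config.get("display_window", DEFAULT_WINDOW))
    for i, img in enumerate(clean):
        save_hu(out_dir / f"clean_{i:03d}.npy", img)
        save_windowed_png(out_dir / f"clean_{i:03d}.png", img, window)
    for i, (y, c) in enumerate(zip(eval_clean, eval_noisy)):
        save_hu(out_dir / f"eval_clean_{i:03d}.npy", y)
        save_hu(out_dir / f"eval_noisy_{i:03d}.npy", c)
    manifest = {
        "command": "make-data",
        "config": config,
        "seeds": {"data": seed, "eval": seed + 1},
        "n_train": n_train,
        "n_eval_pairs": n_eval,
    }
    _write_manifest(out_dir, manifest)
    return manifest


def run_train(config: dict, data_dir: Path, out_dir: Path, force: bool = False) -> dict:
    _prepare_out(out_dir, force)
    tcfg_d = dict(config.get("training", {}))
    geom = _geometry(config)
    clean_paths = sorted(data_dir.glob("clean_*.npy"))
    if not clean_paths:
        raise click.ClickException(f"no clean_*.npy images found in {data_dir}")
    # unsupervised by construction: only clean images are ever loaded
    dataset = [load_hu(p) for p in clean_paths]
    seed = derive_seed(config.get("seed", 0), "train")
    scale_d = tcfg_d.pop("scale_dist", {})
    backbone_d = dict(config.get("backbone", {}))
    for key in ("channel_multipliers", "attention_resolutions"):
        if key in backbone_d:
            backbone_d[key] = tuple(backbone_d[key])
    tcfg = TrainingConfig(
        geom=geom,
        scale_dist=NoiseScaleDistribution(**scale_d),
        seed=seed,
        **tcfg_d,
    )
    t0 = time.time()
    model = train(dataset, tcfg, BackboneConfig(**backbone_d) if backbone_d else None)
    elapsed = time.time() - t0
    save_checkpoint(out_dir / "checkpoint.npz", model)
    with open(out_dir / "train_log.jsonl", "w") as fh:
        for rec in model.history:
            fh.write(json.dumps(rec) + "\n")
    manifest = {
        "command": "train",
        "config": config,
        "seeds": {"train": seed},
        "n_images": len(dataset),
        "elapsed_s": elapsed,
    }
    _write_manifest(out_dir, manifest)
    return manifest


def _sampler_config(config: dict, geom: GeometryConfig, mode: str) -> SamplerConfig:
    s = config.get("sampler", {})
    T = int(s.get("T", 8))
    schedule = make_schedule(
        T,
        float(s.get("sigma_min", 0.002)),
        float(s.get("sigma_max", 80.0)),
        float(s.get("rho", 7.0)),
    )
    tau = s.get("tau")
    tau = T - 1 if tau is None else int(tau)
    return SamplerConfig(
        schedule=schedule, geom=geom, tau=tau, w=float(s.get("w", 0.5)), mode=mode
    )


def run_denoise(
    config: dict, checkpoint: Path, inputs: list[Path], out_dir: Path, force: bool = False
) -> dict:
    _prepare_out(out_dir, force)
    model = load_checkpoint(checkpoint)
    cfg_aug = config.get("geometry", {}).get("aug_dim")
    if cfg_aug is not None:
        want = INFINITE if cfg_aug == "inf" else int(cfg_aug)
        if want != model.geom.aug_dim:
            raise click.ClickException(
                f"checkpoint aug_dim {model.geom.aug_dim} != config aug_dim {want}"
            )
    window = tuple(config.get("display_window", DEFAULT_WINDOW))
    sigma_log = []
    total_nfe = 0
    t0 = time.time()
    for path in inputs:
        c_hu = _load_image(path)
        geom = GeometryConfig(c_hu.size, model.geom.aug_dim)
        scfg = _sampler_config(config, geom, "posterior")
        c = model.normalization.to_normalized(c_hu)
        result = denoise_posterior(model, c, scfg)
        out_hu = model.normalization.to_hu(result.output)
        save_hu(out_dir / f"{path.stem}_denoised.npy", out_hu)
        save_windowed_png(out_dir / f"{path.stem}_denoised.png", out_hu, window)
        total_nfe += result.nfe
        sigma_log = [float(t) for t in scfg.schedule.t]
    manifest = {
        "command": "denoise",
        "config": config,
        "checkpoint": str(checkpoint),
        "inputs": [str(p) for p in inputs],
        "nfe_total": total_nfe,
        "nfe_expected_per_image": count_nfe(scfg),
        "schedule_t": sigma_log,
        "elapsed_s": time.time() - t0,
    }
    _write_manifest(out_dir, manifest)
    return manifest


def run_sample(
    config: dict, checkpoint: Path, n_samples: int, out_dir: Path, force: bool = False
) -> dict:
    _prepare_out(out_dir, force)
    model = load_checkpoint(checkpoint)
    seed = derive_seed(config.get("seed", 0), "sample")
    rng = np.random.default_rng(seed)
    shape = model.data_shape
    geom = GeometryConfig(int(np.prod(shape)), model.geom.aug_dim)
    scfg = _sampler_config(config, geom, "unconditional")
    window = tuple(config.get("display_window", DEFAULT_WINDOW))
    nfes = []
    for i in range(n_samples):
        res = sample_unconditional(model, scfg, shape, rng)
        hu = model.normalization.to_hu(res.output)
        save_hu(out_dir / f"sample_{i:03d}.npy", hu)
        save_windowed_png(out_dir / f"sample_{i:03d}.png", hu, window)
        nfes.append(res.nfe)
    manifest = {
        "command": "sample",
        "config": config,
        "seeds": {"sample": seed},
        "nfe_per_sample": nfes,
        "schedule_t": [float(t) for t in scfg.schedule.t],
    }
    _write_manifest(out_dir, manifest)
    return manifest


def run_evaluate(
    estimates: list[Path], references: list[Path], out_dir: Path, force: bool = False,
    data_range: Optional[float] = None,
) -> dict:
    _prepare_out(out_dir, force)
    est = [_load_image(p) for p in estimates]
    ref = [_load_image(p) for p in references]
    report = evaluate_pairs(est, ref, data_range=data_range)
    rows = ["image\tpsnr_db\tssim"]
    for p, ps, ss in zip(estimates, report.psnr_values, report.ssim_values):
        rows.append(f"{p.name}\t{ps:.4f}\t{ss:.6f}")
    rows.append(
        f"aggregate\t{report.psnr_mean:.4f}±{report.psnr_sd:.4f}"
        f"\t{report.ssim_mean:.6f}±{report.ssim_sd:.6f}"
    )
    (out_dir / "metrics.tsv").write_text("\n".join(rows) + "\n")
    (out_dir / "metrics.json").write_text(json.dumps(report.summary(), indent=2))
    manifest = {"command": "evaluate", "n_pairs": len(est), "summary": report.summary()}
    _write_manifest(out_dir, manifest)
    return manifest


def run_gridsearch(
    config: dict, checkpoint: Path, data_dir: Path, out_dir: Path, force: bool = False
) -> dict:
    _prepare_out(out_dir, force)
    model = load_checkpoint(checkpoint)
    clean = [load_hu(p) for p in sorted(data_dir.glob("eval_clean_*.npy"))]
    noisy = [load_hu(p) for p in sorted(data_dir.glob("eval_noisy_*.npy"))]
    if not clean:
        raise click.ClickException(f"no eval pairs in {data_dir}")
    m = config.get("metrics", {})
    spec = GridSearchSpec(
        T_grid=tuple(m.get("T_grid", (4, 8, 16, 32, 64))),
        w_grid=tuple(m.get("w_grid", (0.5, 0.6, 0.7, 0.8, 0.9, 1.0))),
        criterion=m.get("criterion", "psnr"),
    )
    norm = model.normalization
    pairs = (
        [norm.to_normalized(y) for y in clean],
        [norm.to_normalized(c) for c in noisy],
    )
    s = config.get("sampler", {})
    geom = GeometryConfig(clean[0].size, model.geom.aug_dim)
    best_cfg, table = grid_search(
        model, pairs, spec, geom,
        sigma_min=float(s.get("sigma_min", 0.002)),
        sigma_max=float(s.get("sigma_max", 80.0)),
        rho=float(s.get("rho", 7.0)),
    )
    lines = ["T\tw\tmean\tsd\tcriterion"]
    for row in table:
        lines.append(f"{row['T']}\t{row['w']}\t{row['mean']:.6f}\t{row['sd']:.6f}\t{row['criterion']}")
    (out_dir / "gridsearch.tsv").write_text("\n".join(lines) + "\n")
    best = {"T": best_cfg.schedule.T, "tau": best_cfg.tau, "w": best_cfg.w,
            "criterion": spec.criterion}
    (out_dir / "best.yaml").write_text(yaml.safe_dump(best))
    manifest = {"command": "gridsearch", "config": config, "best": best,
                "table_rows": len(table)}
    _write_manifest(out_dir, manifest)
    return manifest


# -- CLI -----------------------------------------------------------------

@click.group()
@click.version_option(__version__)
def cli() -> None:
    """Unsupervised Poisson-flow CT denoising toolkit."""


def _cfg_opt(fn):
    fn = click.option("--config", "config_path", type=click.Path(exists=True), default=None,
                      help="YAML config file.")(fn)
    fn = click.option("--seed", type=int, default=None, help="Override global seed.")(fn)
    return fn


def _load(config_path: Optional[str], seed: Optional[int]) -> dict:
    config = load_config(config_path) if config_path else {}
    if seed is not None:
        config["seed"] = seed
    config.setdefault("seed", 0)
    return config


@cli.command("make-data")
@_cfg_opt
@click.option("--out", required=True, type=click.Path())
@click.option("--force", is_flag=True)
def cli_make_data(config_path, seed, out, force):
    """Generate phantom training images and paired evaluation data."""
    run_make_data(_load(config_path, seed), Path(out), force)


@cli.command("train")
@_cfg_opt
@click.option("--data", "data_dir", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
@click.option("--force", is_flag=True)
def cli_train(config_path, seed, data_dir, out, force):
    """Train the unconditional denoiser on clean images only."""
    run_train(_load(config_path, seed), Path(data_dir), Path(out), force)


@cli.command("denoise")
@_cfg_opt
@click.option("--checkpoint", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
@click.option("--force", is_flag=True)
@click.argument("inputs", nargs=-1, required=True, type=click.Path(exists=True))
def cli_denoise(config_path, seed, checkpoint, out, force, inputs):
    """Single-step posterior denoising of one or more images."""
    paths: list[Path] = []
    for item in inputs:
        p = Path(item)
        paths.extend(sorted(p.glob("*.npy")) if p.is_dir() else [p])
    run_denoise(_load(config_path, seed), Path(checkpoint), paths, Path(out), force)


@cli.command("sample")
@_cfg_opt
@click.option("--checkpoint", required=True, type=click.Path(exists=True))
@click.option("--n", "n_samples", type=int, default=4)
@click.option("--out", required=True, type=click.Path())
@click.option("--force", is_flag=True)
def cli_sample(config_path, seed, checkpoint, n_samples, out, force):
    """Unconditional generation from the trained prior."""
    run_sample(_load(config_path, seed), Path(checkpoint), n_samples, Path(out), force)


@cli.command("evaluate")
@click.option("--estimates", required=True, type=click.Path(exists=True))
@click.option("--references", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
@click.option("--force", is_flag=True)
@click.option("--data-range", type=float, default=None)
def cli_evaluate(estimates, references, out, force, data_range):
    """PSNR/SSIM report for paired estimate/reference directories."""
    est = sorted(Path(estimates).glob("*.npy"))
    ref = sorted(Path(references).glob("*.npy"))
    run_evaluate(est, ref, Path(out), force, data_range)


@cli.command("gridsearch")
@_cfg_opt
@click.option("--checkpoint", required=True, type=click.Path(exists=True))
@click.option("--data", "data_dir", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
@click.option("--force", is_flag=True)
def cli_gridsearch(config_path, seed, checkpoint, data_dir, out, force):
    """Sweep (T, w) with tau = T - 1 and report the best configuration."""
    run_gridsearch(_load(config_path, seed), Path(checkpoint), Path(data_dir), Path(out), force)


if __name__ == "__main__":  # pragma: no cover
    cli()
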