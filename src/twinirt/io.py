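"""Plain-text IO: datasets, item banks, posterior draws, configs, manifests.

Datasets are delimited tables with one row per twin (family_id, twin,
zygosity, moderator, item_1..item_K; missing values as empty fields); item
banks are three-column tables; posterior draws a long table (chain,
iteration, parameter, value).  A YAML sidecar records the generating
scenario configuration including the seed, and run manifests record seeds,
config hashes and output checksums so any run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .fit import McmcConfig, PosteriorSamples, PriorSpec
from .model import ItemBank
from .simulate import ScenarioConfig, TwinData

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_bank",
    "read_bank",
    "write_posterior",
    "read_posterior",
    "write_summary",
    "load_run_config",
    "write_manifest",
    "file_sha256",
]


def write_dataset(data: TwinData, directory, stem: str = "dataset", include_latent: bool = False) -> dict:
    """Write obs (+ bank, config, optionally latent truth) under ``directory``.

    Returns a mapping of logical names to the files written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {"obs": directory / f"{stem}.csv"}
    data.obs.to_csv(paths["obs"], index=False)
    if data.bank is not None:
        paths["bank"] = directory / f"{stem}_bank.csv"
        write_bank(data.bank, paths["bank"])
    if include_latent and data.latent is not None:
        paths["latent"] = directory / f"{stem}_latent.csv"
        data.latent.to_csv(paths["latent"], index=False)
    if data.config is not None:
        paths["meta"] = directory / f"{stem}_meta.yaml"
        with open(paths["meta"], "w") as fh:
            yaml.safe_dump({"scenario": data.config.to_dict()}, fh, sort_keys=True)
    return paths


def read_dataset(obs_path, bank_path=None, meta_path=None) -> TwinData:
    obs = pd.read_csv(obs_path)
    bank = read_bank(bank_path) if bank_path else None
    config = None
    if meta_path:
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh)
        config = ScenarioConfig.from_dict(meta["scenario"])
    return TwinData(obs=obs, bank=bank, config=config)


def write_bank(bank: ItemBank, path) -> None:
    bank.to_frame().to_csv(path, index=False)


def read_bank(path) -> ItemBank:
    return ItemBank.from_frame(pd.read_csv(path))


def write_posterior(posterior: PosteriorSamples, path) -> None:
    posterior.to_frame().to_csv(path, index=False)


def read_posterior(path) -> PosteriorSamples:
    return PosteriorSamples.from_frame(pd.read_csv(path))


def write_summary(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path)


def load_run_config(path) -> dict:
    """Read a YAML run config with optional scenario/priors/mcmc sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    if "scenario" in raw:
        out["scenario"] = ScenarioConfig.from_dict(raw["scenario"])
    if "priors" in raw:
        out["priors"] = PriorSpec(**raw["priors"])
    if "mcmc" in raw:
        out["mcmc"] = McmcConfig(**raw["mcmc"])
    return out


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(directory, seed, config: Optional[dict] = None, outputs: Optional[dict] = None) -> Path:
    """Record seed, config hash and per-file checksums for a run."""
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    config = config or {}
    cfg_text = yaml.safe_dump(config, sort_keys=True)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "timestamp": pd.Timestamp.now().isoformat(),
        "outputs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in (outputs or {}).items()
        },
    }
    path = directory / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path
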