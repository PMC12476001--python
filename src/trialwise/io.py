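"""File formats and configuration.

Trial tables travel as CSV with header ``participant, trial, block,
cue, paired, amplitude`` (an empty amplitude cell marks a missing
trial).  Posterior draws persist as a single CSV (chain, draw, one
column per flattened parameter) with a JSON sidecar carrying model tag,
seed, sampler settings and the configuration hash, and reload
bit-identically.  Pipeline configuration is a YAML mapping validated
against a documented key set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import BLOCKS, CUES
from .inference import ModelPosterior, SamplerConfig
from .hmc import ChainStats

TRIAL_COLUMNS = ["participant", "trial", "block", "cue", "paired", "amplitude"]


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial table CSV.

    Empty amplitude cells become missing trials.  Unknown cue/block
    labels and duplicated (participant, trial) keys are rejected with
    the offending line numbers (1-based, counting the header as line 1).
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in TRIAL_COLUMNS[:-1]:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if "amplitude" not in df.columns:
        df["amplitude"] = np.nan
    lines = df.index.to_numpy() + 2  # header is line 1
    bad_cue = ~df["cue"].isin(CUES)
    if bad_cue.any():
        where = ", ".join(map(str, lines[bad_cue][:5]))
        raise ValueError(f"{path}: unknown cue label(s) at line(s) {where}")
    bad_block = ~df["block"].isin(BLOCKS)
    if bad_block.any():
        where = ", ".join(map(str, lines[bad_block][:5]))
        raise ValueError(f"{path}: unknown block label(s) at line(s) {where}")
    dup = df.duplicated(subset=["participant", "trial"], keep="first")
    if dup.any():
        where = ", ".join(map(str, lines[dup][:5]))
        raise ValueError(f"{path}: duplicate (participant, trial) at line(s) {where}")
    df["participant"] = df["participant"].astype(int)
    df["trial"] = df["trial"].astype(int)
    df["paired"] = df["paired"].astype(int)
    df["amplitude"] = pd.to_numeric(df["amplitude"], errors="raise")
    return df[TRIAL_COLUMNS]


def write_trial_table(table: pd.DataFrame, path,
                      config_hash: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        table[TRIAL_COLUMNS].to_csv(fh, index=False, float_format="%.17g")


def write_posterior(posterior: ModelPosterior, path,
                    config_hash: str | None = None) -> None:
    """Persist draws + provenance; reloadable bit-identically."""
    if posterior.samples.size == 0:
        raise ValueError("refusing to write an empty posterior")
    path = Path(path)
    C, D, P = posterior.samples.shape
    df = pd.DataFrame(posterior.samples.reshape(C * D, P),
                      columns=posterior.param_names)
    df.insert(0, "chain", np.repeat(np.arange(C), D))
    df.insert(1, "draw", np.tile(np.arange(D), C))
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "model": posterior.model,
        "seed": posterior.seed,
        "config": dataclasses.asdict(posterior.config) if posterior.config else None,
        "config_hash": config_hash,
        "attrs": {k: (v if not isinstance(v, float) or np.isfinite(v) else None)
                  for k, v in posterior.attrs.items()},
        "n_chains": C,
        "n_draws": D,
        "param_names": posterior.param_names,
        "chain_stats": [dataclasses.asdict(cs) for cs in posterior.chain_stats],
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_posterior(path) -> ModelPosterior:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    C, D = meta["n_chains"], meta["n_draws"]
    names = meta["param_names"]
    samples = df[names].to_numpy().reshape(C, D, len(names))
    config = SamplerConfig(**meta["config"]) if meta.get("config") else None
    stats = [ChainStats(**cs) for cs in meta.get("chain_stats", [])]
    post = ModelPosterior(samples, names, model=meta["model"],
                          seed=meta["seed"], config=config, chain_stats=stats,
                          attrs=meta.get("attrs") or {})
    post.attrs["config_hash"] = meta.get("config_hash")
    return post


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (see docs/methods.md for the schema)."""
    seed: int = 1
    n_participants: int = 24
    sigma: float = 0.5
    missing_rate: float = 0.16
    models: tuple = ("m1", "m2", "m3")
    n_chains: int = 4
    n_warmup: int = 500
    n_draws: int = 500
    target_acceptance: float = 0.9
    max_leapfrog: int = 32
    contrast_weights: tuple = (3.0, 1.0, -1.0, -3.0)
    data: str | None = None        # CSV path; None -> simulate
    out_dir: str = "trialwise_out"
    allow_nonconverged: bool = False
    loo_r2_boot: int = 2000

    REQUIRED = ("seed", "out_dir")

    def sampler(self, seed_offset: int = 0) -> SamplerConfig:
        return SamplerConfig(n_chains=self.n_chains, n_warmup=self.n_warmup,
                             n_draws=self.n_draws, seed=self.seed + seed_offset,
                             target_acceptance=self.target_acceptance,
                             max_leapfrog=self.max_leapfrog)


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for key in PipelineConfig.REQUIRED:
        if key not in raw:
            raise ValueError(f"{path}: missing required config key {key!r}")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
    for tup_key in ("models", "contrast_weights"):
        if tup_key in raw and isinstance(raw[tup_key], list):
            raw[tup_key] = tuple(raw[tup_key])
    return PipelineConfig(**raw)


def config_hash(config: PipelineConfig) -> str:
    """Hash of the scientific settings (the output location is excluded
    so reruns into different directories share provenance)."""
    payload = dataclasses.asdict(config)
    payload.pop("out_dir", None)
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]
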