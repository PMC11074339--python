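"""Run configuration: schema-validated YAML tree and seed derivation.

One master seed fans out to per-component seeds through a stable hash of
the component name, so any sub-run (VAE training, scorer folds, the
generation loop) is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class VaeSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    embed_dim: int = 128
    encoder_hidden: int = 256
    encoder_layers: int = 1
    encoder_dropout: float = Field(0.2, ge=0, lt=1)
    latent_dim: int = 128
    decoder_hidden: int = 512
    decoder_layers: int = 3
    decoder_dropout: float = Field(0.0, ge=0, lt=1)
    max_len: int = 100


class TrainSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    epochs: int = Field(200, gt=0)
    learning_rate: float = Field(3e-4, gt=0)
    batch_size: int = Field(1024, gt=0)
    grad_clip: float = Field(50.0, gt=0)
    kl_weight: float = Field(1.0, gt=0)
    kl_warmup_epochs: int = Field(0, ge=0)
    lr_decay: float = Field(1.0, gt=0, le=1)


class GenerationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_cycles: int = Field(200, ge=0)
    samples_per_cycle: int = Field(8192, gt=0)
    top_k: int = Field(4096, gt=0)
    finetune_epochs: int = Field(2, ge=0)
    finetune_batch: int = Field(512, gt=0)
    decode_mode: str = "multinomial"
    cache_scores: bool = True


class RewardSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mu: float
    sigma: float = Field(gt=0)


class RunConfig(BaseModel):
    """Top-level run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    vae: VaeSection = VaeSection()
    train: TrainSection = TrainSection()
    generation: GenerationSection = GenerationSection()
    rewards: dict[str, RewardSection] = {}
    paths: dict[str, str] = {}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def derive_seed(master_seed: int, component: str) -> int:
    """Stable per-component seed below 2**31."""
    h = hashlib.sha256(f"{master_seed}:{component}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def provenance_block(config: RunConfig | None, seed: int) -> dict:
    import sklearn
    import rdkit
    import numpy
    return {
        "config_hash": config.content_hash() if config is not None else None,
        "seed": seed,
        "versions": {"numpy": numpy.__version__,
                     "sklearn": sklearn.__version__,
                     "rdkit": rdkit.__version__},
    }
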