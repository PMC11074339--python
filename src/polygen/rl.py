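"""Reinforcement loop: sample latents, decode, score, select, fine-tune.

Each cycle draws `samples_per_cycle` coordinates from the N(0, I) latent
prior, decodes them to SMILES, curates and deduplicates the results,
scores survivors with the six-reward engine, keeps the `top_k` by
aggregate reward R, and fine-tunes the VAE on them (2 epochs, batch 512
by default). Repeating re-maps the prior's mass onto high-reward regions
of chemical space — the refocusing mechanism of the method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import CuratedMolecule, RawCompoundRecord, curate_record
from .rewards import (KnownLigandSet, RewardSpec, RewardVector, Unscorable,
                      score_candidate)
from .vae import SmilesVAE


@dataclass(frozen=True)
class GenerationConfig:
    """Loop schedule. Defaults are the full-scale run; desk-scale work
    shrinks them via config."""

    n_cycles: int = 200
    samples_per_cycle: int = 8192
    top_k: int = 4096
    finetune_epochs: int = 2
    finetune_batch: int = 512
    seed: int = 0
    decode_mode: str = "multinomial"
    cache_scores: bool = True

    def __post_init__(self):
        if self.top_k > self.samples_per_cycle:
            raise ValueError("top_k cannot exceed samples_per_cycle")
        if min(self.n_cycles, self.samples_per_cycle, self.top_k,
               self.finetune_epochs + 1, self.finetune_batch) < 0:
            raise ValueError("all schedule fields must be nonnegative")


@dataclass
class CycleLog:
    cycle_index: int
    n_sampled: int
    n_valid: int
    n_unique: int
    n_scored: int
    reward_mean: float
    reward_median: float
    reward_max: float
    top_candidates: list  # (smiles, R)

    def validate(self):
        assert self.n_scored <= self.n_unique <= self.n_valid <= self.n_sampled


def select_top_k(candidates: list[tuple[CuratedMolecule, float]],
                 k: int) -> list[CuratedMolecule]:
    """The k highest-R candidates; ties broken by canonical SMILES order
    (lexicographically smaller wins). Equals a full descending sort
    truncated at k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(candidates):
        warnings.warn(f"top_k={k} exceeds candidate count {len(candidates)}; "
                      "returning all")
        k = len(candidates)
    ranked = sorted(candidates, key=lambda c: (-c[1], c[0].smiles))
    return [mol for mol, _ in ranked[:k]]


def run_cycle(model: SmilesVAE, scorers, ligand_sets, specs,
              cfg: GenerationConfig, rng: np.random.Generator,
              cycle_index: int = 0,
              score_cache: dict | None = None) -> CycleLog:
    """One sample-decode-score-select-finetune cycle (mutates the model)."""
    z = rng.standard_normal((cfg.samples_per_cycle, model.latent_dim))
    smiles_list, _ = model.decode(z, mode=cfg.decode_mode, rng=rng)
    curated: list[CuratedMolecule] = []
    for s in smiles_list:
        if not s:
            continue
        out = curate_record(RawCompoundRecord(s))
        if isinstance(out, CuratedMolecule):
            curated.append(out)
    n_valid = len(curated)
    unique = {m.smiles: m for m in curated}
    n_unique = len(unique)
    mols = sorted(unique.values(), key=lambda m: m.smiles)
    scored: list[tuple[CuratedMolecule, RewardVector]] = []
    if mols:
        mus = model.encode_batch(mols)
        for mol, mu in zip(mols, mus):
            if score_cache is not None and mol.smiles in score_cache:
                scored.append((mol, score_cache[mol.smiles]))
                continue
            try:
                rv = score_candidate(mol, scorers, ligand_sets, specs, mu)
            except Unscorable:
                continue
            if score_cache is not None:
                score_cache[mol.smiles] = rv
            scored.append((mol, rv))
    rewards = np.array([rv.aggregate for _, rv in scored])
    log = CycleLog(
        cycle_index=cycle_index, n_sampled=cfg.samples_per_cycle,
        n_valid=n_valid, n_unique=n_unique, n_scored=len(scored),
        reward_mean=float(rewards.mean()) if len(rewards) else float("nan"),
        reward_median=float(np.median(rewards)) if len(rewards) else float("nan"),
        reward_max=float(rewards.max()) if len(rewards) else float("nan"),
        top_candidates=[(m.smiles, rv.aggregate) for m, rv in
                        sorted(scored, key=lambda c: (-c[1].aggregate,
                                                      c[0].smiles))[:cfg.top_k]])
    log.validate()
    if scored and cfg.finetune_epochs > 0:
        winners = select_top_k([(m, rv.aggregate) for m, rv in scored],
                               min(cfg.top_k, len(scored)))
        model.fine_tune(winners, epochs=cfg.finetune_epochs,
                        batch_size=cfg.finetune_batch)
    return log


@dataclass
class GenerationResult:
    model: SmilesVAE
    cycle_logs: list[CycleLog]
    ranked_table: pd.DataFrame
    provenance: dict


def run_polygon(model: SmilesVAE, scorers, ligand_sets, specs,
                cfg: GenerationConfig) -> GenerationResult:
    """Run the full loop; returns the refocused model, per-cycle logs,
    and a ranked table of all distinct scored compounds (max R kept for
    compounds seen in several cycles)."""
    if scorers[0].training_set_hash_ is None or scorers[1].training_set_hash_ is None:
        raise ValueError("scorers must be fitted before generation")
    rng = np.random.default_rng(cfg.seed)
    logs: list[CycleLog] = []
    best: dict[str, tuple[float, int]] = {}  # smiles -> (R, first_seen_cycle)
    cache: dict | None = {} if cfg.cache_scores else None
    for cycle in range(cfg.n_cycles):
        log = run_cycle(model, scorers, ligand_sets, specs, cfg, rng,
                        cycle_index=cycle, score_cache=cache)
        logs.append(log)
        for smiles, r in log.top_candidates:
            if smiles not in best:
                best[smiles] = (r, cycle)
            elif r > best[smiles][0]:
                best[smiles] = (r, best[smiles][1])
    table = pd.DataFrame(
        [{"smiles": s, "R": r, "first_seen_cycle": c}
         for s, (r, c) in best.items()]
    ).sort_values(["R", "smiles"], ascending=[False, True], ignore_index=True) \
        if best else pd.DataFrame(columns=["smiles", "R", "first_seen_cycle"])
    provenance = {"config": cfg.__dict__.copy(),
                  "checkpoint": model.checkpoint_fingerprint(),
                  "scorer_hashes": [scorers[0].training_set_hash_,
                                    scorers[1].training_set_hash_]}
    return GenerationResult(model=model, cycle_logs=logs,
                            ranked_table=table, provenance=provenance)
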