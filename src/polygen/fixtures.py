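"""End-to-end desk-scale scenarios for exercising the whole pipeline.

A scenario bundles a fixture corpus, a small VAE trained on it, planted
structure-activity tables for two (possibly correlated) targets,
known-ligand embedding sets produced by that same VAE, and the six
reward specs — everything the generation loop and the dual-activity
benchmark need, mutually consistent and reproducible from one seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .corpus import CuratedMolecule, generate_fixture_corpus
from .rewards import PLACEHOLDER_SPECS, KnownLigandSet, RewardSpec
from .scoring import ActivityRecord, featurize, generate_synthetic_activity
from .vae import SmilesVAE


@dataclass(frozen=True)
class TargetSpec:
    target_id: str
    n_planted_bits: int = 10
    noise_sigma: float = 0.05
    planted_bits: tuple[int, ...] | None = None  # explicit override


@dataclass(frozen=True)
class ScenarioSpec:
    """Deterministic recipe for one synthetic study."""

    seed: int = 0
    n_families: int = 4
    family_size: int = 25
    targets: tuple[TargetSpec, TargetSpec] = (TargetSpec("T1"), TargetSpec("T2"))
    dual_overlap: float = 1.0  # fraction of planted bits shared between targets
    n_activity_records: int = 200
    n_known_ligands: int = 20
    reward_specs: dict = field(default_factory=lambda: dict(PLACEHOLDER_SPECS))
    # compact VAE sized for CPU scenario work
    vae_kwargs: dict = field(default_factory=lambda: {
        "embed_dim": 24, "encoder_hidden": 48, "encoder_layers": 1,
        "encoder_dropout": 0.0, "latent_dim": 12, "decoder_hidden": 64,
        "decoder_layers": 1, "max_len": 40, "epochs": 60,
        "learning_rate": 3e-3, "batch_size": 64, "kl_weight": 0.1,
        "kl_warmup_epochs": 20})

    def __post_init__(self):
        if not 0.0 <= self.dual_overlap <= 1.0:
            raise ValueError("dual_overlap must lie in [0, 1]")
        if len(self.targets) != 2:
            raise ValueError("a scenario needs exactly two targets")
        if self.targets[0].target_id == self.targets[1].target_id:
            raise ValueError("target ids must differ")


@dataclass
class ScenarioBundle:
    corpus: list[CuratedMolecule]
    vae: SmilesVAE
    activity: dict[str, list[ActivityRecord]]
    planted_bits: dict[str, tuple[int, ...]]
    ligand_sets: dict[str, KnownLigandSet]
    reward_specs: dict[str, RewardSpec]
    manifest: dict


def _informative_bits(corpus, rng, exclude=frozenset()):
    """Fingerprint bits with mid-range prevalence carry structure signal."""
    fps = np.stack([featurize(m) for m in corpus])
    prevalence = fps.mean(axis=0)
    candidates = np.where((prevalence > 0.15) & (prevalence < 0.85))[0]
    candidates = np.array([b for b in candidates if b not in exclude])
    return fps, rng.permutation(candidates)


def build_scenario(spec: ScenarioSpec) -> ScenarioBundle:
    """Expand a :class:`ScenarioSpec` into a consistent component bundle."""
    rng = np.random.default_rng(spec.seed)
    corpus = generate_fixture_corpus(spec.n_families, spec.family_size,
                                     seed=spec.seed)
    t1, t2 = spec.targets
    _, shuffled = _informative_bits(corpus, rng)
    need = t1.n_planted_bits + t2.n_planted_bits
    if len(shuffled) < need:
        raise ValueError(f"corpus exposes only {len(shuffled)} informative "
                         f"fingerprint bits; {need} requested")
    if t1.planted_bits is not None:
        bits1 = tuple(t1.planted_bits)
    else:
        bits1 = tuple(int(b) for b in shuffled[:t1.n_planted_bits])
    if t2.planted_bits is not None:
        bits2 = tuple(t2.planted_bits)
    else:
        n_shared = int(round(spec.dual_overlap * t2.n_planted_bits))
        shared = bits1[:n_shared]
        fresh = [int(b) for b in shuffled if b not in bits1]
        bits2 = tuple(shared) + tuple(fresh[:t2.n_planted_bits - n_shared])
    activity = {}
    for tgt, bits in ((t1, bits1), (t2, bits2)):
        activity[tgt.target_id] = generate_synthetic_activity(
            spec.n_activity_records, tgt.target_id, list(bits),
            seed=int(rng.integers(2**31)), noise_sigma=tgt.noise_sigma,
            molecules=corpus)
    vae = SmilesVAE(seed=spec.seed, **spec.vae_kwargs).fit(corpus)
    ligand_sets = {}
    for tgt in (t1, t2):
        recs = sorted(activity[tgt.target_id],
                      key=lambda r: (-r.ligand_efficiency, r.smiles))
        top_smiles = list(dict.fromkeys(r.smiles for r in recs))[:spec.n_known_ligands]
        emb = vae.encode_batch(top_smiles)
        ligand_sets[tgt.target_id] = KnownLigandSet(
            target_id=tgt.target_id, embeddings=emb,
            k=min(20, len(top_smiles)))
    manifest = {
        "seed": spec.seed,
        "corpus_sha": _sha("".join(m.smiles for m in corpus)),
        "activity_sha": {
            t: _sha(json.dumps([(r.smiles, r.affinity_value) for r in recs]))
            for t, recs in activity.items()},
        "planted_bits": {t1.target_id: bits1, t2.target_id: bits2},
        "vae_checkpoint": vae.checkpoint_fingerprint(),
        "ligand_set_sha": {
            t: _sha(ls.embeddings.tobytes().hex())
            for t, ls in ligand_sets.items()},
    }
    return ScenarioBundle(corpus=corpus, vae=vae, activity=activity,
                          planted_bits={t1.target_id: bits1,
                                        t2.target_id: bits2},
                          ligand_sets=ligand_sets,
                          reward_specs=dict(spec.reward_specs),
                          manifest=manifest)


def _sha(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]
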