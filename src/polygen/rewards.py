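"""Six-component reward for candidate compounds, half-Gaussian normalized.

Raw rewards: predicted ligand efficiency against each of two targets
(r1, r2; maximized), Euclidean distance of the candidate's embedding to
the closest known ligands of each target (r3, r4; minimized), synthetic
accessibility (r5, SA score, minimized) and drug-likeness (r6, QED,
maximized). Each reward is mapped to [0, 1] by a half-Gaussian: 1 on the
satisfied side of the threshold mean mu_i, a Gaussian falloff with width
sigma_i on the other side. The aggregate R is the arithmetic mean of the
six normalized rewards.

The mu_i/sigma_i defaults shipped here are documented placeholders for
desk-scale work; a production run must set them from its own calibration.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDConfig
from rdkit.Chem import QED

sys.path.append(RDConfig.RDContribDir + "/SA_Score")
import sascorer  # noqa: E402  (RDKit contrib module, path injected above)

from .corpus import CuratedMolecule  # noqa: E402
from .scoring import LigandEfficiencyScorer  # noqa: E402

REWARD_NAMES = ("le_target1", "le_target2", "dist_target1", "dist_target2",
                "sa", "qed")

#: Fixed optimization direction per reward.
REWARD_DIRECTIONS = {"le_target1": "maximize", "le_target2": "maximize",
                     "dist_target1": "minimize", "dist_target2": "minimize",
                     "sa": "minimize", "qed": "maximize"}


@dataclass(frozen=True)
class RewardSpec:
    """Threshold mean and width for half-Gaussian normalization of one reward."""

    name: str
    mu: float
    sigma: float

    def __post_init__(self):
        if self.name not in REWARD_DIRECTIONS:
            raise ValueError(f"unknown reward {self.name!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def direction(self) -> str:
        return REWARD_DIRECTIONS[self.name]


#: Placeholder defaults (documented, not calibrated to any published run).
PLACEHOLDER_SPECS = {
    "le_target1": RewardSpec("le_target1", mu=0.4, sigma=0.1),
    "le_target2": RewardSpec("le_target2", mu=0.4, sigma=0.1),
    "dist_target1": RewardSpec("dist_target1", mu=3.0, sigma=2.0),
    "dist_target2": RewardSpec("dist_target2", mu=3.0, sigma=2.0),
    "sa": RewardSpec("sa", mu=4.0, sigma=1.0),
    "qed": RewardSpec("qed", mu=0.7, sigma=0.1),
}


def normalize_half_gaussian(r: float, spec: RewardSpec) -> float:
    """1 on the satisfied side of mu; exp(-((r-mu)/sigma)^2 / 2) otherwise."""
    if spec.direction == "maximize":
        unsatisfied = r < spec.mu
    else:
        unsatisfied = r > spec.mu
    if not unsatisfied:
        return 1.0
    return float(np.exp(-0.5 * ((r - spec.mu) / spec.sigma) ** 2))


@dataclass(frozen=True)
class KnownLigandSet:
    """Latent means of a target's known ligands, from one VAE checkpoint."""

    target_id: str
    embeddings: np.ndarray  # (n_ligands, latent_dim)
    k: int = 20

    def __post_init__(self):
        emb = np.atleast_2d(np.asarray(self.embeddings, dtype=float))
        object.__setattr__(self, "embeddings", emb)
        if emb.shape[0] == 0:
            raise ValueError("ligand set is empty")


def distance_reward(candidate_mu: np.ndarray, ligands: KnownLigandSet,
                    statistic: str = "mean") -> float:
    """Euclidean distance from the candidate embedding to the k closest
    known ligands: the mean of the k smallest distances (or their min,
    when configured)."""
    candidate_mu = np.asarray(candidate_mu, dtype=float)
    if candidate_mu.shape[-1] != ligands.embeddings.shape[1]:
        raise ValueError("latent dimension mismatch with ligand set")
    d = np.linalg.norm(ligands.embeddings - candidate_mu[None, :], axis=1)
    k = min(ligands.k, len(d))
    smallest = np.sort(d)[:k]
    return float(smallest.min() if statistic == "min" else smallest.mean())


def _as_rdmol(mol: CuratedMolecule | str) -> Chem.Mol:
    smiles = mol.smiles if isinstance(mol, CuratedMolecule) else mol
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    return rdmol


def sa_reward(mol: CuratedMolecule | str) -> float:
    """Synthetic-accessibility score, ~1 (easy) to ~10 (hard)."""
    return float(sascorer.calculateScore(_as_rdmol(mol)))


def qed_reward(mol: CuratedMolecule | str) -> float:
    """Quantitative estimate of drug-likeness in [0, 1]."""
    return float(QED.qed(_as_rdmol(mol)))


@dataclass(frozen=True)
class RewardVector:
    """Raw rewards r1..r6, their normalized values, and the aggregate R."""

    raw: dict[str, float]
    normalized: dict[str, float]

    @property
    def aggregate(self) -> float:
        return float(np.mean([self.normalized[n] for n in REWARD_NAMES]))


class Unscorable(Exception):
    """A candidate that cannot be scored (dropped and logged downstream)."""


def score_candidate(mol: CuratedMolecule,
                    scorers: tuple[LigandEfficiencyScorer, LigandEfficiencyScorer],
                    ligand_sets: tuple[KnownLigandSet, KnownLigandSet],
                    specs: dict[str, RewardSpec],
                    candidate_mu: np.ndarray,
                    distance_statistic: str = "mean") -> RewardVector:
    """Score one candidate against the six rewards.

    `candidate_mu` is the candidate's latent mean under the same VAE
    checkpoint that embedded the ligand sets. Any component failure
    raises :class:`Unscorable`.
    """
    try:
        raw = {
            "le_target1": scorers[0].predict_efficiency(mol),
            "le_target2": scorers[1].predict_efficiency(mol),
            "dist_target1": distance_reward(candidate_mu, ligand_sets[0],
                                            distance_statistic),
            "dist_target2": distance_reward(candidate_mu, ligand_sets[1],
                                            distance_statistic),
            "sa": sa_reward(mol),
            "qed": qed_reward(mol),
        }
    except Exception as exc:  # component failure -> unscorable, never a crash
        raise Unscorable(str(exc)) from exc
    normalized = {name: normalize_half_gaussian(raw[name], specs[name])
                  for name in REWARD_NAMES}
    return RewardVector(raw=raw, normalized=normalized)
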