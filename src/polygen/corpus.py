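"""Chemical corpus handling: curation, tokenization, fixture generation.

Curation mirrors the standard generative-chemistry preprocessing of ChEMBL:
salt stripping (keep the largest fragment), charge neutralization, a 100
character SMILES length cap, and an element whitelist. Tokenization is
character-level with the two-character element symbols Cl/Br/Si/Se kept
atomic, so a decoder can never emit half an element symbol.
"""

from __future__ import annotations

import csv
import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Element whitelist used for corpus curation.
ALLOWED_ATOMS = frozenset({"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"})

#: Maximum canonical-SMILES length admitted to the corpus.
MAX_SMILES_LEN = 100

_TOKEN_RE = re.compile(r"Cl|Br|Si|Se|.")

PAD, START, END = "<pad>", "<start>", "<end>"


@dataclass(frozen=True)
class RawCompoundRecord:
    """A SMILES string as read from input, before any validation."""

    raw_smiles: str
    source_id: str = ""

    def __post_init__(self):
        if not self.raw_smiles:
            raise ValueError("raw_smiles must be non-empty")


@dataclass(frozen=True)
class CuratedMolecule:
    """A validated, desalted, neutralized molecule in canonical SMILES."""

    smiles: str
    heavy_atom_count: int

    @property
    def length(self) -> int:
        return len(self.smiles)


@dataclass(frozen=True)
class Rejection:
    """Why a raw record failed curation."""

    raw_smiles: str
    reason: str  # one of: unparseable, too_long, disallowed_atom


_UNCHARGER = rdMolStandardize.Uncharger()


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep the fragment with the most heavy atoms; ties go to the
    lexicographically smallest canonical SMILES."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return frags[0]
    keyed = []
    for f in frags:
        try:
            smi = Chem.MolToSmiles(f)
        except Exception:
            smi = ""
        keyed.append((-f.GetNumHeavyAtoms(), smi, f))
    keyed.sort(key=lambda t: (t[0], t[1]))
    return keyed[0][2]


def curate_record(rec: RawCompoundRecord,
                  allowed_atoms: frozenset[str] = ALLOWED_ATOMS,
                  max_len: int = MAX_SMILES_LEN) -> CuratedMolecule | Rejection:
    """Curate one raw SMILES record.

    Steps: parse, keep the largest fragment, neutralize formal charges,
    check the element whitelist, canonicalize, enforce the length cap.
    Failures return a :class:`Rejection` (never raise).
    """
    mol = Chem.MolFromSmiles(rec.raw_smiles)
    if mol is None:
        return Rejection(rec.raw_smiles, "unparseable")
    mol = _largest_fragment(mol)
    try:
        mol = _UNCHARGER.uncharge(mol)
        Chem.SanitizeMol(mol)
    except Exception:
        return Rejection(rec.raw_smiles, "unparseable")
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in allowed_atoms:
            return Rejection(rec.raw_smiles, "disallowed_atom")
    smiles = Chem.MolToSmiles(mol)
    if len(smiles) > max_len:
        return Rejection(rec.raw_smiles, "too_long")
    return CuratedMolecule(smiles=smiles, heavy_atom_count=mol.GetNumHeavyAtoms())


def curate_corpus(records: list[RawCompoundRecord],
                  allowed_atoms: frozenset[str] = ALLOWED_ATOMS,
                  max_len: int = MAX_SMILES_LEN):
    """Curate a list of records; returns (accepted, rejections)."""
    accepted, rejected = [], []
    for rec in records:
        out = curate_record(rec, allowed_atoms, max_len)
        (accepted if isinstance(out, CuratedMolecule) else rejected).append(out)
    return accepted, rejected


# ---------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------

def smiles_tokens(smiles: str) -> list[str]:
    """Split a SMILES string into tokens (Cl/Br/Si/Se atomic)."""
    return _TOKEN_RE.findall(smiles)


@dataclass(frozen=True)
class TokenVocabulary:
    """Ordered token inventory with pad/start/end specials first."""

    tokens: tuple[str, ...]

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def start_id(self) -> int:
        return 1

    @property
    def end_id(self) -> int:
        return 2

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tokens)}

    def __post_init__(self):
        assert self.tokens[:3] == (PAD, START, END)


def build_vocabulary(corpus: list[CuratedMolecule]) -> TokenVocabulary:
    """Character census of the corpus; deterministic (sorted) ordering."""
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    charset: set[str] = set()
    for mol in corpus:
        charset.update(smiles_tokens(mol.smiles))
    return TokenVocabulary(tokens=(PAD, START, END) + tuple(sorted(charset)))


@dataclass(frozen=True)
class EncodedSequence:
    """Fixed-length token-id sequence: <start> content <end> <pad>..."""

    token_ids: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.token_ids)


def tokenize(mol: CuratedMolecule, vocab: TokenVocabulary,
             max_len: int = MAX_SMILES_LEN) -> EncodedSequence:
    """Encode a curated molecule as <start> tokens <end> padded to max_len."""
    index = vocab.index
    toks = smiles_tokens(mol.smiles)
    if len(toks) > max_len - 2:
        raise ValueError(f"SMILES has {len(toks)} tokens; budget is {max_len - 2} "
                         f"(start/end framing inside the {max_len} window)")
    ids = [vocab.start_id]
    for t in toks:
        if t not in index:
            raise KeyError(f"token {t!r} not in vocabulary")
        ids.append(index[t])
    ids.append(vocab.end_id)
    ids.extend([vocab.pad_id] * (max_len - len(ids)))
    return EncodedSequence(token_ids=tuple(ids))


def detokenize(seq: EncodedSequence, vocab: TokenVocabulary) -> str:
    """Invert :func:`tokenize`; stops at the end token, skips framing."""
    out = []
    for tid in seq.token_ids:
        if tid == vocab.end_id or tid == vocab.pad_id:
            break
        if tid == vocab.start_id:
            continue
        out.append(vocab.tokens[tid])
    return "".join(out)


# ---------------------------------------------------------------------
# Fixture corpora
# ---------------------------------------------------------------------

_FAMILY_SCAFFOLDS = [
    # (core template with {n} repeat, substituent pool)
    ("alkane", "C" * 4, ["C", "CC", "CCC", "C(C)C", "CCCC", "C(C)(C)C"]),
    ("ether", "COC", ["C", "CC", "CCO", "COC", "CCC", "OC"]),
    ("amine", "CCN", ["C", "CC", "CN", "CCN", "N(C)C", "CCC"]),
    ("alcohol", "CCO", ["O", "CO", "CCO", "C(O)C", "OCC", "C(C)O"]),
    ("ring", "C1CCCCC1", ["C", "CC", "O", "N", "CO", "CN"]),
    ("amide", "CC(=O)N", ["C", "CC", "NC", "OC", "CCC", "CN"]),
]


def generate_fixture_corpus(n_families: int, family_size: int,
                            seed: int) -> list[CuratedMolecule]:
    """Deterministic families of structurally related small molecules.

    Each family grows a fixed scaffold with substituents drawn from a
    family-specific pool, so members of a family share substructure
    (high intra-family fingerprint overlap) while families differ.
    """
    if n_families < 1 or family_size < 1:
        raise ValueError("n_families and family_size must be >= 1")
    rng = np.random.default_rng(seed)
    corpus: list[CuratedMolecule] = []
    for fam in range(n_families):
        name, core, pool = _FAMILY_SCAFFOLDS[fam % len(_FAMILY_SCAFFOLDS)]
        seen: set[str] = set()
        attempts = 0
        while len(seen) < family_size and attempts < family_size * 200:
            attempts += 1
            n_subs = int(rng.integers(1, 4))
            smi = core + "".join(pool[int(rng.integers(0, len(pool)))]
                                 for _ in range(n_subs))
            out = curate_record(RawCompoundRecord(smi))
            if isinstance(out, CuratedMolecule) and out.smiles not in seen:
                seen.add(out.smiles)
                corpus.append(out)
        if len(seen) < family_size:
            raise RuntimeError(f"family {name!r} exhausted at {len(seen)} molecules")
    return corpus


def train_val_split(corpus: list[CuratedMolecule], val_fraction: float,
                    seed: int) -> tuple[list[CuratedMolecule], list[CuratedMolecule]]:
    """Deterministic split by hashing canonical SMILES with the seed."""
    train, val = [], []
    for mol in corpus:
        h = hashlib.sha256(f"{seed}:{mol.smiles}".encode()).digest()
        frac = int.from_bytes(h[:8], "big") / 2**64
        (val if frac < val_fraction else train).append(mol)
    return train, val


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------

def read_smiles_file(path: str | Path) -> list[RawCompoundRecord]:
    """Read .smi (SMILES [whitespace id]) or one-SMILES-per-line text."""
    records = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        records.append(RawCompoundRecord(parts[0], parts[1] if len(parts) > 1 else str(i)))
    return records


def write_smiles_file(molecules: list[CuratedMolecule], path: str | Path) -> None:
    Path(path).write_text("".join(m.smiles + "\n" for m in molecules))


def write_rejection_log(rejections: list[Rejection], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["raw_smiles", "reason"])
        for r in rejections:
            writer.writerow([r.raw_smiles, r.reason])
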