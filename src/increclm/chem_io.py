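"""SMILES standardization, tokenization, augmentation, fingerprints and tabular I/O.

All molecules entering the pipeline pass through :func:`standardize_smiles`,
which enforces the corpus conventions used throughout: the largest organic
fragment, no isotopes, no stereochemistry, neutralized charges where a simple
(de)protonation suffices, a molecular-weight ceiling and a token-length
ceiling. Activities are stored on the negative decadic log molar scale
(``potency_p``, higher = more potent).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeRecord",
    "Rejection",
    "TokenVocabulary",
    "TokenSequence",
    "UnknownTokenError",
    "standardize_smiles",
    "tokenize",
    "detokenize",
    "build_vocabulary",
    "randomize_smiles",
    "morgan_fingerprint",
    "fingerprint_similarity",
    "bulk_max_similarity",
    "read_activity_table",
    "write_molecule_table",
    "PAD_TOKEN",
    "START_TOKEN",
    "END_TOKEN",
]

PAD_TOKEN = "<pad>"
START_TOKEN = "<start>"
END_TOKEN = "<end>"

DEFAULT_MAX_MW = 1000.0
DEFAULT_MAX_TOKENS = 140

# Atom-level tokenization: bracket atoms, two-letter halogens and two-digit
# ring closures are single tokens; everything else is one character.
_TOKEN_RE = re.compile(r"\[[^\]]*\]|Br|Cl|%\d{2}|.")

_UNCHARGER = rdMolStandardize.Uncharger()


@dataclass(frozen=True)
class MoleculeRecord:
    """A standardized molecule with optional potency and provenance."""

    smiles_canonical: str
    potency_p: float | None = None
    series_id: str | None = None
    annotations: frozenset = field(default_factory=frozenset)

    def with_potency(self, potency_p: float) -> "MoleculeRecord":
        return replace(self, potency_p=potency_p)


@dataclass(frozen=True)
class Rejection:
    """A machine-readable reason a raw SMILES was excluded from the corpus."""

    raw: str
    reason: str  # unparsable | overweight | overlong | empty-after-salt-strip


class UnknownTokenError(KeyError):
    """Raised when a SMILES contains a token outside the model vocabulary."""

    def __init__(self, token: str):
        super().__init__(token)
        self.token = token

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"token {self.token!r} is not in the vocabulary"


@dataclass(frozen=True)
class TokenVocabulary:
    """Ordered token set with pad/start/end sentinels at indices 0..2."""

    tokens: tuple
    index: Mapping[str, int]

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def pad_index(self) -> int:
        return self.index[PAD_TOKEN]

    @property
    def start_index(self) -> int:
        return self.index[START_TOKEN]

    @property
    def end_index(self) -> int:
        return self.index[END_TOKEN]

    def encode(self, tokens: Sequence[str]) -> list:
        out = []
        for t in tokens:
            if t not in self.index:
                raise UnknownTokenError(t)
            out.append(self.index[t])
        return out

    def decode(self, indices: Sequence[int]) -> str:
        sent = {self.pad_index, self.start_index, self.end_index}
        return "".join(self.tokens[i] for i in indices if i not in sent)


@dataclass(frozen=True)
class TokenSequence:
    tokens: tuple
    indices: tuple | None
    n: int  # chemical token count, sentinels excluded


def _segment(smiles: str) -> list:
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise ValueError(f"tokenization does not cover input: {smiles!r}")
    return tokens


def tokenize(smiles: str, vocab: TokenVocabulary | None = None) -> TokenSequence:
    """Split a SMILES into atom-level tokens.

    Two-letter halogens (Cl, Br), full bracket atoms and two-digit ring
    closures are single tokens. With ``vocab`` given, unknown tokens raise
    :class:`UnknownTokenError`.
    """
    if not smiles:
        raise ValueError("cannot tokenize an empty SMILES")
    tokens = _segment(smiles)
    indices = tuple(vocab.encode(tokens)) if vocab is not None else None
    return TokenSequence(tokens=tuple(tokens), indices=indices, n=len(tokens))


def detokenize(tokens: Iterable[str]) -> str:
    return "".join(tokens)


def build_vocabulary(corpus: Iterable[str]) -> TokenVocabulary:
    """Vocabulary = sorted union of corpus tokens plus the three sentinels."""
    chem_tokens: set = set()
    n = 0
    for smiles in corpus:
        n += 1
        chem_tokens.update(_segment(smiles))
    if n == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    tokens = (PAD_TOKEN, START_TOKEN, END_TOKEN) + tuple(sorted(chem_tokens))
    return TokenVocabulary(tokens=tokens, index={t: i for i, t in enumerate(tokens)})


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol | None:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags if any(a.GetSymbol() == "C" for a in f.GetAtoms())]
    if not organic:
        return None
    # largest by heavy atoms, ties by molecular weight, then canonical SMILES
    def key(f: Chem.Mol):
        return (f.GetNumHeavyAtoms(), Descriptors.MolWt(f), Chem.MolToSmiles(f))

    return max(organic, key=key)


def standardize_smiles(
    raw: str,
    max_mw: float = DEFAULT_MAX_MW,
    max_tokens: int = DEFAULT_MAX_TOKENS,
) -> MoleculeRecord | Rejection:
    """Standardize a raw SMILES or reject it with a machine-readable reason.

    Keeps the largest carbon-containing fragment (salt stripping), clears
    isotopes and stereochemistry, neutralizes simple ionizable groups
    (permanently charged centers such as quaternary nitrogen are kept), and
    enforces the token-length then molecular-weight ceilings. Never raises
    for bad chemistry: failures come back as :class:`Rejection`.
    """
    if not raw or not raw.strip():
        return Rejection(raw=raw, reason="unparsable")
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        return Rejection(raw=raw, reason="unparsable")
    mol = _largest_organic_fragment(mol)
    if mol is None or mol.GetNumAtoms() == 0:
        return Rejection(raw=raw, reason="empty-after-salt-strip")
    for atom in mol.GetAtoms():
        atom.SetIsotope(0)
    Chem.RemoveStereochemistry(mol)
    try:
        mol = _UNCHARGER.uncharge(mol)
        Chem.SanitizeMol(mol)
    except Exception:
        return Rejection(raw=raw, reason="unparsable")
    canonical = Chem.MolToSmiles(mol)
    if not canonical:
        return Rejection(raw=raw, reason="empty-after-salt-strip")
    if len(_segment(canonical)) > max_tokens:
        return Rejection(raw=raw, reason="overlong")
    if Descriptors.MolWt(mol) > max_mw:
        return Rejection(raw=raw, reason="overweight")
    return MoleculeRecord(smiles_canonical=canonical)


def randomize_smiles(
    record: MoleculeRecord | str, n: int, seed: int
) -> list:
    """Draw ``n`` non-canonical SMILES of the same molecule, seed-reproducibly.

    Atom order is permuted with a seeded generator and the string written
    non-canonically; every output canonicalizes back to the input.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    smiles = record.smiles_canonical if isinstance(record, MoleculeRecord) else record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid molecule record: {smiles!r}")
    rng = np.random.default_rng(seed)
    out = []
    n_atoms = mol.GetNumAtoms()
    for _ in range(n):
        perm = rng.permutation(n_atoms).tolist()
        shuffled = Chem.RenumberAtoms(mol, perm)
        out.append(Chem.MolToSmiles(shuffled, canonical=False))
    return out


_FP_GENERATORS: dict = {}


def _fp_generator(radius: int, nbits: int):
    key = (radius, nbits)
    if key not in _FP_GENERATORS:
        _FP_GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=nbits
        )
    return _FP_GENERATORS[key]


def morgan_fingerprint(smiles: str, radius: int = 2, nbits: int = 2048):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot fingerprint invalid SMILES {smiles!r}")
    return _fp_generator(radius, nbits).GetFingerprint(mol)


def fingerprint_similarity(
    a: MoleculeRecord | str,
    b: MoleculeRecord | str,
    radius: int = 2,
    nbits: int = 2048,
) -> float:
    """Tanimoto similarity on Morgan fingerprints (symmetric, in [0, 1])."""
    sa = a.smiles_canonical if isinstance(a, MoleculeRecord) else a
    sb = b.smiles_canonical if isinstance(b, MoleculeRecord) else b
    return DataStructs.TanimotoSimilarity(
        morgan_fingerprint(sa, radius, nbits), morgan_fingerprint(sb, radius, nbits)
    )


def bulk_max_similarity(
    queries: Sequence[str], references: Sequence[str], radius: int = 2, nbits: int = 2048
) -> np.ndarray:
    """For each query SMILES, the maximum Tanimoto to any reference SMILES."""
    ref_fps = [morgan_fingerprint(s, radius, nbits) for s in references]
    out = np.zeros(len(queries))
    for i, q in enumerate(queries):
        fp = morgan_fingerprint(q, radius, nbits)
        sims = DataStructs.BulkTanimotoSimilarity(fp, ref_fps)
        out[i] = max(sims) if sims else 0.0
    return out


_UNIT_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "μM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
    "fM": 1e-15,
}


def potency_from_value(value: float, unit: str) -> float:
    """Convert an activity value + unit to -log10 molar potency."""
    if unit not in _UNIT_TO_MOLAR:
        raise ValueError(f"unparsable unit {unit!r}")
    molar = float(value) * _UNIT_TO_MOLAR[unit]
    if not (molar > 0):
        raise ValueError(f"activity value must be positive, got {value!r}")
    return -math.log10(molar)


def read_activity_table(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
    max_mw: float = DEFAULT_MAX_MW,
    max_tokens: int = DEFAULT_MAX_TOKENS,
) -> tuple:
    """Read a delimited activity table into standardized molecule records.

    ``column_map`` names the relevant columns: ``smiles`` (required),
    ``value``/``unit`` (optional activity), ``potency`` (already on the
    -log10 molar scale, taking precedence over value/unit), ``target``,
    ``series``. Activities are converted to -log10 molar; rows failing
    standardization or unit parsing are dropped and reported; duplicate
    canonical SMILES collapse to a single record keeping the best (highest)
    potency.

    Returns ``(records, rejections)`` where rejections is a list of dicts.
    """
    cmap = {"smiles": "smiles", "value": "value", "unit": "unit",
            "potency": "potency_p", "target": "target", "series": "series"}
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep, engine="python")
    if cmap["smiles"] not in df.columns:
        raise ValueError(f"missing SMILES column {cmap['smiles']!r}")

    records: dict = {}
    rejections: list = []
    for _, row in df.iterrows():
        raw = row[cmap["smiles"]]
        result = standardize_smiles(str(raw), max_mw=max_mw, max_tokens=max_tokens)
        if isinstance(result, Rejection):
            rejections.append({"smiles": result.raw, "reason": result.reason})
            continue
        potency = None
        if cmap["potency"] in df.columns and not pd.isna(row.get(cmap["potency"])):
            potency = float(row[cmap["potency"]])
        elif cmap["value"] in df.columns and not pd.isna(row[cmap["value"]]):
            unit = str(row[cmap["unit"]]) if cmap["unit"] in df.columns else "M"
            try:
                potency = potency_from_value(float(row[cmap["value"]]), unit)
            except ValueError as exc:
                rejections.append({"smiles": str(raw), "reason": str(exc)})
                continue
        annotations = []
        if cmap["target"] in df.columns and not pd.isna(row.get(cmap["target"])):
            annotations.append((str(row[cmap["target"]]), potency))
        series_id = None
        if cmap["series"] in df.columns and not pd.isna(row.get(cmap["series"])):
            series_id = str(row[cmap["series"]])
        rec = MoleculeRecord(
            smiles_canonical=result.smiles_canonical,
            potency_p=potency,
            series_id=series_id,
            annotations=frozenset(annotations),
        )
        key = rec.smiles_canonical
        if key in records:
            old = records[key]
            best = rec if (rec.potency_p or -np.inf) > (old.potency_p or -np.inf) else old
            merged = replace(best, annotations=old.annotations | rec.annotations)
            records[key] = merged
        else:
            records[key] = rec
    return list(records.values()), rejections


def write_molecule_table(records: Sequence[MoleculeRecord], path,
                         rejections: Sequence[dict] | None = None,
                         rejection_path=None) -> None:
    """Write records as CSV; optionally a JSON-lines rejection log."""
    df = pd.DataFrame(
        {
            "smiles": [r.smiles_canonical for r in records],
            "potency_p": [r.potency_p for r in records],
            "series_id": [r.series_id for r in records],
        }
    )
    df.to_csv(path, index=False)
    if rejection_path is not None and rejections is not None:
        with open(rejection_path, "w") as fh:
            for rej in rejections:
                fh.write(json.dumps(rej) + "\n")
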