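"""Reference-corpus filtering, SAR-series curation and potency-staged splits.

A SAR series is a set of structurally related molecules sharing a chemotype
with measured potencies on one target. Curation enforces a minimum size,
minimum internal similarity and drops structural outliers; splitting orders
the series by potency into the staged subsets used for incremental
fine-tuning, with the most potent fraction optionally withheld as holdout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from rdkit import DataStructs
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem_io import (
    MoleculeRecord,
    morgan_fingerprint,
    standardize_smiles,
)

__all__ = [
    "SarSeries",
    "PotencySplit",
    "CurationRejection",
    "filter_reference_corpus",
    "curate_series",
    "split_series",
    "extract_holdout",
    "discover_series",
    "SPLIT_STRATEGIES",
]

SPLIT_STRATEGIES = ("all", "values", "focused", "scaffold", "random", "best")

SERIES_FP_RADIUS = 3
SERIES_FP_NBITS = 2048


def _series_fps(records: Sequence[MoleculeRecord]):
    return [
        morgan_fingerprint(r.smiles_canonical, SERIES_FP_RADIUS, SERIES_FP_NBITS)
        for r in records
    ]


def _mean_pairwise_similarity(fps) -> float:
    n = len(fps)
    if n < 2:
        return 1.0
    total, count = 0.0, 0
    for i in range(1, n):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        total += sum(sims)
        count += i
    return total / count


@dataclass(frozen=True)
class SarSeries:
    """A curated SAR series: potency-annotated records plus summary stats."""

    id: str
    records: tuple
    mean_internal_similarity: float
    potency_span: float

    @classmethod
    def from_records(cls, series_id: str, records: Iterable[MoleculeRecord]) -> "SarSeries":
        records = tuple(records)
        if any(r.potency_p is None for r in records):
            raise ValueError("every series record needs a potency_p")
        fps = _series_fps(records)
        potencies = [r.potency_p for r in records]
        return cls(
            id=series_id,
            records=records,
            mean_internal_similarity=_mean_pairwise_similarity(fps),
            potency_span=(max(potencies) - min(potencies)) if potencies else 0.0,
        )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def smiles(self) -> list:
        return [r.smiles_canonical for r in self.records]


@dataclass(frozen=True)
class CurationRejection:
    reason: str  # too-few-candidates | too-small | too-diverse
    detail: str = ""


@dataclass(frozen=True)
class PotencySplit:
    """Ordered fine-tuning subsets of non-decreasing potency plus holdout."""

    subsets: tuple  # tuple of tuples of MoleculeRecord
    holdout: tuple
    strategy: str
    k: int

    @property
    def all_records(self) -> list:
        out = []
        for s in self.subsets:
            out.extend(s)
        out.extend(self.holdout)
        return out


def _sort_key(record: MoleculeRecord):
    # stable potency ordering; ties broken by canonical SMILES
    return (record.potency_p, record.smiles_canonical)


def filter_reference_corpus(
    corpus: Sequence[MoleculeRecord],
    target_ligands: Sequence[MoleculeRecord],
    sim_threshold: float = 0.4,
    radius: int = 2,
    nbits: int = 2048,
    target_names: Iterable[str] | None = None,
) -> tuple:
    """Remove target knowledge from a pretraining corpus.

    Drops (i) corpus molecules carrying an annotation on the target family
    (``target_names``) and (ii) molecules whose maximum Tanimoto similarity
    to any target ligand strictly exceeds ``sim_threshold``.

    Returns ``(filtered_corpus, report)`` with per-rule removal counts.
    """
    report = {"annotated_removed": 0, "similar_removed": 0, "kept": 0}
    if not target_ligands:
        report["kept"] = len(corpus)
        report["warning"] = "no target ligands supplied; corpus unchanged"
        return list(corpus), report

    names = set(target_names) if target_names else set()
    ligand_fps = [
        morgan_fingerprint(r.smiles_canonical, radius, nbits) for r in target_ligands
    ]
    kept = []
    for rec in corpus:
        if names and any(t in names for t, _ in rec.annotations):
            report["annotated_removed"] += 1
            continue
        fp = morgan_fingerprint(rec.smiles_canonical, radius, nbits)
        sims = DataStructs.BulkTanimotoSimilarity(fp, ligand_fps)
        if max(sims) > sim_threshold:
            report["similar_removed"] += 1
            continue
        kept.append(rec)
    report["kept"] = len(kept)
    return kept, report


def curate_series(
    candidates: Sequence[MoleculeRecord],
    min_size: int = 25,
    min_mean_sim: float = 0.3,
    outlier_sim: float = 0.5,
    series_id: str = "series",
) -> SarSeries | CurationRejection:
    """Trim structural outliers, then accept or reject the series.

    Members whose mean similarity to the remaining members falls below
    ``outlier_sim`` are dropped, iterating until stable; the series is then
    rejected if fewer than ``min_size`` members remain or the mean internal
    pairwise similarity is below ``min_mean_sim``. Similarities use Morgan
    fingerprints, radius 3, 2048-bit.
    """
    if len(candidates) < 2:
        return CurationRejection("too-few-candidates", f"n={len(candidates)}")
    members = list(candidates)
    fps = _series_fps(members)
    while len(members) >= 2:
        mean_sims = []
        for i in range(len(members)):
            others = fps[:i] + fps[i + 1 :]
            sims = DataStructs.BulkTanimotoSimilarity(fps[i], others)
            mean_sims.append(float(np.mean(sims)))
        drop = [i for i, s in enumerate(mean_sims) if s < outlier_sim]
        if not drop:
            break
        members = [m for i, m in enumerate(members) if i not in set(drop)]
        fps = [f for i, f in enumerate(fps) if i not in set(drop)]
    if len(members) < min_size:
        return CurationRejection("too-small", f"n={len(members)} < {min_size}")
    mean_sim = _mean_pairwise_similarity(fps)
    if mean_sim < min_mean_sim:
        return CurationRejection(
            "too-diverse", f"mean similarity {mean_sim:.3f} < {min_mean_sim}"
        )
    return SarSeries.from_records(series_id, members)


def _values_groups(ordered: Sequence[MoleculeRecord], k: int) -> list:
    """k contiguous potency-ordered groups of (near) equal size.

    The remainder is spread over the lowest-potency groups so the most
    potent step is never diluted.
    """
    n = len(ordered)
    base, rem = divmod(n, k)
    sizes = [base + (1 if i < rem else 0) for i in range(k)]
    groups, pos = [], 0
    for s in sizes:
        groups.append(tuple(ordered[pos : pos + s]))
        pos += s
    return groups


def _focused_groups(ordered: Sequence[MoleculeRecord], k: int) -> list:
    """Halving group sizes ending at the most potent group.

    The final group holds m = n // (2^k - 1) records and each earlier group
    doubles it; leftover records join the first (lowest potency) group.
    """
    n = len(ordered)
    denom = 2**k - 1
    m = n // denom
    if m < 1:
        raise ValueError(f"focused split needs at least {denom} records for k={k}")
    sizes = [m * 2 ** (k - 1 - j) for j in range(k)]
    sizes[0] += n - sum(sizes)
    groups, pos = [], 0
    for s in sizes:
        groups.append(tuple(ordered[pos : pos + s]))
        pos += s
    return groups


def split_series(
    series: SarSeries,
    strategy: str,
    k: int = 4,
    seed: int = 0,
    holdout: Sequence[MoleculeRecord] = (),
) -> PotencySplit:
    """Partition a series into staged fine-tuning subsets.

    Strategies: ``all`` (single subset, no splitting), ``values`` (k equal
    potency-ordered groups), ``focused`` (halving sizes toward the most
    potent), ``scaffold`` (Murcko scaffolds first, then full molecules),
    ``random`` (k seeded shuffled groups), ``best`` (only the most active
    values group).
    """
    if strategy not in SPLIT_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    records = sorted(series.records, key=_sort_key)
    n = len(records)
    if strategy not in ("all", "best", "scaffold") and (k < 1 or k > n):
        raise ValueError(f"k={k} out of range for series of size {n}")

    if strategy == "all":
        subsets = (tuple(records),)
    elif strategy == "values":
        subsets = tuple(_values_groups(records, k))
    elif strategy == "focused":
        subsets = tuple(_focused_groups(records, k))
    elif strategy == "random":
        rng = np.random.default_rng(seed)
        shuffled = [records[i] for i in rng.permutation(n)]
        subsets = tuple(_values_groups(shuffled, k))
    elif strategy == "best":
        subsets = (tuple(_values_groups(records, k)[-1]),)
    else:  # scaffold
        scaffolds = {}
        for rec in records:
            scaf = MurckoScaffold.MurckoScaffoldSmiles(rec.smiles_canonical)
            if not scaf:
                continue
            std = standardize_smiles(scaf)
            if isinstance(std, MoleculeRecord) and std.smiles_canonical not in scaffolds:
                scaffolds[std.smiles_canonical] = replace(
                    std, potency_p=rec.potency_p, series_id=series.id
                )
        if not scaffolds:
            raise ValueError("no Murcko scaffolds could be derived")
        subsets = (tuple(scaffolds.values()), tuple(records))

    return PotencySplit(
        subsets=subsets,
        holdout=tuple(holdout),
        strategy=strategy,
        k=len(subsets),
    )


def extract_holdout(series: SarSeries, fraction: float = 0.25) -> tuple:
    """Withhold the most potent ceil(fraction*n) records as holdout.

    Ties at the potency boundary are resolved by canonical-SMILES
    lexicographic order, making the extraction deterministic.
    Returns ``(training_series, holdout_records)``.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    ordered = sorted(series.records, key=_sort_key)
    n_hold = math.ceil(fraction * len(ordered))
    if len(ordered) - n_hold < 2:
        raise ValueError("training set would have fewer than 2 records")
    holdout = tuple(ordered[len(ordered) - n_hold :])
    training = SarSeries.from_records(series.id, ordered[: len(ordered) - n_hold])
    return training, holdout


def discover_series(
    records: Sequence[MoleculeRecord],
    sim_threshold: float = 0.5,
    radius: int = SERIES_FP_RADIUS,
    nbits: int = SERIES_FP_NBITS,
) -> list:
    """Group molecules into candidate SAR series by similarity-graph clustering.

    Builds a graph with an edge wherever Tanimoto >= ``sim_threshold`` and
    returns the connected components (largest first) as record lists.
    """
    import networkx as nx

    fps = [morgan_fingerprint(r.smiles_canonical, radius, nbits) for r in records]
    g = nx.Graph()
    g.add_nodes_from(range(len(records)))
    for i in range(1, len(records)):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        for j, s in enumerate(sims):
            if s >= sim_threshold:
                g.add_edge(i, j)
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    return [[records[i] for i in sorted(comp)] for comp in components]
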