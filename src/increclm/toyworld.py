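"""Synthetic chemical space with a known pseudo-potency landscape.

The toy universe enumerates a benzimidazole-like scaffold decorated at a
small number of substitution positions with short fragment lists, so the
whole space (product of the substituent set sizes) is enumerable and every
pipeline stage can be exercised at desk scale. Pseudo-potency is an
additive per-(position, fragment) contribution model plus sparse pairwise
interaction terms — the long-range substituent dependencies a sequence
model has to capture — plus seeded Gaussian noise, all deterministic given
the seed.

A :class:`ToyBenchmark` bundles the universe with a sampled SAR series
(spanning at least two log units of pseudo-potency), a scaffold-disjoint
pretraining corpus guaranteed ignorant of the series (no corpus molecule
with Tanimoto > 0.4 to any series member), and the withheld top-25% most
potent members as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np

from .chem_io import (
    MoleculeRecord,
    Rejection,
    build_vocabulary,
    standardize_smiles,
)
from .sar_curation import SarSeries, extract_holdout, filter_reference_corpus

__all__ = [
    "ToyUniverseConfig",
    "ToyUniverse",
    "ToyBenchmark",
    "generate_toy_universe",
    "toy_potency",
    "build_toy_benchmark",
    "generate_background_corpus",
]

DEFAULT_SCAFFOLD = "c1cc({2})cc2c1nc({0})n2{1}"
DEFAULT_SUBSTITUENTS = (
    ("C", "CC", "CCC", "C(C)C", "CO", "CCO"),
    ("C", "CC", "CCN", "CC(C)C", "CCO", "CCC"),
    ("F", "Cl", "C", "O", "OC", "C(F)(F)F"),
)


@dataclass(frozen=True)
class ToyUniverseConfig:
    scaffold: str = DEFAULT_SCAFFOLD
    substituent_sets: tuple = DEFAULT_SUBSTITUENTS
    baseline: float = 6.0
    contribution_range: float = 0.6
    n_interactions: int = 4
    interaction_scale: float = 0.8
    noise_sd: float = 0.15
    contributions: dict | None = None  # explicit (position, fragment) -> effect
    interactions: dict | None = None  # ((p1, f1), (p2, f2)) -> effect


@dataclass(frozen=True)
class ToyUniverse:
    config: ToyUniverseConfig
    seed: int
    contributions: dict
    interactions: dict
    molecules: tuple  # MoleculeRecord per enumerant, potency_p = noisy potency
    assignments: tuple  # substituent tuple per enumerant
    _index: dict = field(repr=False, default_factory=dict)

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def smiles(self) -> list:
        return [m.smiles_canonical for m in self.molecules]

    def additive_potency(self, assignment: Sequence[str]) -> float:
        """Noise-free potency of a substituent assignment."""
        cfg = self.config
        p = cfg.baseline
        for pos, frag in enumerate(assignment):
            p += self.contributions[(pos, frag)]
        for ((p1, f1), (p2, f2)), effect in self.interactions.items():
            if assignment[p1] == f1 and assignment[p2] == f2:
                p += effect
        return p


def generate_toy_universe(
    config: ToyUniverseConfig | None = None, seed: int = 0
) -> ToyUniverse:
    """Enumerate the toy chemical space and assign pseudo-potencies.

    Every enumerated molecule is standardized; a chemically invalid
    scaffold or fragment raises at construction. The pseudo-potency of an
    enumerant is baseline + per-position contributions + interaction terms
    + Gaussian noise (sd ``noise_sd``), all reproducible from ``seed``.
    """
    cfg = config or ToyUniverseConfig()
    if len(cfg.substituent_sets) < 2:
        raise ValueError("need at least 2 substitution positions")
    if any(len(s) < 3 for s in cfg.substituent_sets):
        raise ValueError("need at least 3 substituents per position")
    rng = np.random.default_rng(seed)

    if cfg.contributions is not None:
        contributions = dict(cfg.contributions)
    else:
        contributions = {
            (pos, frag): float(
                rng.uniform(-cfg.contribution_range, cfg.contribution_range)
            )
            for pos, frags in enumerate(cfg.substituent_sets)
            for frag in frags
        }
    if cfg.interactions is not None:
        interactions = dict(cfg.interactions)
    else:
        interactions = {}
        n_pos = len(cfg.substituent_sets)
        for _ in range(cfg.n_interactions):
            p1, p2 = sorted(rng.choice(n_pos, size=2, replace=False))
            f1 = cfg.substituent_sets[p1][rng.integers(len(cfg.substituent_sets[p1]))]
            f2 = cfg.substituent_sets[p2][rng.integers(len(cfg.substituent_sets[p2]))]
            interactions[((int(p1), f1), (int(p2), f2))] = float(
                rng.uniform(-cfg.interaction_scale, cfg.interaction_scale)
            )

    assignments = list(product(*cfg.substituent_sets))
    noise = (
        rng.normal(0.0, cfg.noise_sd, size=len(assignments))
        if cfg.noise_sd > 0
        else np.zeros(len(assignments))
    )
    universe = ToyUniverse(
        config=cfg,
        seed=seed,
        contributions=contributions,
        interactions=interactions,
        molecules=(),
        assignments=tuple(assignments),
    )
    molecules, index = [], {}
    for i, assignment in enumerate(assignments):
        raw = cfg.scaffold.format(*assignment)
        std = standardize_smiles(raw)
        if isinstance(std, Rejection):
            raise ValueError(
                f"invalid enumerant {raw!r} ({std.reason}); check scaffold/fragments"
            )
        potency = universe.additive_potency(assignment) + float(noise[i])
        rec = MoleculeRecord(
            smiles_canonical=std.smiles_canonical, potency_p=potency,
            series_id="toy",
        )
        if std.smiles_canonical not in index:
            index[std.smiles_canonical] = len(molecules)
            molecules.append(rec)
    return ToyUniverse(
        config=cfg,
        seed=seed,
        contributions=contributions,
        interactions=interactions,
        molecules=tuple(molecules),
        assignments=tuple(assignments),
        _index=index,
    )


def toy_potency(universe: ToyUniverse, molecule: str | MoleculeRecord) -> float:
    """Pseudo-potency of a universe member; non-members raise ValueError."""
    smiles = (
        molecule.smiles_canonical
        if isinstance(molecule, MoleculeRecord)
        else molecule
    )
    std = standardize_smiles(smiles)
    key = std.smiles_canonical if not isinstance(std, Rejection) else smiles
    if key not in universe._index:
        raise ValueError(f"{smiles!r} is not a member of this universe")
    return universe.molecules[universe._index[key]].potency_p


# ---------------------------------------------------------------------------
# background corpus

_BG_TEMPLATES = (
    "c1cc({0})ccc1{1}",
    "c1cc({0})cnc1{1}",
    "c1cnc({0})nc1{1}",
    "c1cc({0})co1",
    "c1cc({0})cs1",
    "C1CCC({0})CC1",
    "C1CCN({0})CC1",
    "c1ccc2c(c1)CCC2{0}",
    "C({0})C(=O)N{1}",
    "C({0})C(=O)O",
)

_BG_FRAGMENTS = (
    "C", "CC", "CCC", "CCCC", "C(C)C", "CO", "CCO", "OC", "OCC", "N", "NC",
    "NCC", "CN", "C(=O)O", "C(=O)N", "C(=O)NC", "CC(=O)O", "Cl", "F", "Br",
    "C(F)(F)F", "C#N", "O", "CCN(C)C", "c1ccccc1", "Cc1ccccc1", "OCc1ccccc1",
    "S(=O)(=O)N", "S(=O)(=O)NC", "NS(C)(=O)=O", "CNC(C)=O",
)


def generate_background_corpus(n: int, seed: int) -> list:
    """Random scaffold-diverse decorated molecules for toy pretraining.

    Molecules are assembled from a template/fragment grammar disjoint from
    the toy scaffold, standardized and deduplicated.
    """
    rng = np.random.default_rng(seed)
    corpus: dict = {}
    attempts = 0
    while len(corpus) < n and attempts < n * 100:
        attempts += 1
        template = _BG_TEMPLATES[rng.integers(len(_BG_TEMPLATES))]
        n_slots = template.count("{")
        frags = [
            _BG_FRAGMENTS[rng.integers(len(_BG_FRAGMENTS))] for _ in range(n_slots)
        ]
        std = standardize_smiles(template.format(*frags))
        if isinstance(std, Rejection):
            continue
        if std.smiles_canonical not in corpus:
            corpus[std.smiles_canonical] = MoleculeRecord(
                smiles_canonical=std.smiles_canonical
            )
    if len(corpus) < n:
        raise ValueError(f"could only generate {len(corpus)} of {n} corpus molecules")
    return list(corpus.values())


@dataclass(frozen=True)
class ToyBenchmark:
    universe: ToyUniverse
    pretrain_corpus: tuple
    series: SarSeries
    truth: tuple  # top-25% most potent series members (the holdout)
    ignorance_report: dict


def build_toy_benchmark(
    universe: ToyUniverse,
    series_size: int = 60,
    corpus_size: int = 2000,
    seed: int = 0,
    min_span: float = 2.0,
    holdout_fraction: float = 0.25,
) -> ToyBenchmark:
    """Sample a SAR series and a target-ignorant pretraining corpus.

    The series must span at least ``min_span`` log units of pseudo-potency;
    the corpus is filtered so no member has Tanimoto similarity > 0.4
    (Morgan radius 2, 2048-bit) to any series molecule.
    """
    if series_size > len(universe):
        raise ValueError("series_size exceeds the universe size")
    rng = np.random.default_rng(seed)
    series = None
    for _ in range(50):
        idx = rng.choice(len(universe), size=series_size, replace=False)
        records = [universe.molecules[i] for i in idx]
        potencies = [r.potency_p for r in records]
        if max(potencies) - min(potencies) >= min_span:
            series = SarSeries.from_records("toy-series", records)
            break
    if series is None:
        raise ValueError(
            f"universe potency landscape cannot span {min_span} log units "
            f"with series_size={series_size}"
        )
    raw_corpus = generate_background_corpus(
        int(corpus_size * 1.2) + 20, seed=seed + 1
    )
    corpus, report = filter_reference_corpus(
        raw_corpus, list(series.records), sim_threshold=0.4, radius=2
    )
    if len(corpus) < corpus_size:
        raise ValueError("not enough corpus molecules after the ignorance filter")
    corpus = corpus[:corpus_size]
    _, truth = extract_holdout(series, holdout_fraction)
    return ToyBenchmark(
        universe=universe,
        pretrain_corpus=tuple(corpus),
        series=series,
        truth=tuple(truth),
        ignorance_report=report,
    )


def benchmark_vocabulary(benchmark: ToyBenchmark):
    """Token vocabulary covering the pretraining corpus and the series."""
    return build_vocabulary(
        [m.smiles_canonical for m in benchmark.pretrain_corpus]
        + benchmark.series.smiles
    )
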