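"""Design generation: temperature sampling, perplexity, ranking and filtering.

Designs are drawn token-by-token by multinomial sampling from the softmax
of the model logits divided by a temperature T (default 1.0), up to 140
tokens. Each design is scored by perplexity,

    PPL = exp(-(1/N) * sum_i log q_i),

the exponential of the mean negative log probability of the realized
tokens, where the realized tokens are the chemical tokens plus the
terminating end sentinel and N counts those scored positions. Lower
perplexity means the model considers the design more probable; ranking is
ascending by PPL. A configurable filter cascade then removes designs that
are trivially explained by the pretraining corpus (naive-model perplexity
floor), already known, derivable from the training data (substructures,
isomers, high similarity), or structurally undesirable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from . import nn
from .chem_io import (
    MoleculeRecord,
    Rejection,
    randomize_smiles,
    standardize_smiles,
    tokenize,
)
from .clm_engine import ModelState, encode_batch

__all__ = [
    "DesignSample",
    "DesignSet",
    "FilterConfig",
    "softmax_with_temperature",
    "sample_designs",
    "perplexity_from_probs",
    "sequence_perplexity",
    "sequence_perplexities",
    "rank_designs",
    "filter_designs",
]


def softmax_with_temperature(logits: np.ndarray, temperature: float) -> np.ndarray:
    """Sampling distribution q_i = exp(z_i/T) / sum_j exp(z_j/T).

    Strictly positive and sums to 1 along the last axis.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    z = np.asarray(logits, dtype=float) / temperature
    z = z - z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


@dataclass(frozen=True)
class DesignSample:
    """One unique sampled molecule with its sampling frequency and score."""

    smiles_canonical: str
    frequency: int
    perplexity: float | None = None
    rank: int | None = None


@dataclass(frozen=True)
class DesignSet:
    """Aggregated output of one sampling run.

    ``samples`` holds unique valid molecules (canonical after
    standardization) with their raw sampling frequencies; invalid emissions
    are counted, not kept. Strings that hit the length cap without emitting
    the end sentinel count as invalid.
    """

    samples: tuple
    n_requested: int
    n_emitted: int
    n_invalid: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_valid(self) -> int:
        return self.n_emitted - self.n_invalid

    @property
    def smiles(self) -> list:
        return [s.smiles_canonical for s in self.samples]


def sample_designs(
    state: ModelState,
    n: int,
    temperature: float = 1.0,
    max_len: int = 140,
    seed: int = 0,
    batch_size: int = 256,
) -> DesignSet:
    """Draw ``n`` SMILES strings from the model by multinomial sampling.

    Generation proceeds token-by-token until the end sentinel or
    ``max_len`` tokens; unfinished or unparsable strings are counted as
    invalid. Valid strings are standardized and aggregated by canonical
    SMILES into frequencies. Fully seed-reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    vocab = state.config.vocab
    spec = state.config.net_spec("randomized")  # no dropout at sampling time
    rng = np.random.default_rng(seed)
    counts: dict = {}
    n_invalid = 0
    remaining = n
    while remaining > 0:
        b = min(batch_size, remaining)
        remaining -= b
        tokens = np.full(b, vocab.start_index, dtype=np.int64)
        hc = nn.init_step_state(spec, b)
        active = np.ones(b, dtype=bool)
        emitted = [[] for _ in range(b)]
        finished = np.zeros(b, dtype=bool)
        for _ in range(max_len + 1):
            logits, hc = nn.step(state.params, spec, tokens, hc, state.bn_stats)
            q = softmax_with_temperature(logits, temperature)
            # one multinomial draw per active sequence
            u = rng.random(b)
            draws = (q.cumsum(axis=1) < u[:, None]).sum(axis=1)
            draws = np.minimum(draws, vocab.size - 1)
            for i in range(b):
                if not active[i]:
                    continue
                d = int(draws[i])
                if d == vocab.end_index:
                    active[i] = False
                    finished[i] = True
                elif d in (vocab.pad_index, vocab.start_index):
                    active[i] = False  # degenerate emission -> invalid
                else:
                    emitted[i].append(vocab.tokens[d])
                    if len(emitted[i]) >= max_len:
                        active[i] = False
            tokens = draws
            if not active.any():
                break
        for i in range(b):
            if not finished[i] or not emitted[i]:
                n_invalid += 1
                continue
            raw = "".join(emitted[i])
            std = standardize_smiles(raw)
            if isinstance(std, Rejection):
                n_invalid += 1
                continue
            try:
                # canonicalization may introduce bracket tokens the model
                # vocabulary lacks; such designs cannot be scored
                tokenize(std.smiles_canonical, vocab)
            except KeyError:
                n_invalid += 1
                continue
            counts[std.smiles_canonical] = counts.get(std.smiles_canonical, 0) + 1
    samples = tuple(
        DesignSample(smiles_canonical=s, frequency=f)
        for s, f in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    return DesignSet(
        samples=samples,
        n_requested=n,
        n_emitted=n,
        n_invalid=n_invalid,
        provenance={"temperature": temperature, "seed": seed, "epoch": state.epoch},
    )


def perplexity_from_probs(probs: Sequence[float]) -> float:
    """PPL = exp(-mean(log q_i)) over the realized token probabilities."""
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        raise ValueError("need at least one probability")
    if np.any(probs <= 0) or np.any(probs > 1):
        raise ValueError("probabilities must be in (0, 1]")
    return float(np.exp(-np.mean(np.log(probs))))


def sequence_perplexities(
    state: ModelState,
    smiles_list: Sequence[str],
    n_augment: int = 1,
    seed: int = 0,
    batch_size: int = 256,
) -> np.ndarray:
    """Perplexity of each SMILES under the model (teacher-forced, eval mode).

    The scored tokens are the chemical tokens plus the end sentinel. With
    ``n_augment > 1``, each molecule is rewritten as that many randomized
    SMILES and the perplexities are arithmetically averaged.
    """
    spec = state.config.net_spec("randomized")
    vocab = state.config.vocab

    def _ppl_batch(batch: Sequence[str]) -> np.ndarray:
        X, Y = encode_batch(batch, vocab, state.config.max_len)
        logp, counts = nn.sequence_log_probs(state.params, spec, X, Y,
                                             state.bn_stats)
        return np.exp(-logp / np.maximum(counts, 1))

    if n_augment <= 1:
        out = np.empty(len(smiles_list))
        for start in range(0, len(smiles_list), batch_size):
            out[start : start + batch_size] = _ppl_batch(
                smiles_list[start : start + batch_size]
            )
        return out

    rng = np.random.default_rng(seed)
    out = np.empty(len(smiles_list))
    for i, smiles in enumerate(smiles_list):
        forms = randomize_smiles(smiles, n_augment, int(rng.integers(2**31)))
        out[i] = float(np.mean(_ppl_batch(forms)))
    return out


def sequence_perplexity(
    state: ModelState, smiles: str, n_augment: int = 1, seed: int = 0
) -> float:
    """Perplexity of a single SMILES; see :func:`sequence_perplexities`."""
    tokenize(smiles, state.config.vocab)  # raises UnknownTokenError early
    return float(sequence_perplexities(state, [smiles], n_augment, seed)[0])


def rank_designs(
    designs: DesignSet,
    state: ModelState,
    variant: str = "canonical",
    training_set: Iterable[str] = (),
    n_augment: int | None = None,
    seed: int = 0,
) -> DesignSet:
    """Score and rank a design set by ascending perplexity.

    Members of the fine-tuning set are removed (invalids and duplicates are
    already handled at sampling time). For the augmented and randomized
    variants the perplexity is the mean over 10 randomized SMILES forms.
    Ties are broken by higher sampling frequency, then lexicographically.
    """
    training = set(training_set)
    kept = [s for s in designs.samples if s.smiles_canonical not in training]
    if not kept:
        warnings.warn("no designs left after removing fine-tuning molecules")
        return replace(designs, samples=())
    if n_augment is None:
        n_augment = 10 if variant in ("augmented", "randomized") else 1
    ppls = sequence_perplexities(
        state, [s.smiles_canonical for s in kept], n_augment=n_augment, seed=seed
    )
    scored = [replace(s, perplexity=float(p)) for s, p in zip(kept, ppls)]
    scored.sort(key=lambda s: (s.perplexity, -s.frequency, s.smiles_canonical))
    ranked = tuple(replace(s, rank=i + 1) for i, s in enumerate(scored))
    return replace(designs, samples=ranked)


@dataclass(frozen=True)
class FilterConfig:
    """Design-filter cascade configuration.

    With the defaults only the naive-perplexity floor applies. The 1.012
    floor is corpus-specific; it mirrors the threshold calibrated on the
    reference pretraining corpus and should be recalibrated per corpus.
    """

    min_naive_perplexity: float = 1.012
    known_sets: tuple = ()
    baseline_top: tuple = ()
    remove_substructures_isomers: bool = False
    max_similarity: float | None = None
    similarity_radius: int = 3
    substructure_blacklist: tuple = ()
    max_ring_size: int | None = None
    priority_pattern: str | None = None


def _mol(smiles: str):
    return Chem.MolFromSmiles(smiles)


def filter_designs(
    ranked: DesignSet,
    naive: ModelState,
    cfg: FilterConfig = FilterConfig(),
    training: Sequence[MoleculeRecord] | Sequence[str] = (),
) -> tuple:
    """Apply the prospective design-filter cascade, logging every removal.

    Rules, in order: (1) naive-model perplexity below the floor; (2) member
    of a known reference set; (3) member of the classical-baseline top
    list; (4) substructure or isomer (same molecular formula) of a training
    molecule; (5) maximum Tanimoto similarity to training above the cap;
    (6) blacklist substructure or oversized ring; (7) designs matching the
    priority pattern are stably moved to the front. Returns
    ``(filtered_set, removal_log)``; each removal is attributed to exactly
    one rule.
    """
    from .chem_io import bulk_max_similarity

    train_smiles = [
        t.smiles_canonical if isinstance(t, MoleculeRecord) else t for t in training
    ]
    known = set()
    for ks in cfg.known_sets:
        known.update(ks if not isinstance(ks, str) else [ks])
    baseline = set(cfg.baseline_top)

    removal_log: list = []
    survivors = list(ranked.samples)

    if survivors:
        naive_ppls = sequence_perplexities(
            naive, [s.smiles_canonical for s in survivors]
        )
        kept = []
        for s, p in zip(survivors, naive_ppls):
            if p < cfg.min_naive_perplexity:
                removal_log.append((s.smiles_canonical, "naive-perplexity-floor"))
            else:
                kept.append(s)
        survivors = kept

    if known:
        kept = []
        for s in survivors:
            if s.smiles_canonical in known:
                removal_log.append((s.smiles_canonical, "known-molecule"))
            else:
                kept.append(s)
        survivors = kept

    if baseline:
        kept = []
        for s in survivors:
            if s.smiles_canonical in baseline:
                removal_log.append((s.smiles_canonical, "classical-baseline-top"))
            else:
                kept.append(s)
        survivors = kept

    if cfg.remove_substructures_isomers and train_smiles and survivors:
        train_mols = [_mol(t) for t in train_smiles]
        train_formulas = {rdMolDescriptors.CalcMolFormula(m) for m in train_mols}
        kept = []
        for s in survivors:
            mol = _mol(s.smiles_canonical)
            formula = rdMolDescriptors.CalcMolFormula(mol)
            if formula in train_formulas:
                removal_log.append((s.smiles_canonical, "isomer-of-training"))
                continue
            if any(tm.HasSubstructMatch(mol) for tm in train_mols):
                removal_log.append((s.smiles_canonical, "substructure-of-training"))
                continue
            kept.append(s)
        survivors = kept

    if cfg.max_similarity is not None and train_smiles and survivors:
        sims = bulk_max_similarity(
            [s.smiles_canonical for s in survivors],
            train_smiles,
            radius=cfg.similarity_radius,
        )
        kept = []
        for s, sim in zip(survivors, sims):
            if sim > cfg.max_similarity:
                removal_log.append((s.smiles_canonical, "training-similarity"))
            else:
                kept.append(s)
        survivors = kept

    if (cfg.substructure_blacklist or cfg.max_ring_size) and survivors:
        patterns = [Chem.MolFromSmarts(p) for p in cfg.substructure_blacklist]
        kept = []
        for s in survivors:
            mol = _mol(s.smiles_canonical)
            if any(mol.HasSubstructMatch(p) for p in patterns if p is not None):
                removal_log.append((s.smiles_canonical, "blacklist-substructure"))
                continue
            if cfg.max_ring_size is not None and any(
                len(ring) > cfg.max_ring_size
                for ring in mol.GetRingInfo().AtomRings()
            ):
                removal_log.append((s.smiles_canonical, "oversized-ring"))
                continue
            kept.append(s)
        survivors = kept

    if cfg.priority_pattern and survivors:
        pattern = Chem.MolFromSmarts(cfg.priority_pattern)
        matches = [s for s in survivors
                   if _mol(s.smiles_canonical).HasSubstructMatch(pattern)]
        rest = [s for s in survivors
                if not _mol(s.smiles_canonical).HasSubstructMatch(pattern)]
        survivors = matches + rest

    survivors = [replace(s, rank=i + 1) for i, s in enumerate(survivors)]
    return replace(ranked, samples=tuple(survivors)), removal_log
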