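"""Rediscovery scoring, sampling statistics, distributional similarity and
the retrospective benchmark harness.

The rediscovery score quantifies whether a fine-tuned model re-designs the
withheld most-potent members of a SAR series. With N_R rediscovered holdout
molecules among the top-k (default 30) perplexity-ranked designs, sampling
frequency mass F, and holdout size N_hold, the score is the product of
three factors,

    score = (N_R / k) * (sum F_R / sum F_k) * (N_R / N_hold),

bounded in [0, 1], zero exactly when nothing is rediscovered, and balancing
the extreme cases of many rarely-sampled hits versus a single
frequently-sampled hit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .chem_io import MoleculeRecord, Rejection, morgan_fingerprint, standardize_smiles
from .generator import DesignSet
from .sar_curation import SarSeries

__all__ = [
    "RediscoveryResult",
    "SamplingStats",
    "DistributionalSimilarity",
    "CorrelationResult",
    "rediscovery_score",
    "sampling_statistics",
    "sampling_statistics_from_strings",
    "fcd_similarity",
    "kl_similarity",
    "potency_perplexity_correlation",
    "run_retrospective_benchmark",
    "BenchmarkResult",
]


@dataclass(frozen=True)
class RediscoveryResult:
    n_rediscovered: int
    freq_rediscovered: int
    freq_top: int
    n_holdout: int
    top_k: int
    score: float


def rediscovery_score(
    ranked: DesignSet | Sequence,
    holdout: Sequence[MoleculeRecord] | Sequence[str],
    top_k: int = 30,
) -> RediscoveryResult:
    """Composite rediscovery score of the top-k ranked designs vs the holdout.

    ``ranked`` may be a ranked :class:`DesignSet` or a list of
    ``(smiles, frequency)`` pairs in rank order. If fewer than ``top_k``
    designs exist, all are used but the first factor's denominator stays
    ``top_k``.
    """
    if not holdout:
        raise ValueError("holdout set is empty")
    holdout_smiles = {
        h.smiles_canonical if isinstance(h, MoleculeRecord) else h for h in holdout
    }
    if isinstance(ranked, DesignSet):
        pairs = [(s.smiles_canonical, s.frequency) for s in ranked.samples]
    else:
        pairs = list(ranked)
    top = pairs[:top_k]
    n_r = sum(1 for s, _ in top if s in holdout_smiles)
    f_r = sum(f for s, f in top if s in holdout_smiles)
    f_top = sum(f for _, f in top)
    if n_r == 0 or f_top == 0:
        score = 0.0
    else:
        score = (n_r / top_k) * (f_r / f_top) * (n_r / len(holdout_smiles))
    return RediscoveryResult(
        n_rediscovered=n_r,
        freq_rediscovered=f_r,
        freq_top=f_top,
        n_holdout=len(holdout_smiles),
        top_k=top_k,
        score=score,
    )


@dataclass(frozen=True)
class SamplingStats:
    validity: float
    uniqueness: float
    novelty: float


def sampling_statistics_from_strings(
    emitted: Sequence[str], training: Iterable[str]
) -> SamplingStats:
    """Validity/uniqueness/novelty of raw emitted strings.

    Validity = parsable / total emitted; uniqueness = unique canonical /
    valid; novelty = fraction of unique molecules absent from the training
    set (training SMILES are canonicalized for comparison).
    """
    if not emitted:
        raise ValueError("no emitted strings")
    valid: list = []
    for s in emitted:
        std = standardize_smiles(s)
        if not isinstance(std, Rejection):
            valid.append(std.smiles_canonical)
    if not valid:
        raise ValueError("no valid molecules among the emitted strings")
    train_canonical = set()
    for t in training:
        std = standardize_smiles(t)
        if not isinstance(std, Rejection):
            train_canonical.add(std.smiles_canonical)
    unique = sorted(set(valid))
    novel = [u for u in unique if u not in train_canonical]
    return SamplingStats(
        validity=len(valid) / len(emitted),
        uniqueness=len(unique) / len(valid),
        novelty=len(novel) / len(unique),
    )


def sampling_statistics(designs: DesignSet, training: Iterable[str]) -> SamplingStats:
    """Validity/uniqueness/novelty of a sampling run (aggregated counts)."""
    if designs.n_emitted == 0:
        raise ValueError("no emitted strings")
    if designs.n_valid == 0:
        raise ValueError("no valid molecules among the emitted strings")
    train_canonical = set()
    for t in training:
        t = t.smiles_canonical if isinstance(t, MoleculeRecord) else t
        std = standardize_smiles(t)
        if not isinstance(std, Rejection):
            train_canonical.add(std.smiles_canonical)
    unique = designs.smiles
    novel = [u for u in unique if u not in train_canonical]
    return SamplingStats(
        validity=designs.n_valid / designs.n_emitted,
        uniqueness=len(unique) / designs.n_valid,
        novelty=len(novel) / len(unique) if unique else 0.0,
    )


def fcd_similarity(fcd_value: float) -> float:
    """S_FCD = exp(-0.2 * FCD); 1 exactly when the FCD is 0."""
    if fcd_value < 0:
        raise ValueError("FCD must be non-negative")
    return float(math.exp(-0.2 * fcd_value))


def aggregate_kl(kl_values) -> float:
    """S_KL = (1/D) * sum_d exp(-KL_d) over the descriptor divergences."""
    values = list(kl_values)
    if not values:
        raise ValueError("no divergences to aggregate")
    return float(np.mean([math.exp(-v) for v in values]))


@dataclass(frozen=True)
class DistributionalSimilarity:
    kl_per_descriptor: dict
    s_kl: float
    fcd: float | None = None
    s_fcd: float | None = None


_CONTINUOUS = {
    "bertz": lambda m: Descriptors.BertzCT(m),
    "logp": lambda m: Crippen.MolLogP(m),
    "mol_weight": lambda m: Descriptors.MolWt(m),
    "tpsa": lambda m: rdMolDescriptors.CalcTPSA(m),
}
_DISCRETE = {
    "hbond_acceptors": lambda m: rdMolDescriptors.CalcNumHBA(m),
    "hbond_donors": lambda m: rdMolDescriptors.CalcNumHBD(m),
    "rotatable_bonds": lambda m: rdMolDescriptors.CalcNumRotatableBonds(m),
    "aliphatic_rings": lambda m: rdMolDescriptors.CalcNumAliphaticRings(m),
    "aromatic_rings": lambda m: rdMolDescriptors.CalcNumAromaticRings(m),
}

_KL_EPS = 1e-10


def _max_internal_tanimoto(smiles: Sequence[str]) -> np.ndarray:
    fps = [morgan_fingerprint(s, radius=2, nbits=2048) for s in smiles]
    out = np.zeros(len(fps))
    for i, fp in enumerate(fps):
        others = fps[:i] + fps[i + 1 :]
        if others:
            out[i] = max(DataStructs.BulkTanimotoSimilarity(fp, others))
    return out


def _kl_discrete(p_counts: np.ndarray, q_counts: np.ndarray) -> float:
    p = p_counts / p_counts.sum() + _KL_EPS
    q = q_counts / q_counts.sum() + _KL_EPS
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


def _kl_continuous(gen: np.ndarray, ref: np.ndarray, grid_points: int = 1000) -> float:
    from scipy.stats import gaussian_kde

    lo = min(gen.min(), ref.min())
    hi = max(gen.max(), ref.max())
    margin = 0.1 * (hi - lo) if hi > lo else 1.0
    grid = np.linspace(lo - margin, hi + margin, grid_points)
    try:
        p = gaussian_kde(gen)(grid)
        q = gaussian_kde(ref)(grid)
    except np.linalg.LinAlgError:
        raise ValueError("degenerate")
    return _kl_discrete(p, q)


def _histogram_kl(gen: np.ndarray, ref: np.ndarray, bins: int = 10) -> float:
    lo = min(gen.min(), ref.min())
    hi = max(gen.max(), ref.max())
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi + 1e-9, bins + 1)
    p, _ = np.histogram(gen, bins=edges)
    q, _ = np.histogram(ref, bins=edges)
    return _kl_discrete(p.astype(float), q.astype(float))


def kl_similarity(
    generated: Sequence, reference: Sequence, fcd_value: float | None = None
) -> DistributionalSimilarity:
    """Descriptor-panel KL similarity S_KL = (1/D) sum_d exp(-KL_d).

    The panel covers Bertz complexity, logP, molecular weight, TPSA
    (continuous; Gaussian KDE on a shared grid), hydrogen-bond acceptors
    and donors, rotatable bonds, aliphatic and aromatic ring counts
    (discrete; shared 10-bin histograms) and the maximum internal Tanimoto
    similarity (Morgan radius 2, 2048-bit; continuous). The divergence is
    KL(generated || reference) with a 1e-10 density floor. A continuous
    descriptor with zero variance falls back to the histogram estimate with
    a warning.
    """
    if not len(generated) or not len(reference):
        raise ValueError("both molecule lists must be non-empty")

    def smiles_of(items):
        return [
            i.smiles_canonical if isinstance(i, MoleculeRecord) else i for i in items
        ]

    gen_smiles, ref_smiles = smiles_of(generated), smiles_of(reference)
    gen_mols = [Chem.MolFromSmiles(s) for s in gen_smiles]
    ref_mols = [Chem.MolFromSmiles(s) for s in ref_smiles]
    if any(m is None for m in gen_mols + ref_mols):
        raise ValueError("all molecules must be valid SMILES")

    kl: dict = {}
    for name, fn in _CONTINUOUS.items():
        g = np.array([fn(m) for m in gen_mols], dtype=float)
        r = np.array([fn(m) for m in ref_mols], dtype=float)
        if g.std() == 0 or r.std() == 0:
            warnings.warn(f"descriptor {name} degenerate; histogram fallback")
            kl[name] = _histogram_kl(g, r)
        else:
            try:
                kl[name] = _kl_continuous(g, r)
            except ValueError:
                warnings.warn(f"descriptor {name} degenerate; histogram fallback")
                kl[name] = _histogram_kl(g, r)
    g = _max_internal_tanimoto(gen_smiles)
    r = _max_internal_tanimoto(ref_smiles)
    if g.std() == 0 or r.std() == 0:
        kl["max_internal_similarity"] = _histogram_kl(g, r)
    else:
        try:
            kl["max_internal_similarity"] = _kl_continuous(g, r)
        except ValueError:
            kl["max_internal_similarity"] = _histogram_kl(g, r)
    for name, fn in _DISCRETE.items():
        g = np.array([fn(m) for m in gen_mols], dtype=float)
        r = np.array([fn(m) for m in ref_mols], dtype=float)
        kl[name] = _histogram_kl(g, r)

    s_kl = aggregate_kl(kl.values())
    s_fcd = fcd_similarity(fcd_value) if fcd_value is not None else None
    return DistributionalSimilarity(
        kl_per_descriptor=kl, s_kl=s_kl, fcd=fcd_value, s_fcd=s_fcd
    )


@dataclass(frozen=True)
class CorrelationResult:
    slope: float
    p_value: float
    r_squared: float
    degenerate: bool = False


def potency_perplexity_correlation(
    records: Sequence[MoleculeRecord], perplexities: Sequence[float]
) -> CorrelationResult:
    """OLS of -log10 potency on mean perplexity (slope, two-sided p, R^2)."""
    import statsmodels.api as sm

    potencies = np.array([r.potency_p for r in records], dtype=float)
    ppl = np.asarray(perplexities, dtype=float)
    if potencies.size != ppl.size or potencies.size < 3:
        raise ValueError("need >= 3 paired (potency, perplexity) observations")
    if np.ptp(ppl) == 0:
        warnings.warn("constant perplexity; slope undefined")
        return CorrelationResult(slope=0.0, p_value=1.0, r_squared=0.0,
                                 degenerate=True)
    model = sm.OLS(potencies, sm.add_constant(ppl)).fit()
    return CorrelationResult(
        slope=float(model.params[1]),
        p_value=float(model.pvalues[1]),
        r_squared=float(model.rsquared),
    )


@dataclass(frozen=True)
class BenchmarkResult:
    scores: dict  # strategy -> list of per-repeat scores
    traces: dict  # strategy -> list of per-repeat holdout-perplexity traces
    stats: dict  # strategy -> list of per-repeat SamplingStats


def run_retrospective_benchmark(
    naive,
    series: SarSeries,
    strategies: Sequence[str] = ("all", "values"),
    n_samples: int = 2048,
    finetune_repeats: int = 5,
    sampling_repeats: int = 5,
    k: int = 4,
    top_k: int = 30,
    holdout_fraction: float = 0.25,
    naive_ppl_floor: float = 1.012,
    stage_params=None,
    seed: int = 0,
) -> BenchmarkResult:
    """Retrospective rediscovery benchmark over splitting strategies.

    For each strategy and fine-tuning repeat: withhold the most potent
    ``holdout_fraction`` of the series, split the remainder, incrementally
    fine-tune the naive model, sample ``n_samples`` designs
    ``sampling_repeats`` times, apply the naive-perplexity floor, rank by
    perplexity and score rediscovery of the holdout in the top ``top_k``.
    """
    from .clm_engine import StageParams, incremental_finetune
    from .generator import FilterConfig, filter_designs, rank_designs, sample_designs
    from .sar_curation import extract_holdout, split_series

    if stage_params is None:
        stage_params = StageParams()
    training_series, holdout = extract_holdout(series, holdout_fraction)
    train_smiles = set(training_series.smiles)
    scores: dict = {s: [] for s in strategies}
    traces: dict = {s: [] for s in strategies}
    stats: dict = {s: [] for s in strategies}
    rng = np.random.default_rng(seed)
    for strategy in strategies:
        for rep in range(finetune_repeats):
            rep_seed = int(rng.integers(2**31))
            split = split_series(training_series, strategy, k=k, seed=rep_seed,
                                 holdout=holdout)
            model, _, trace = incremental_finetune(
                naive, split, stage_params=stage_params, seed=rep_seed,
                holdout=holdout,
            )
            traces[strategy].append(trace)
            rep_scores = []
            for s_rep in range(sampling_repeats):
                designs = sample_designs(
                    model, n=n_samples, seed=rep_seed + 7919 * (s_rep + 1)
                )
                if designs.n_valid > 0:
                    stats[strategy].append(
                        sampling_statistics(designs, training=train_smiles)
                    )
                ranked = rank_designs(
                    designs, model, variant=stage_params.variant,
                    training_set=train_smiles,
                )
                if naive_ppl_floor is not None:
                    ranked, _ = filter_designs(
                        ranked, naive,
                        FilterConfig(min_naive_perplexity=naive_ppl_floor),
                    )
                rep_scores.append(rediscovery_score(ranked, holdout, top_k).score)
            scores[strategy].append(float(np.mean(rep_scores)))
    return BenchmarkResult(scores=scores, traces=traces, stats=stats)
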