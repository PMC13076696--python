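"""Training engine: pretraining and incremental fine-tuning of the SMILES LSTM.

The model is an autoregressive next-token network (embedding -> optional
batch normalization -> stacked LSTM layers -> optional batch normalization
-> dense projection to vocabulary logits), trained with Adam on masked
categorical cross-entropy under teacher forcing.

Three training variants are supported:

- ``canonical``  — one canonical SMILES per molecule, dropout active,
  learning-rate reduction on plateau (factor 0.5, patience 3, floor);
- ``augmented``  — ten randomized SMILES per molecule, fixed up front,
  same schedule as canonical;
- ``randomized`` — one fresh random SMILES per molecule re-drawn every
  epoch, no dropout, constant learning rate; checkpoint selection uses a
  10-epoch moving average of the validation loss instead of the raw argmin.

Each stage returns the model restored (weights *and* optimizer state) to
the epoch selected by its variant's rule; incremental fine-tuning chains
stages over potency-ordered subsets, carrying the restored state forward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .chem_io import (
    MoleculeRecord,
    TokenVocabulary,
    randomize_smiles,
    tokenize,
)
from .sar_curation import PotencySplit

__all__ = [
    "ModelConfig",
    "ModelState",
    "TrainLog",
    "StageParams",
    "PlateauConfig",
    "PlateauScheduler",
    "build_model",
    "train_stage",
    "incremental_finetune",
    "select_pretrain_epoch",
    "select_best_epoch",
    "select_best_epoch_smoothed",
    "encode_batch",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("canonical", "augmented", "randomized")
MOVING_AVERAGE_WINDOW = 10
N_AUGMENT = 10


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training-loop configuration.

    Defaults follow the reference architecture (64-dim embedding, LSTM
    stack 1024+256 with batch normalization); toy-scale runs shrink
    ``embedding_dim`` and ``recurrent_layers``.
    """

    vocab: TokenVocabulary
    embedding_dim: int = 64
    recurrent_layers: tuple = (1024, 256)
    use_batchnorm: bool = True
    dropout: float = 0.2
    batch_size: int = 128
    max_len: int = 140

    def net_spec(self, variant: str = "canonical") -> nn.NetSpec:
        eff_dropout = 0.0 if variant == "randomized" else self.dropout
        return nn.NetSpec(
            vocab_size=self.vocab.size,
            embedding_dim=self.embedding_dim,
            recurrent_layers=tuple(self.recurrent_layers),
            use_batchnorm=self.use_batchnorm,
            dropout=eff_dropout,
        )


@dataclass
class ModelState:
    """Checkpointable model snapshot: weights, optimizer moments, epoch, lr."""

    config: ModelConfig
    params: dict
    opt: nn.AdamState
    bn_stats: dict
    epoch: int = 0
    learning_rate: float = 1e-3

    def copy(self) -> "ModelState":
        return ModelState(
            config=self.config,
            params={k: v.copy() for k, v in self.params.items()},
            opt=self.opt.copy(),
            bn_stats={k: v.copy() for k, v in self.bn_stats.items()},
            epoch=self.epoch,
            learning_rate=self.learning_rate,
        )


@dataclass(frozen=True)
class PlateauConfig:
    """Learning-rate reduction on validation-loss plateau."""

    factor: float = 0.5
    patience: int = 3
    min_lr: float = 1e-4
    min_delta: float = 1e-4  # improvement below this counts as plateau


class PlateauScheduler:
    """Reduce-on-plateau: halve the rate after ``patience`` stagnant epochs.

    An epoch counts as stagnant when the validation loss fails to improve
    on the best seen by more than ``min_delta``; the rate never drops
    below ``min_lr``.
    """

    def __init__(self, initial_lr: float, config: PlateauConfig):
        self.lr = initial_lr
        self.config = config
        self.best = np.inf
        self.wait = 0

    def update(self, val_loss: float) -> float:
        if val_loss < self.best - self.config.min_delta:
            self.best = val_loss
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.config.patience:
                self.lr = max(self.config.min_lr, self.lr * self.config.factor)
                self.wait = 0
        return self.lr


@dataclass
class TrainLog:
    variant: str
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    learning_rate: list = field(default_factory=list)
    selected_epoch: int | None = None  # 1-based

    def append(self, train_loss: float, val_loss: float, lr: float) -> None:
        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            raise FloatingPointError("non-finite loss encountered")
        self.train_loss.append(train_loss)
        self.val_loss.append(val_loss)
        self.learning_rate.append(lr)


@dataclass(frozen=True)
class StageParams:
    """Per-stage training configuration for fine-tuning runs."""

    variant: str = "canonical"
    epochs: int = 100
    initial_lr: float = 1e-4
    plateau: PlateauConfig = PlateauConfig()
    val_fraction: float = 0.10


def build_model(config: ModelConfig, seed: int) -> ModelState:
    """Seed-reproducible weight initialization of a fresh model."""
    if config.vocab.size < 4:
        raise ValueError("empty vocabulary")
    spec = config.net_spec()
    return ModelState(
        config=config,
        params=nn.init_params(spec, seed),
        opt=nn.AdamState(),
        bn_stats=nn.init_bn_stats(spec),
        epoch=0,
        learning_rate=1e-3,
    )


def encode_batch(smiles_list: Sequence[str], vocab: TokenVocabulary,
                 max_len: int = 140) -> tuple:
    """Encode SMILES as padded teacher-forcing (inputs, targets) arrays.

    Sequence = start + tokens + end; inputs drop the final element, targets
    drop the first; both are post-padded with the pad index (0).
    """
    encoded = []
    for s in smiles_list:
        seq = tokenize(s, vocab)
        idx = [vocab.start_index] + list(seq.indices) + [vocab.end_index]
        encoded.append(idx[: max_len + 2])
    t_max = max(len(e) for e in encoded) - 1
    X = np.zeros((len(encoded), t_max), dtype=np.int64)
    Y = np.zeros((len(encoded), t_max), dtype=np.int64)
    for i, e in enumerate(encoded):
        X[i, : len(e) - 1] = e[:-1]
        Y[i, : len(e) - 1] = e[1:]
    return X, Y


def _epoch_pass(state: ModelState, spec: nn.NetSpec, smiles, rng, shuffle_rng):
    """One training epoch over `smiles`; returns mean masked loss."""
    order = shuffle_rng.permutation(len(smiles))
    bs = state.config.batch_size
    losses, weights = [], []
    for start in range(0, len(smiles), bs):
        batch = [smiles[i] for i in order[start : start + bs]]
        X, Y = encode_batch(batch, state.config.vocab, state.config.max_len)
        loss, grads = nn.loss_and_grads(
            state.params, spec, X, Y, state.bn_stats, train=True, dropout_rng=rng
        )
        nn.adam_step(state.params, grads, state.opt, state.learning_rate)
        losses.append(loss)
        weights.append((Y != 0).sum())
    return float(np.average(losses, weights=weights))


def _val_loss(state: ModelState, spec: nn.NetSpec, smiles) -> float:
    bs = state.config.batch_size
    losses, weights = [], []
    for start in range(0, len(smiles), bs):
        X, Y = encode_batch(smiles[start : start + bs], state.config.vocab,
                            state.config.max_len)
        losses.append(nn.eval_loss(state.params, spec, X, Y, state.bn_stats))
        weights.append((Y != 0).sum())
    return float(np.average(losses, weights=weights))


def select_best_epoch(val_losses: Sequence[float]) -> int:
    """1-based epoch minimizing validation loss (ties -> earliest)."""
    return int(np.argmin(val_losses)) + 1


def select_best_epoch_smoothed(val_losses: Sequence[float],
                               window: int = MOVING_AVERAGE_WINDOW) -> int:
    """1-based epoch selected via a trailing moving average of the loss.

    Among all trailing windows of ``window`` epochs (shortened to the trace
    length if fewer), the one with the lowest mean is chosen (ties ->
    earliest); within that window the epoch with the lowest raw loss is
    returned (ties -> earliest).
    """
    n = len(val_losses)
    w = min(window, n)
    means = [np.mean(val_losses[e - w : e]) for e in range(w, n + 1)]
    end = int(np.argmin(means)) + w  # 1-based end epoch of best window
    segment = val_losses[end - w : end]
    return (end - w) + int(np.argmin(segment)) + 1


def _training_smiles(records, variant: str, rng: np.random.Generator,
                     epoch: int | None = None):
    smiles = [
        r.smiles_canonical if isinstance(r, MoleculeRecord) else r for r in records
    ]
    if variant == "canonical":
        return smiles
    if variant == "augmented":
        out = []
        for s in smiles:
            out.extend(randomize_smiles(s, N_AUGMENT, int(rng.integers(2**31))))
        return out
    # randomized: one fresh form per molecule per epoch
    return [randomize_smiles(s, 1, int(rng.integers(2**31)))[0] for s in smiles]


def train_stage(
    state: ModelState,
    data: Sequence,
    variant: str = "canonical",
    epochs: int = 100,
    initial_lr: float | None = None,
    plateau: PlateauConfig | None = PlateauConfig(),
    val_fraction: float = 0.10,
    seed: int = 0,
    snapshot_callback=None,
) -> tuple:
    """Train for up to ``epochs`` epochs and restore the best checkpoint.

    ``data`` is a list of molecule records (or SMILES). A ``val_fraction``
    of the molecules is held out for validation (canonical forms). The
    returned state is the snapshot (weights + optimizer moments + learning
    rate) of the epoch selected by the variant's rule; with ``epochs=0``
    the input state is returned unchanged.

    ``initial_lr=None`` continues from the learning rate stored in the
    state (used when chaining fine-tuning stages). ``snapshot_callback``,
    if given, receives ``(epoch, state_copy)`` after every epoch.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown training variant {variant!r}")
    if not data:
        raise ValueError("training data is empty")
    log = TrainLog(variant=variant)
    if epochs == 0:
        return state.copy(), log

    rng = np.random.default_rng(seed)
    records = list(data)
    n_val = max(1, int(round(val_fraction * len(records))))
    if len(records) - n_val < 1:
        raise ValueError(
            f"{len(records)} molecules cannot support a {val_fraction:.0%} "
            "validation split"
        )
    order = rng.permutation(len(records))
    val_records = [records[i] for i in order[:n_val]]
    train_records = [records[i] for i in order[n_val:]]
    val_smiles = [
        r.smiles_canonical if isinstance(r, MoleculeRecord) else r
        for r in val_records
    ]

    work = state.copy()
    if initial_lr is not None:
        work.learning_rate = initial_lr
    spec = work.config.net_spec(variant)
    use_plateau = plateau is not None and variant in ("canonical", "augmented")
    window = min(MOVING_AVERAGE_WINDOW, epochs)

    fixed_train = None
    if variant in ("canonical", "augmented"):
        fixed_train = _training_smiles(train_records, variant, rng)

    best_state: ModelState | None = None
    best_raw = np.inf
    scheduler = PlateauScheduler(work.learning_rate, plateau) if use_plateau else None
    recent: list = []  # (epoch, val_loss, snapshot) trailing window (randomized)
    best_mean = np.inf

    for epoch in range(1, epochs + 1):
        smiles = (
            fixed_train
            if fixed_train is not None
            else _training_smiles(train_records, variant, rng, epoch)
        )
        train_loss = _epoch_pass(work, spec, smiles, rng, rng)
        val_loss = _val_loss(work, spec, val_smiles)
        work.epoch = epoch
        log.append(train_loss, val_loss, work.learning_rate)
        snap = work.copy()
        if snapshot_callback is not None:
            snapshot_callback(epoch, snap)

        if variant == "randomized":
            recent.append((epoch, val_loss, snap))
            if len(recent) > window:
                recent.pop(0)
            if len(recent) == window:
                mean = float(np.mean([v for _, v, _ in recent]))
                if mean < best_mean:
                    best_mean = mean
                    in_win = int(np.argmin([v for _, v, _ in recent]))
                    best_state = recent[in_win][2]
        else:
            if val_loss < best_raw:
                best_raw = val_loss
                best_state = snap
            if scheduler is not None:
                work.learning_rate = scheduler.update(val_loss)

    if variant == "randomized":
        log.selected_epoch = select_best_epoch_smoothed(log.val_loss, window)
    else:
        log.selected_epoch = select_best_epoch(log.val_loss)
    assert best_state is not None and best_state.epoch == log.selected_epoch
    return best_state, log


def incremental_finetune(
    naive: ModelState,
    split: PotencySplit,
    stage_params: StageParams = StageParams(),
    seed: int = 0,
    holdout: Sequence[MoleculeRecord] | None = None,
) -> tuple:
    """Sequential fine-tuning over the potency-ordered subsets of a split.

    Stage j trains on subset S_j starting from the restored checkpoint
    (weights and optimizer state) of stage j-1; the first stage continues
    from the pretrained (naive) state at ``stage_params.initial_lr``, and
    every later stage continues at the learning rate in effect at the
    restored epoch of the previous stage.

    Returns ``(final_state, logs, holdout_ppl_trace)`` where the trace
    holds the mean holdout perplexity after each stage (empty when no
    holdout is supplied).
    """
    if holdout is None:
        holdout = split.holdout
    state = naive
    logs: list = []
    trace: list = []
    rng = np.random.default_rng(seed)
    for j, subset in enumerate(split.subsets, start=1):
        if len(subset) < 2:
            raise ValueError(f"fine-tuning stage {j} has fewer than 2 molecules")
        lr = stage_params.initial_lr if j == 1 else None
        state, log = train_stage(
            state,
            list(subset),
            variant=stage_params.variant,
            epochs=stage_params.epochs,
            initial_lr=lr,
            plateau=stage_params.plateau,
            val_fraction=stage_params.val_fraction,
            seed=int(rng.integers(2**31)),
        )
        logs.append(log)
        if holdout:
            from .generator import sequence_perplexity

            ppls = [
                sequence_perplexity(state, h.smiles_canonical, n_augment=1)
                for h in holdout
            ]
            trace.append(float(np.mean(ppls)))
    return state, logs, trace


def select_pretrain_epoch(
    candidates: Sequence[ModelState],
    reference_sample: Sequence[str],
    n_designs: int = 10_000,
    min_validity: float = 0.9,
    temperature: float = 1.0,
    seed: int = 0,
) -> tuple:
    """Choose the naive checkpoint by sampling statistics + distributional similarity.

    Samples ``n_designs`` molecules from each candidate, computes
    validity/uniqueness/novelty and the descriptor-KL similarity S_KL
    against ``reference_sample``, and returns
    ``(best_state, metric_table)``. The composite rule: highest S_KL among
    candidates with validity >= ``min_validity``; if none qualify, highest
    validity wins; ties favor higher validity then earlier candidates.
    """
    from .evaluation import kl_similarity, sampling_statistics
    from .generator import sample_designs

    if not candidates:
        raise ValueError("no candidate checkpoints supplied")
    table = []
    for i, cand in enumerate(candidates):
        designs = sample_designs(cand, n=n_designs, temperature=temperature,
                                 seed=seed + i)
        try:
            stats = sampling_statistics(designs, training=reference_sample)
            validity = stats.validity
        except ValueError:
            stats = None
            validity = 0.0
        if stats is not None and designs.samples:
            skl = kl_similarity(
                [s.smiles_canonical for s in designs.samples], reference_sample
            ).s_kl
        else:
            skl = 0.0
        table.append(
            {
                "candidate": i,
                "epoch": cand.epoch,
                "validity": validity,
                "uniqueness": stats.uniqueness if stats else 0.0,
                "novelty": stats.novelty if stats else 0.0,
                "s_kl": skl,
            }
        )
    qualified = [row for row in table if row["validity"] >= min_validity]
    pool = qualified if qualified else table
    best = max(pool, key=lambda r: (r["s_kl"], r["validity"], -r["candidate"]))
    return candidates[best["candidate"]], table


# ---------------------------------------------------------------------------
# checkpoint I/O: binary weight file + JSON sidecar


def save_checkpoint(state: ModelState, path) -> None:
    path = Path(path)
    arrays = {f"p_{k}": v for k, v in state.params.items()}
    arrays.update({f"m_{k}": v for k, v in state.opt.m.items()})
    arrays.update({f"v_{k}": v for k, v in state.opt.v.items()})
    arrays.update({f"s_{k}": v for k, v in state.bn_stats.items()})
    np.savez_compressed(path, **arrays)
    sidecar = {
        "epoch": state.epoch,
        "learning_rate": state.learning_rate,
        "opt_t": state.opt.t,
        "embedding_dim": state.config.embedding_dim,
        "recurrent_layers": list(state.config.recurrent_layers),
        "use_batchnorm": state.config.use_batchnorm,
        "dropout": state.config.dropout,
        "batch_size": state.config.batch_size,
        "max_len": state.config.max_len,
        "vocab_tokens": list(state.config.vocab.tokens),
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh)


def load_checkpoint(path) -> ModelState:
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with open(npz_path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    tokens = tuple(sidecar["vocab_tokens"])
    vocab = TokenVocabulary(tokens=tokens, index={t: i for i, t in enumerate(tokens)})
    config = ModelConfig(
        vocab=vocab,
        embedding_dim=sidecar["embedding_dim"],
        recurrent_layers=tuple(sidecar["recurrent_layers"]),
        use_batchnorm=sidecar["use_batchnorm"],
        dropout=sidecar["dropout"],
        batch_size=sidecar["batch_size"],
        max_len=sidecar["max_len"],
    )
    data = np.load(npz_path)
    params, m, v, bn = {}, {}, {}, {}
    for key in data.files:
        kind, name = key.split("_", 1)
        {"p": params, "m": m, "v": v, "s": bn}[kind][name] = data[key]
    return ModelState(
        config=config,
        params=params,
        opt=nn.AdamState(m=m, v=v, t=sidecar["opt_t"]),
        bn_stats=bn,
        epoch=sidecar["epoch"],
        learning_rate=sidecar["learning_rate"],
    )
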