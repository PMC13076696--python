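"""Model construction, training mechanics, checkpointing and epoch selection."""

import numpy as np
import pytest

from increclm import nn
from increclm.chem_io import build_vocabulary
from increclm.clm_engine import (
    ModelConfig,
    StageParams,
    build_model,
    encode_batch,
    incremental_finetune,
    load_checkpoint,
    save_checkpoint,
    select_best_epoch,
    select_best_epoch_smoothed,
    select_pretrain_epoch,
    train_stage,
)
from increclm.generator import sample_designs
from increclm.sar_curation import PotencySplit
from increclm.chem_io import MoleculeRecord


class TestGradients:
    def test_backprop_matches_numerical_gradients(self):
        spec = nn.NetSpec(vocab_size=7, embedding_dim=4, recurrent_layers=(5, 3),
                          use_batchnorm=True, dropout=0.0)
        params = nn.init_params(spec, seed=0)
        bn = nn.init_bn_stats(spec)
        rng = np.random.default_rng(1)
        X = rng.integers(1, 7, size=(3, 6))
        Y = rng.integers(1, 7, size=(3, 6))
        X[0, 4:] = 0
        Y[0, 4:] = 0

        def loss_at(p):
            stats = {k: v.copy() for k, v in bn.items()}
            loss, _ = nn.loss_and_grads(p, spec, X, Y, stats, train=True)
            return loss

        stats = {k: v.copy() for k, v in bn.items()}
        _, grads = nn.loss_and_grads(params, spec, X, Y, stats, train=True)
        eps = 1e-6
        check_rng = np.random.default_rng(2)
        for key, grad in grads.items():
            flat_idx = check_rng.choice(grad.size, size=min(6, grad.size),
                                        replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, grad.shape)
                orig = params[key][idx]
                params[key][idx] = orig + eps
                lp = loss_at(params)
                params[key][idx] = orig - eps
                lm = loss_at(params)
                params[key][idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grad[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8), key


class TestBuildModel:
    def test_seeded_init_is_deterministic(self, tiny_vocab):
        config = ModelConfig(vocab=tiny_vocab, embedding_dim=8,
                             recurrent_layers=(12,), dropout=0.0)
        a, b = build_model(config, seed=4), build_model(config, seed=4)
        X, Y = encode_batch(["CCO"], tiny_vocab)
        la, _ = nn.forward(a.params, config.net_spec(), X, a.bn_stats)
        lb, _ = nn.forward(b.params, config.net_spec(), X, b.bn_stats)
        np.testing.assert_array_equal(la, lb)
        c = build_model(config, seed=5)
        lc, _ = nn.forward(c.params, config.net_spec(), X, c.bn_stats)
        assert not np.array_equal(la, lc)

    def test_logit_width_equals_vocabulary(self):
        vocab = build_vocabulary(["CC", "CO", "CN", "CCl", "C=O", "C#N", "CF"])
        assert vocab.size == 10
        config = ModelConfig(vocab=vocab, embedding_dim=4, recurrent_layers=(16,))
        model = build_model(config, seed=0)
        X, _ = encode_batch(["CC"], vocab)
        logits, _ = nn.forward(model.params, config.net_spec(), X, model.bn_stats)
        assert logits.shape[-1] == 10


class TestEpochSelection:
    def test_argmin_with_early_tie(self):
        assert select_best_epoch([1.0, 0.8, 0.9]) == 2
        assert select_best_epoch([0.5, 0.5, 0.5]) == 1

    def test_smoothed_constant_trace_returns_first_window_position(self):
        assert select_best_epoch_smoothed([1.0] * 30, window=10) == 1

    def test_smoothed_picks_best_window_then_raw_argmin(self):
        # windows of 3: means [2, 5/3, 4/3, 5/3]; best window covers epochs
        # 3-5, whose raw minimum sits at epoch 4
        losses = [3.0, 2.0, 1.0, 2.0, 1.0, 2.0]
        assert select_best_epoch_smoothed(losses, window=3) == 3
        losses = [3.0, 2.0, 2.0, 1.0, 1.5, 2.0]
        assert select_best_epoch_smoothed(losses, window=3) == 4

    def test_smoothed_matches_bruteforce_on_random_traces(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 25))
            w = int(rng.integers(1, 12))
            losses = rng.choice([0.5, 1.0, 1.5, 2.0], size=n).tolist()
            w_eff = min(w, n)
            means = [np.mean(losses[e - w_eff: e]) for e in range(w_eff, n + 1)]
            end = int(np.argmin(means)) + w_eff
            seg = losses[end - w_eff: end]
            expected = end - w_eff + int(np.argmin(seg)) + 1
            assert select_best_epoch_smoothed(losses, window=w) == expected


class TestTrainStage:
    SMILES = ["CCO", "CCN", "CC(=O)O", "c1ccccc1", "Clc1ccccc1",
              "CCOC", "CCNC", "CCCO", "CCCN", "OCCO"]

    def test_zero_epochs_returns_input_unchanged(self, tiny_model):
        out, log = train_stage(tiny_model, self.SMILES, epochs=0)
        for k in tiny_model.params:
            np.testing.assert_array_equal(out.params[k], tiny_model.params[k])
        assert log.train_loss == []

    def test_restores_argmin_snapshot_bit_for_bit(self, tiny_model):
        snapshots = {}
        out, log = train_stage(
            tiny_model, self.SMILES, variant="canonical", epochs=8,
            initial_lr=1e-2, seed=3,
            snapshot_callback=lambda e, s: snapshots.__setitem__(e, s),
        )
        assert log.selected_epoch == select_best_epoch(log.val_loss)
        best = snapshots[log.selected_epoch]
        for k in out.params:
            np.testing.assert_array_equal(out.params[k], best.params[k])
        for k in out.opt.m:
            np.testing.assert_array_equal(out.opt.m[k], best.opt.m[k])
        assert out.opt.t == best.opt.t

    def test_randomized_uses_moving_average_selection(self, tiny_model):
        out, log = train_stage(
            tiny_model, self.SMILES, variant="randomized", epochs=12,
            initial_lr=1e-2, seed=3,
        )
        assert log.selected_epoch == select_best_epoch_smoothed(log.val_loss, 10)
        assert out.epoch == log.selected_epoch

    def test_validation_loss_decreases_on_learnable_data(self, tiny_model):
        _, log = train_stage(
            tiny_model, ["CCO"] * 10, variant="canonical", epochs=12,
            initial_lr=1e-2, plateau=None, seed=0,
        )
        assert log.val_loss[-1] < log.val_loss[0]

    def test_plateau_scheduler_halves_after_patience(self):
        from increclm.clm_engine import PlateauConfig, PlateauScheduler

        sched = PlateauScheduler(1e-2, PlateauConfig())
        for loss in (1.0, 0.9):
            assert sched.update(loss) == 1e-2  # improving
        for loss in (0.9, 0.9):
            assert sched.update(loss) == 1e-2  # stagnant, within patience
        assert sched.update(0.9) == pytest.approx(5e-3)  # third stagnant epoch

    def test_plateau_scheduler_respects_floor(self):
        from increclm.clm_engine import PlateauConfig, PlateauScheduler

        sched = PlateauScheduler(2e-4, PlateauConfig(min_lr=1e-4))
        for _ in range(12):
            lr = sched.update(1.0)
        assert lr == 1e-4

    def test_tiny_improvements_count_as_plateau(self):
        from increclm.clm_engine import PlateauConfig, PlateauScheduler

        sched = PlateauScheduler(1e-2, PlateauConfig(min_delta=1e-4))
        lrs = [sched.update(1.0 - i * 1e-5) for i in range(1, 7)]
        assert lrs[-1] < 1e-2

    def test_too_small_dataset_errors(self, tiny_model):
        with pytest.raises(ValueError):
            train_stage(tiny_model, ["CCO"], epochs=1)

    def test_unknown_variant_errors(self, tiny_model):
        with pytest.raises(ValueError):
            train_stage(tiny_model, self.SMILES, variant="beam")


class TestCheckpoints:
    def test_roundtrip_reproduces_token_stream(self, tiny_model, tmp_path):
        state, _ = train_stage(
            tiny_model, TestTrainStage.SMILES, epochs=3, initial_lr=1e-2, seed=1
        )
        save_checkpoint(state, tmp_path / "ckpt.npz")
        loaded = load_checkpoint(tmp_path / "ckpt.npz")
        a = sample_designs(state, n=64, seed=9)
        b = sample_designs(loaded, n=64, seed=9)
        assert a.samples == b.samples
        assert a.n_invalid == b.n_invalid
        assert loaded.epoch == state.epoch
        assert loaded.learning_rate == state.learning_rate


class TestIncrementalFinetune:
    def _split(self, groups):
        return PotencySplit(
            subsets=tuple(
                tuple(MoleculeRecord(s, potency_p=6.0) for s in g) for g in groups
            ),
            holdout=(), strategy="values", k=len(groups),
        )

    def test_single_stage_equals_classical_fine_tuning(self, tiny_model):
        split = self._split([TestTrainStage.SMILES])
        _, logs, trace = incremental_finetune(
            tiny_model, split, StageParams(epochs=2), seed=0
        )
        assert len(logs) == 1 and trace == []

    def test_stage_too_small_names_stage(self, tiny_model):
        split = self._split([TestTrainStage.SMILES, ["CCO"]])
        with pytest.raises(ValueError, match="stage 2"):
            incremental_finetune(tiny_model, split, StageParams(epochs=1), seed=0)

    def test_learning_rate_travels_between_stages(self, tiny_model):
        split = self._split([TestTrainStage.SMILES, TestTrainStage.SMILES])
        _, logs, _ = incremental_finetune(
            tiny_model, split, StageParams(epochs=2, initial_lr=5e-4), seed=0
        )
        # stage 2 starts at the lr in effect at stage 1's restored epoch
        assert logs[1].learning_rate[0] == logs[0].learning_rate[
            logs[0].selected_epoch - 1
        ]


class TestSelectPretrainEpoch:
    def test_single_candidate_returned(self, tiny_model):
        best, table = select_pretrain_epoch(
            [tiny_model], ["CCO", "CCN"], n_designs=16, seed=0
        )
        assert best is tiny_model and len(table) == 1

    def test_invalid_only_candidate_never_selected(self, tiny_vocab, tiny_model):
        # a model whose output bias forces a degenerate start token on every
        # draw produces no valid molecules and must lose to any valid-capable
        # candidate
        import math

        broken = tiny_model.copy()
        for k in broken.params:
            broken.params[k][:] = 0.0
        broken.params["bout"][tiny_vocab.start_index] = 100.0
        capable = tiny_model.copy()
        for k in capable.params:
            capable.params[k][:] = 0.0
        capable.params["bout"][:] = -1e9
        capable.params["bout"][tiny_vocab.index["C"]] = math.log(0.5)
        capable.params["bout"][tiny_vocab.end_index] = math.log(0.5)
        best, table = select_pretrain_epoch(
            [broken, capable], ["CCO", "CCN"], n_designs=64,
            min_validity=0.0, seed=0,
        )
        assert best is capable
        assert table[0]["validity"] == 0.0 and table[1]["validity"] > 0.3
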