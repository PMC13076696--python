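"""Temperature sampling, perplexity, ranking and the design-filter cascade."""

import math

import numpy as np
import pytest

from increclm.clm_engine import ModelConfig, build_model, train_stage
from increclm.generator import (
    DesignSample,
    DesignSet,
    FilterConfig,
    filter_designs,
    perplexity_from_probs,
    rank_designs,
    sample_designs,
    sequence_perplexity,
    softmax_with_temperature,
)


def uniform_model(vocab):
    """All-zero weights: every next-token distribution is uniform over V."""
    config = ModelConfig(vocab=vocab, embedding_dim=4, recurrent_layers=(6,),
                         use_batchnorm=True, dropout=0.0)
    model = build_model(config, seed=0)
    for k in model.params:
        model.params[k][:] = 0.0
    return model


def biased_model(vocab, logit_map):
    """Zero weights except a fixed output bias: a hand-specified sampler."""
    model = uniform_model(vocab)
    model.params["bout"][:] = -1e9
    for token, logit in logit_map.items():
        model.params["bout"][vocab.index[token]] = logit
    return model


class TestSoftmax:
    def test_hand_computed_values(self):
        q = softmax_with_temperature(np.array([1.0, 0.0]), 1.0)
        assert q[0] == pytest.approx(math.e / (1 + math.e), abs=1e-9)
        assert q[1] == pytest.approx(1 / (1 + math.e), abs=1e-9)

    def test_sums_to_one_and_positive(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            z = rng.normal(size=rng.integers(2, 12))
            t = float(rng.uniform(0.1, 5.0))
            q = softmax_with_temperature(z, t)
            assert q.sum() == pytest.approx(1.0, abs=1e-12)
            assert (q > 0).all()

    def test_equal_logits_uniform_at_any_temperature(self):
        for t in (0.2, 1.0, 7.0):
            q = softmax_with_temperature(np.ones(5) * 3.3, t)
            np.testing.assert_allclose(q, 0.2, atol=1e-12)

    def test_temperature_limits(self):
        z = np.array([2.0, 1.0, 0.0])
        hot = softmax_with_temperature(z, 1e6)
        np.testing.assert_allclose(hot, 1 / 3, atol=1e-5)
        cold = softmax_with_temperature(z, 1e-6)
        assert cold[0] == pytest.approx(1.0)

    def test_nonpositive_temperature_errors(self):
        with pytest.raises(ValueError):
            softmax_with_temperature(np.ones(3), 0.0)


class TestPerplexity:
    def test_closed_forms(self):
        assert perplexity_from_probs([1.0, 1.0, 1.0]) == pytest.approx(1.0)
        assert perplexity_from_probs([0.5, 0.25, 0.25]) == pytest.approx(
            32 ** (1 / 3)
        )
        v = 9
        assert perplexity_from_probs([1 / v] * 5) == pytest.approx(v)

    def test_at_least_one(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            probs = rng.uniform(0.01, 1.0, size=rng.integers(1, 10))
            assert perplexity_from_probs(probs) >= 1.0

    def test_uniform_model_gives_vocabulary_size(self, tiny_vocab):
        model = uniform_model(tiny_vocab)
        for smiles in ("CCO", "c1ccccc1", "C"):
            assert sequence_perplexity(model, smiles) == pytest.approx(
                tiny_vocab.size, rel=1e-9
            )

    def test_augmented_mean_is_seeded(self, tiny_vocab):
        model = uniform_model(tiny_vocab)
        a = sequence_perplexity(model, "CC(=O)O", n_augment=10, seed=5)
        b = sequence_perplexity(model, "CC(=O)O", n_augment=10, seed=5)
        assert a == b


class TestSampling:
    def test_hand_specified_distribution_reproduced(self, tiny_vocab):
        # P(end)=0.5, P(C)=0.3, P(O)=0.2 at every step; the design "C" is
        # emitted with probability 0.3*0.5 per draw
        model = biased_model(tiny_vocab, {
            "<end>": math.log(0.5), "C": math.log(0.3), "O": math.log(0.2),
        })
        n = 10_000
        designs = sample_designs(model, n=n, seed=11)
        freq = {s.smiles_canonical: s.frequency for s in designs.samples}
        p = 0.3 * 0.5
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(freq["C"] - n * p) < 3 * sigma

    def test_seed_reproducible(self, tiny_vocab):
        model = uniform_model(tiny_vocab)
        a = sample_designs(model, n=256, seed=3)
        b = sample_designs(model, n=256, seed=3)
        assert a == b
        c = sample_designs(model, n=256, seed=4)
        assert a.samples != c.samples or a.n_invalid != c.n_invalid

    def test_counts_are_consistent(self, tiny_vocab):
        model = uniform_model(tiny_vocab)
        designs = sample_designs(model, n=500, seed=0)
        assert designs.n_emitted == 500
        assert sum(s.frequency for s in designs.samples) == designs.n_valid

    def test_max_len_truncation_is_invalid(self, tiny_vocab):
        # end token unreachable -> every sequence hits the cap -> all invalid
        model = biased_model(tiny_vocab, {"C": 0.0})
        designs = sample_designs(model, n=20, max_len=10, seed=0)
        assert designs.n_invalid == 20 and designs.samples == ()


class TestRanking:
    def test_sorted_by_perplexity(self, tiny_vocab):
        # biased model: longer molecules accumulate more improbable tokens
        model = biased_model(tiny_vocab, {
            "<end>": math.log(0.5), "C": math.log(0.4), "O": math.log(0.1),
        })
        designs = DesignSet(
            samples=(
                DesignSample("CCO", frequency=5),
                DesignSample("C", frequency=5),
            ),
            n_requested=10, n_emitted=10, n_invalid=0,
        )
        ranked = rank_designs(designs, model, variant="canonical")
        assert [s.smiles_canonical for s in ranked.samples] == ["C", "CCO"]
        assert [s.rank for s in ranked.samples] == [1, 2]
        # analytic check: PPL("C") = (0.4 * 0.5) ** -0.5
        assert ranked.samples[0].perplexity == pytest.approx(
            (0.4 * 0.5) ** -0.5, rel=1e-9
        )

    def test_tie_broken_by_frequency(self, tiny_vocab):
        model = uniform_model(tiny_vocab)  # equal PPL for equal lengths
        designs = DesignSet(
            samples=(
                DesignSample("CCN", frequency=10),
                DesignSample("CCO", frequency=40),
            ),
            n_requested=50, n_emitted=50, n_invalid=0,
        )
        ranked = rank_designs(designs, model, variant="canonical")
        assert ranked.samples[0].smiles_canonical == "CCO"

    def test_training_set_members_removed(self, tiny_vocab):
        model = uniform_model(tiny_vocab)
        designs = DesignSet(
            samples=(DesignSample("CCO", 3), DesignSample("CCN", 2)),
            n_requested=5, n_emitted=5, n_invalid=0,
        )
        ranked = rank_designs(designs, model, training_set={"CCO"})
        assert [s.smiles_canonical for s in ranked.samples] == ["CCN"]

    def test_never_increases_sample_count(self, tiny_vocab):
        model = uniform_model(tiny_vocab)
        designs = sample_designs(model, n=200, seed=1)
        ranked = rank_designs(designs, model)
        assert len(ranked.samples) <= len(designs.samples)


class TestFilterCascade:
    def _ranked(self, smiles_freq):
        samples = tuple(
            DesignSample(s, frequency=f, rank=i + 1)
            for i, (s, f) in enumerate(smiles_freq)
        )
        return DesignSet(samples=samples, n_requested=10, n_emitted=10,
                         n_invalid=0)

    def test_default_config_applies_only_perplexity_floor(self, tiny_vocab):
        naive = uniform_model(tiny_vocab)  # naive PPL = V >> 1.012
        ranked = self._ranked([("CCO", 5), ("CCN", 3)])
        out, log = filter_designs(ranked, naive)
        assert [s.smiles_canonical for s in out.samples] == ["CCO", "CCN"]
        assert log == []

    def test_naive_perplexity_floor_removes(self, tiny_vocab):
        naive = uniform_model(tiny_vocab)
        ranked = self._ranked([("CCO", 5)])
        out, log = filter_designs(
            ranked, naive, FilterConfig(min_naive_perplexity=tiny_vocab.size + 1)
        )
        assert out.samples == ()
        assert log == [("CCO", "naive-perplexity-floor")]

    def test_known_and_baseline_rules(self, tiny_vocab):
        naive = uniform_model(tiny_vocab)
        ranked = self._ranked([("CCO", 5), ("CCN", 3), ("OCCO", 2)])
        out, log = filter_designs(
            ranked, naive,
            FilterConfig(known_sets=(("CCO",),), baseline_top=("CCN",)),
        )
        assert [s.smiles_canonical for s in out.samples] == ["OCCO"]
        assert ("CCO", "known-molecule") in log
        assert ("CCN", "classical-baseline-top") in log

    def test_isomer_and_substructure_rules(self, tiny_vocab):
        naive = uniform_model(tiny_vocab)
        ranked = self._ranked([("COC", 4), ("c1ccccc1", 3), ("OCCO", 2)])
        out, log = filter_designs(
            ranked, naive,
            FilterConfig(remove_substructures_isomers=True),
            training=["CCO", "Cc1ccccc1"],
        )
        # COC is an isomer of CCO; benzene is a substructure of toluene
        assert [s.smiles_canonical for s in out.samples] == ["OCCO"]
        assert ("COC", "isomer-of-training") in log
        assert ("c1ccccc1", "substructure-of-training") in log

    def test_similarity_cap(self, tiny_vocab):
        naive = uniform_model(tiny_vocab)
        ranked = self._ranked([("CCO", 4), ("OCCOCCO", 2)])
        out, log = filter_designs(
            ranked, naive, FilterConfig(max_similarity=0.8), training=["CCO"]
        )
        assert ("CCO", "training-similarity") in log  # similarity 1.0 > 0.8
        assert [s.smiles_canonical for s in out.samples] == ["OCCOCCO"]

    def test_blacklist_and_ring_size(self, tiny_vocab):
        naive = uniform_model(tiny_vocab)
        ranked = self._ranked([
            ("C1=CC=CCC1", 3),      # 1,3-cyclohexadiene
            ("C1CCCCCCC1", 2),      # 8-membered ring
            ("CCO", 1),
        ])
        out, log = filter_designs(
            ranked, naive,
            FilterConfig(substructure_blacklist=("C1=CC=CCC1",),
                         max_ring_size=7),
        )
        assert [s.smiles_canonical for s in out.samples] == ["CCO"]
        rules = dict(log)
        assert rules["C1=CC=CCC1"] == "blacklist-substructure"
        assert rules["C1CCCCCCC1"] == "oversized-ring"

    def test_priority_pattern_stable_partition(self, tiny_vocab):
        naive = uniform_model(tiny_vocab)
        ranked = self._ranked([
            ("CCO", 5), ("CS(N)(=O)=O", 3), ("CCN", 2), ("CCS(N)(=O)=O", 1),
        ])
        out, _ = filter_designs(
            ranked, naive,
            FilterConfig(priority_pattern="S(=O)(=O)N"),
        )
        assert [s.smiles_canonical for s in out.samples] == [
            "CS(N)(=O)=O", "CCS(N)(=O)=O", "CCO", "CCN",
        ]
        assert [s.rank for s in out.samples] == [1, 2, 3, 4]

    def test_removals_disjointly_attributed(self, tiny_vocab):
        naive = uniform_model(tiny_vocab)
        ranked = self._ranked([("CCO", 5), ("COC", 3), ("OCCO", 2)])
        out, log = filter_designs(
            ranked, naive,
            FilterConfig(known_sets=(("CCO", "COC"),),
                         remove_substructures_isomers=True),
            training=["CCO"],
        )
        removed = [s for s, _ in log]
        assert sorted(removed) == sorted(set(removed))
        assert len(out.samples) + len(log) == 3
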