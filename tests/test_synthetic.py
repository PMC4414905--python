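"""Generator determinism, noise model, feasibility checks, share convergence."""

import numpy as np
import pytest

from hospmine.corpus import write_corpus
from hospmine.hospital_ner import edit_distance, fuzzy_threshold, match_hospital
from hospmine.preprocess import normalize_text, split_sentences, tokenize
from hospmine.synthetic import (
    ConfigError,
    DISTRACTOR_VOCAB,
    GeneratorConfig,
    corrupt_alias,
    generate_corpus,
)


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path, bundled_lexicons):
        paths = []
        for name in ("a", "b"):
            threads, messages, _ = generate_corpus(
                GeneratorConfig(seed=1, n_threads_per_region=4, typo_rate=0.3),
                *bundled_lexicons,
            )
            p = tmp_path / f"{name}.jsonl"
            write_corpus(threads, messages, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_different_seeds_differ(self, bundled_lexicons):
        t1, m1, _ = generate_corpus(GeneratorConfig(seed=1, n_threads_per_region=2), *bundled_lexicons)
        t2, m2, _ = generate_corpus(GeneratorConfig(seed=2, n_threads_per_region=2), *bundled_lexicons)
        assert [m.raw_text for m in m1] != [m.raw_text for m in m2]


class TestNoiseModel:
    def test_typo_rate_zero_surfaces_are_verbatim_aliases(self, bundled_lexicons):
        hospitals, _, _ = bundled_lexicons
        surfaces = {
            normalize_text(a)[0] for e in hospitals for a in e.aliases
        }
        _, _, gold = generate_corpus(
            GeneratorConfig(seed=3, n_threads_per_region=6, typo_rate=0.0), *bundled_lexicons
        )
        planted = [h for g in gold.values() for h in g.hospitals]
        assert planted
        assert all(h.surface in surfaces and not h.corrupted for h in planted)

    def test_corrupt_alias_identity_at_zero_ops(self):
        rng = np.random.default_rng(0)
        assert corrupt_alias("clinic", 0, rng) == "clinic"

    def test_corrupt_alias_single_op_distance(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            out = corrupt_alias("clinic", 1, rng)
            assert edit_distance("clinic", out) <= 1

    def test_corrupted_distance_bounded_by_ops(self):
        # measured over many draws: realized distance never exceeds n_ops
        rng = np.random.default_rng(2)
        for _ in range(1000):
            out = corrupt_alias("sunrise kids", 2, rng)
            assert edit_distance("sunrise kids", out) <= 2
            assert " ".join(out.split()) == out  # token structure stable

    def test_planted_typos_stay_resolvable(self, bundled_lexicons):
        hospitals, _, _ = bundled_lexicons
        _, _, gold = generate_corpus(
            GeneratorConfig(seed=4, n_threads_per_region=8, typo_rate=1.0, max_edit_ops=2),
            *bundled_lexicons,
        )
        planted = [
            (g, h) for g in gold.values() for h in g.hospitals if h.corrupted
        ]
        assert planted
        for g, h in planted:
            d = edit_distance(h.surface, h.alias)
            assert 0 < d <= h.n_ops
            assert d <= fuzzy_threshold(h.alias, 0.25)
            result = match_hospital(h.surface, hospitals)
            assert result is not None and result.canonical_id == h.canonical_id


class TestStructure:
    def test_gold_sentence_plan_matches_rendered_text(self, bundled_lexicons):
        _, messages, gold = generate_corpus(
            GeneratorConfig(seed=5, n_threads_per_region=4), *bundled_lexicons
        )
        for m in messages:
            n_sent = len(split_sentences(m.raw_text))
            assert n_sent == len(gold[m.message_id].sentence_polarities)

    def test_bilateral_messages_have_both_polarities(self, bundled_lexicons):
        _, _, gold = generate_corpus(
            GeneratorConfig(seed=6, n_threads_per_region=25, p_bilateral=0.3),
            *bundled_lexicons,
        )
        bilaterals = [g for g in gold.values() if g.four_class == "bilateral"]
        assert bilaterals
        for g in bilaterals:
            assert 1 in g.sentence_polarities and -1 in g.sentence_polarities

    def test_messages_per_thread_mean_converges(self, bundled_lexicons):
        threads, messages, _ = generate_corpus(
            GeneratorConfig(seed=7, n_threads_per_region=60), *bundled_lexicons
        )
        mean = len(messages) / len(threads)
        # Poisson(4.59)+1: SE of the mean ≈ sqrt(4.59/360) ≈ 0.11
        assert abs(mean - 5.59) < 3 * np.sqrt(4.59 / len(threads))

    def test_factor_share_converges_to_config(self, bundled_lexicons):
        cfg = GeneratorConfig(seed=8, n_threads_per_region=60)
        _, messages, gold = generate_corpus(cfg, *bundled_lexicons)
        share = np.mean([bool(g.factors) for g in gold.values()])
        se = np.sqrt(0.1845 * (1 - 0.1845) / len(messages))
        assert abs(share - 0.1845) < 3 * se

    def test_vocabulary_cannot_shadow_hospital_aliases(self, bundled_lexicons):
        """No 1- or 2-gram of generated filler/keyword text fuzzy-matches an alias.

        This is the structural guarantee behind the perfect-precision claims:
        spurious mentions can only come from planted distractors, never from
        the background vocabulary.
        """
        hospitals, factors, sentiment = bundled_lexicons
        words = set(DISTRACTOR_VOCAB)
        for e in factors:
            for s in e.surfaces:
                words.update(t.text for t in tokenize(normalize_text(s)[0]))
        for cue in sentiment.positive_cues | sentiment.negative_cues:
            words.update(t.text for t in tokenize(normalize_text(cue)[0]))
        words = sorted(words)
        for w in words:
            assert match_hospital(w, hospitals) is None, w
        rng = np.random.default_rng(0)
        pairs = [(words[rng.integers(len(words))], words[rng.integers(len(words))])
                 for _ in range(2000)]
        for a, b in pairs:
            assert match_hospital(f"{a} {b}", hospitals) is None, (a, b)


class TestFeasibility:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(typo_rate=1.5),
            dict(p_positive=0.8, p_negative=0.3),  # mixture > 1
            dict(p_bilateral=0.1, sentences_max=1),  # bilateral needs >= 2 sentences
            dict(sentences_min=4, sentences_max=2),
            dict(messages_per_thread_mean=0.5),
        ],
    )
    def test_infeasible_configs_rejected(self, kwargs, bundled_lexicons):
        with pytest.raises(ConfigError):
            generate_corpus(GeneratorConfig(seed=0, **kwargs), *bundled_lexicons)

    def test_unknown_weight_keyword_rejected(self, bundled_lexicons):
        cfg = GeneratorConfig(seed=0, factor_keyword_weights=(("no such keyword", 1.0),))
        with pytest.raises(ConfigError):
            generate_corpus(cfg, *bundled_lexicons)


class TestShareRecovery:
    def test_positive_share_recovered_at_n5000(self, bundled_lexicons):
        cfg = GeneratorConfig(seed=12345, n_threads_per_region=150)
        _, messages, gold = generate_corpus(cfg, *bundled_lexicons)
        n = len(messages)
        assert n >= 4500
        share = np.mean([g.four_class == "positive" for g in gold.values()])
        se = np.sqrt(0.36 * 0.64 / n)
        assert abs(share - 0.36) < 3 * se

    def test_negative_including_bilateral_share(self, bundled_lexicons):
        cfg = GeneratorConfig(seed=54321, n_threads_per_region=150)
        _, messages, gold = generate_corpus(cfg, *bundled_lexicons)
        share = np.mean([g.binary == "negative" for g in gold.values()])
        se = np.sqrt(0.08 * 0.92 / len(messages))
        assert abs(share - 0.08) < 3 * se
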