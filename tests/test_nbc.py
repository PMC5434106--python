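"""Naive Bayesian classifier: word extraction, training formulas, calls,
bootstrap confidence, and amplicon evaluation."""

from __future__ import annotations

import math

import numpy as np
import pytest

import hcbprimer as h
from hcbprimer.core_io import ReferenceSequence
from hcbprimer.nbc import (
    NBCModel,
    classify,
    classify_bootstrap,
    classify_scores,
    evaluate_amplicon_classification,
    extract_words,
    train,
)


def _rec(rid, seq, genus):
    return ReferenceSequence(
        id=rid, sequence=seq,
        taxonomy=("Bacteria", "P", "C", "O", "F", genus))


class TestExtractWords:
    def test_single_window(self):
        assert extract_words("ACGTACGT", k=8) == {"ACGTACGT"}

    def test_repeated_word_counted_once(self):
        assert extract_words("AAAAAAAAA", k=8) == {"AAAAAAAA"}

    def test_words_with_ambiguity_codes_skipped(self):
        # every window overlapping the N is dropped
        assert extract_words("ACGTNACGT", k=4) == {"ACGT"}
        assert extract_words("AACGTNGGGG", k=4) == {"AACG", "ACGT", "GGGG"}

    def test_count_bounded_by_window_count(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = "".join(rng.choice(list("ACGT"), size=int(rng.integers(8, 60))))
            assert len(extract_words(s, k=8)) <= len(s) - 8 + 1

    def test_short_sequence_raises(self):
        with pytest.raises(ValueError):
            extract_words("ACGT", k=8)


class TestTrain:
    def test_smoothing_formulas(self):
        # two genera, one sequence each, k=2:
        # N=2; a word present in exactly one sequence has prior (1+0.5)/3
        model = train([_rec("x1", "AAC", "X"), _rec("y1", "GGT", "Y")], k=2)
        w = model.genera.index  # noqa: F841  (genera sorted: X, Y)
        idx_aa = 0 * 4 + 0  # "AA"
        prior = (1 + 0.5) / (2 + 1)
        assert model.word_prior[idx_aa] == pytest.approx(prior)
        # X contains AA: cond = (1 + prior) / (1 + 1); Y: (0 + prior) / 2
        gx = model.genera.index("X")
        gy = model.genera.index("Y")
        assert math.exp(model.cond_log_prob[gx, idx_aa]) == pytest.approx((1 + prior) / 2)
        assert math.exp(model.cond_log_prob[gy, idx_aa]) == pytest.approx(prior / 2)
        # a word absent everywhere: prior = 0.5/3, cond = prior/2 for both
        idx_cc = 1 * 4 + 1
        assert model.word_prior[idx_cc] == pytest.approx(0.5 / 3)
        assert math.exp(model.cond_log_prob[gx, idx_cc]) == pytest.approx(0.5 / 6)

    def test_probabilities_match_recount_oracle(self):
        rng = np.random.default_rng(4)
        k = 4
        recs = [_rec(f"s{i}", "".join(rng.choice(list("ACGT"), size=40)),
                     "X" if i < 5 else "Y") for i in range(10)]
        model = train(recs, k=k)
        # independent recount with plain python sets
        words_of = {r.id: {r.sequence[i:i + k] for i in range(len(r.sequence) - k + 1)}
                    for r in recs}

        def widx(word):
            return sum({"A": 0, "C": 1, "G": 2, "T": 3}[c] * 4 ** (k - 1 - i)
                       for i, c in enumerate(word))

        import itertools
        for word in ("".join(t) for t in itertools.product("ACGT", repeat=k)):
            n_w = sum(word in ws for ws in words_of.values())
            prior = (n_w + 0.5) / (10 + 1)
            assert model.word_prior[widx(word)] == pytest.approx(prior)
            for genus, ids in (("X", [f"s{i}" for i in range(5)]),
                               ("Y", [f"s{i}" for i in range(5, 10)])):
                m_g = sum(word in words_of[i] for i in ids)
                expected = (m_g + prior) / (5 + 1)
                gi = model.genera.index(genus)
                assert math.exp(model.cond_log_prob[gi, widx(word)]) == \
                    pytest.approx(expected)

    def test_probabilities_strictly_inside_unit_interval(self):
        model = train([_rec("a", "ACGTACGTAAA", "X"), _rec("b", "TTTTCCCCGGG", "Y")],
                      k=3)
        assert (model.word_prior > 0).all() and (model.word_prior < 1).all()
        cond = np.exp(model.cond_log_prob)
        assert (cond > 0).all() and (cond < 1).all()
        assert np.isfinite(model.cond_log_prob).all()

    def test_single_genus_rejected(self):
        with pytest.raises(ValueError, match="2 labeled genera"):
            train([_rec("a", "ACGTACGT", "X")], k=4)


def _separable_model(k=4):
    recs = [
        _rec("x1", "AAAACCCCAAAACCCC", "X"),
        _rec("x2", "AAAACCCCAAAACCCG", "X"),
        _rec("y1", "GGGGTTTTGGGGTTTT", "Y"),
        _rec("y2", "GGGGTTTTGGGGTTTA", "Y"),
    ]
    return train(recs, k=k), recs


class TestClassify:
    def test_training_sequences_classified_to_own_genus(self):
        model, recs = _separable_model()
        for rec in recs:
            assert classify(model, rec.sequence) == rec.genus

    def test_all_shared_words_win(self):
        model, _ = _separable_model()
        assert classify(model, "AAAACCCC") == "X"
        assert classify(model, "GGGGTTTT") == "Y"

    def test_scores_equal_brute_force_summation(self):
        model, _ = _separable_model()
        seq = "AAAACCCCGGGG"
        words = extract_words(seq, k=4)

        def widx(word):
            return sum({"A": 0, "C": 1, "G": 2, "T": 3}[c] * 4 ** (3 - i)
                       for i, c in enumerate(word))

        scores = classify_scores(model, seq)
        for gi in range(len(model.genera)):
            brute = sum(model.cond_log_prob[gi, widx(w)] for w in words)
            assert scores[gi] == pytest.approx(brute)

    def test_tie_broken_lexicographically(self):
        # two genera with mirror-image training content score a neutral query
        # identically; the lexicographically first genus must win
        recs = [_rec("a1", "AAAAAAAA", "Beta"), _rec("b1", "AAAAAAAA", "Alpha")]
        model = train(recs, k=4)
        assert classify(model, "AAAAAAAA") == "Alpha"

    def test_word_multiplicity_irrelevant(self):
        model, _ = _separable_model()
        # same distinct-word set, different lengths/multiplicities
        s1 = "AAAAC"  # words AAAA, AAAC
        s2 = "AAAAAAC"  # same distinct words
        assert np.allclose(classify_scores(model, s1), classify_scores(model, s2))


class TestClassifyBootstrap:
    def test_separable_fixture_fully_confident(self):
        model, recs = _separable_model()
        res = classify_bootstrap(model, recs[0].sequence, n_boot=100, seed=1,
                                 seq_id="x1")
        assert res.predicted_genus == "X"
        assert res.bootstrap_confidence == 1.0

    def test_single_replicate_confidence_is_binary(self):
        model, recs = _separable_model()
        res = classify_bootstrap(model, recs[0].sequence, n_boot=1, seed=5)
        assert res.bootstrap_confidence in (0.0, 1.0)

    def test_reproducible_from_seed_and_id(self):
        model, recs = _separable_model()
        a = classify_bootstrap(model, recs[0].sequence, n_boot=50, seed=3, seq_id="q")
        b = classify_bootstrap(model, recs[0].sequence, n_boot=50, seed=3, seq_id="q")
        assert a == b

    def test_confidence_declines_with_shrinking_divergence(self):
        from hcbprimer.synthetic import PrimerSite, SynthConfig, DEFAULT_FORWARD_MOTIF

        mean_conf = []
        for div in (0.20, 0.05, 0.01):
            confs = []
            for seed in (1, 2):
                cfg = SynthConfig(n_genera=3, seqs_per_genus=6, seq_length=400,
                                  between_genus_divergence=div,
                                  within_genus_divergence=0.02, indel_rate=0.0,
                                  seed=seed,
                                  primer_sites=(PrimerSite(DEFAULT_FORWARD_MOTIF, 101),))
                records, truth = h.generate_reference_set(cfg)
                model = train(records)
                for rec in records[::3]:
                    res = classify_bootstrap(model, rec.sequence[50:350],
                                             n_boot=50, seed=seed, seq_id=rec.id)
                    confs.append(res.bootstrap_confidence)
            mean_conf.append(float(np.mean(confs)))
        assert mean_conf[0] >= mean_conf[-1]


class TestEvaluateAmpliconClassification:
    def test_separable_fixture_perfect_accuracy(self):
        model, recs = _separable_model()
        amps = [(r.id, r.sequence[:12], r.genus) for r in recs]
        table = evaluate_amplicon_classification(model, amps, n_boot=20, seed=0)
        assert (table["fraction_correct"] == 1.0).all()

    def test_unknown_genus_counts_as_incorrect(self):
        model, recs = _separable_model()
        amps = [("z1", "ACACACACAC", "Zeta")]
        with pytest.warns(UserWarning, match="Zeta"):
            table = evaluate_amplicon_classification(model, amps, n_boot=5, seed=0)
        assert table.iloc[0]["fraction_correct"] == 0.0

    def test_duplicate_amplicons_dereplicated(self):
        model, recs = _separable_model()
        amps = [("a", "AAAACCCCAAAA", "X"), ("b", "AAAACCCCAAAA", "X")]
        table = evaluate_amplicon_classification(model, amps, n_boot=5, seed=0)
        assert int(table.iloc[0]["n"]) == 1


class TestAccuracyRecovery:
    def test_accuracy_improves_with_divergence(self):
        from hcbprimer.synthetic import PrimerSite, SynthConfig, DEFAULT_FORWARD_MOTIF

        accs = []
        for div in (0.02, 0.08, 0.25):
            cfg = SynthConfig(n_genera=4, seqs_per_genus=8, seq_length=500,
                              between_genus_divergence=div,
                              within_genus_divergence=0.02, indel_rate=0.0, seed=6,
                              primer_sites=(PrimerSite(DEFAULT_FORWARD_MOTIF, 101),))
            records, truth = h.generate_reference_set(cfg)
            model = train(records)
            amps = [(r.id, r.sequence[100:400], truth.genus_of[r.id])
                    for r in records]
            table = evaluate_amplicon_classification(model, amps, n_boot=10, seed=1)
            accs.append(float(table["fraction_correct"].mean()))
        assert accs[-1] >= accs[0]
        assert accs[-1] >= 0.99


def test_model_tsv_round_trip(tmp_path):
    model, _ = _separable_model()
    p = tmp_path / "model.tsv"
    model.save(p)
    back = NBCModel.load(p)
    assert back.k == model.k and back.genera == model.genera
    assert np.allclose(back.word_prior, model.word_prior)
    assert np.allclose(back.cond_log_prob, model.cond_log_prob)
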