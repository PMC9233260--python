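"""Bernoulli naive Bayes, rule gate and variant logic.

The BNB implementation is checked against two independent oracles: a
brute-force evaluation of the Bernoulli joint probability, and
scikit-learn's BernoulliNB with identical smoothing.
"""

import math

import numpy as np
import pytest

from pamt import (
    NEGATIVE,
    POSITIVE,
    Corpus,
    FeatureSpace,
    RuleGate,
    Transcript,
    VARIANTS,
    VariantModel,
    bnb_log_posterior,
    fit_bnb,
    predict_bnb,
    predict_variant,
    rule_gate,
    train_variant,
    vectorize,
)
from pamt.classifiers import DEFER, FIRE_POSITIVE
from pamt.features import ORIGIN_TFIDF


def make_fs(n):
    return FeatureSpace(terms=[f"t{i}" for i in range(n)], origin=[ORIGIN_TFIDF] * n)


def brute_force_log_joint(x, prior, p):
    """Independent oracle: log of prior * product of Bernoulli terms."""
    joint = prior
    for xi, pi in zip(x, p):
        joint *= pi if xi else (1 - pi)
    return math.log(joint)


class TestFitBNB:
    def test_laplace_arithmetic_on_two_documents(self):
        fs = make_fs(1)
        params = fit_bnb([[True], [False]], [POSITIVE, NEGATIVE], fs, alpha=1.0)
        assert params.cond_prob[POSITIVE][0] == pytest.approx(2 / 3)
        assert params.cond_prob[NEGATIVE][0] == pytest.approx(1 / 3)

    def test_equal_class_counts_give_half_priors(self):
        fs = make_fs(1)
        params = fit_bnb(
            [[True], [False], [True], [False]],
            [POSITIVE, POSITIVE, NEGATIVE, NEGATIVE],
            fs,
        )
        assert math.exp(params.class_log_prior[POSITIVE]) == pytest.approx(0.5)

    def test_smoothing_keeps_probabilities_interior(self):
        fs = make_fs(2)
        # term 0 present in every positive, term 1 in none
        params = fit_bnb(
            [[True, False], [True, False], [False, True]],
            [POSITIVE, POSITIVE, NEGATIVE],
            fs,
        )
        for k in (POSITIVE, NEGATIVE):
            assert ((params.cond_prob[k] > 0) & (params.cond_prob[k] < 1)).all()

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_bnb([[True], [False]], [POSITIVE, POSITIVE], make_fs(1))

    def test_uniform_priors_option(self):
        fs = make_fs(1)
        params = fit_bnb(
            [[True], [False], [False]],
            [POSITIVE, NEGATIVE, NEGATIVE],
            fs,
            priors="uniform",
        )
        assert params.class_log_prior[POSITIVE] == params.class_log_prior[NEGATIVE]


class TestPosterior:
    def test_normalized_posteriors_sum_to_one(self):
        fs = make_fs(3)
        rng = np.random.default_rng(1)
        params = fit_bnb(
            rng.random((8, 3)) < 0.5,
            [POSITIVE, NEGATIVE] * 4,
            fs,
        )
        scores = bnb_log_posterior(params, np.array([True, False, True]))
        z = sum(math.exp(s) for s in scores.values())
        post = {k: math.exp(s) / z for k, s in scores.items()}
        assert sum(post.values()) == pytest.approx(1.0)

    def test_symmetric_parameters_give_equal_scores_and_positive_tie(self):
        fs = make_fs(2)
        params = fit_bnb(
            [[True, False], [True, False]],
            [POSITIVE, NEGATIVE],
            fs,
        )
        v = np.array([False, True])
        scores = bnb_log_posterior(params, v)
        assert scores[POSITIVE] == pytest.approx(scores[NEGATIVE])
        assert predict_bnb(params, v) == POSITIVE
        assert predict_bnb(params, v, tie_break=NEGATIVE) == NEGATIVE

    def test_matches_brute_force_enumeration_on_toys(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_feat = rng.integers(1, 6)
            n_docs = int(rng.integers(4, 12))
            x = rng.random((n_docs, n_feat)) < rng.random(n_feat)
            y = [POSITIVE, NEGATIVE] + [
                POSITIVE if b else NEGATIVE for b in rng.random(n_docs - 2) < 0.4
            ]
            fs = make_fs(n_feat)
            params = fit_bnb(x, y, fs, alpha=1.0)
            v = rng.random(n_feat) < 0.5
            scores = bnb_log_posterior(params, v)
            for k in (POSITIVE, NEGATIVE):
                expected = brute_force_log_joint(
                    v,
                    math.exp(params.class_log_prior[k]),
                    params.cond_prob[k],
                )
                assert scores[k] == pytest.approx(expected, abs=1e-10)

    def test_agrees_with_sklearn_bernoulli_nb(self):
        sklearn_nb = pytest.importorskip("sklearn.naive_bayes")
        rng = np.random.default_rng(7)
        for _ in range(200):
            n_feat = int(rng.integers(1, 6))
            n_docs = int(rng.integers(4, 20))
            x = rng.random((n_docs, n_feat)) < rng.random(n_feat)
            y = np.r_[[1, 0], (rng.random(n_docs - 2) < 0.4).astype(int)]
            fs = make_fs(n_feat)
            params = fit_bnb(x, [POSITIVE if b else NEGATIVE for b in y], fs, alpha=1.0)
            ref = sklearn_nb.BernoulliNB(alpha=1.0).fit(x.astype(int), y)
            test = rng.random((5, n_feat)) < 0.5
            jll = ref._joint_log_likelihood(test.astype(int))
            for row, (jl_neg, jl_pos) in zip(test, jll):
                # mathematical ties round arbitrarily in either
                # implementation; the tie convention is tested separately
                if abs(jl_pos - jl_neg) < 1e-9:
                    continue
                assert predict_bnb(params, row) == (
                    POSITIVE if jl_pos > jl_neg else NEGATIVE
                )

    def test_misaligned_vector_rejected(self):
        params = fit_bnb([[True], [False]], [POSITIVE, NEGATIVE], make_fs(1))
        with pytest.raises(ValueError, match="aligned"):
            bnb_log_posterior(params, np.array([True, False]))


class TestRuleGate:
    gate = RuleGate(keywords={"bleeding", "unconscious", "trapped"}, m=2)

    def test_two_distinct_keywords_fire(self):
        assert rule_gate(["bleeding", "car", "trapped"], self.gate) == FIRE_POSITIVE

    def test_one_keyword_repeated_defers_in_distinct_mode(self):
        assert rule_gate(["bleeding"] * 5, self.gate) == DEFER

    def test_no_keywords_defers(self):
        assert rule_gate(["calm", "call"], self.gate) == DEFER

    def test_token_occurrence_mode_counts_repeats(self):
        gate = RuleGate(self.gate.keywords, m=2, count_mode="token_occurrences")
        assert rule_gate(["bleeding"] * 2, gate) == FIRE_POSITIVE

    def test_lower_threshold_fires_superset(self, study_corpus):
        corpus, truth = study_corpus
        kws = set(truth["expert_keywords"])
        g1 = RuleGate(kws, m=1)
        g2 = RuleGate(kws, m=2)
        fired1 = {t.id for t in corpus if rule_gate(t.tokens, g1) == FIRE_POSITIVE}
        fired2 = {t.id for t in corpus if rule_gate(t.tokens, g2) == FIRE_POSITIVE}
        assert fired2 <= fired1
        assert fired1 > fired2  # strictly more at m=1 on this corpus

    def test_empty_keyword_set_rejected(self):
        with pytest.raises(ValueError):
            RuleGate(keywords=set(), m=2)


class TestVariants:
    @pytest.fixture
    def trained(self, study_corpus, expert_keywords):
        corpus, _ = study_corpus
        return {
            name: train_variant(list(corpus), name, expert_keywords, k=160)
            for name in VARIANTS
        }

    def test_gate_fires_positive_regardless_of_bnb(self, trained):
        model = trained["PAMT"]
        doc = Transcript(id="x", tokens=sorted(model.gate.keywords)[:2])
        assert model.predict(doc) == POSITIVE

    def test_variant_a_defers_to_negative(self, trained):
        doc = Transcript(id="x", tokens=["w0001", "w0002"])
        assert trained["A"].predict(doc) == NEGATIVE

    def test_variant_b_ignores_gate(self, study_corpus, expert_keywords):
        corpus, _ = study_corpus
        b = train_variant(list(corpus), "B", expert_keywords)
        assert b.gate is None
        preds = [b.predict(t) for t in corpus]
        with_gate = [
            predict_variant(VARIANTS["B"], b.bnb, None, t, b.feature_space)
            for t in corpus
        ]
        assert preds == with_gate

    def test_missing_component_is_configuration_error(self, trained):
        doc = Transcript(id="x", tokens=[])
        with pytest.raises(ValueError, match="requires"):
            predict_variant(VARIANTS["PAMT"], trained["PAMT"].bnb, None, doc,
                            trained["PAMT"].feature_space)

    def test_pamt_sensitivity_at_least_model_c(self, trained, study_corpus):
        """The gate can only add positive predictions to C's output."""
        corpus, _ = study_corpus
        c, p = trained["C"], trained["PAMT"]
        # force shared fitted BNB so the comparison isolates the gate
        p_same = VariantModel(variant=p.variant, feature_space=c.feature_space,
                              bnb=c.bnb, gate=p.gate)
        pos = [t for t in corpus if t.label == POSITIVE]
        sens_c = np.mean([c.predict(t) == POSITIVE for t in pos])
        sens_p = np.mean([p_same.predict(t) == POSITIVE for t in pos])
        assert sens_p >= sens_c

    def test_serialization_round_trip_is_bit_exact(self, trained):
        model = trained["PAMT"]
        again = VariantModel.from_json(model.to_json())
        assert (again.bnb.cond_prob[POSITIVE] == model.bnb.cond_prob[POSITIVE]).all()
        assert again.bnb.class_log_prior == model.bnb.class_log_prior
        assert again.gate.keywords == model.gate.keywords

    def test_reload_gives_identical_predictions(self, trained, study_corpus):
        corpus, _ = study_corpus
        model = trained["PAMT"]
        again = VariantModel.from_json(model.to_json())
        assert [model.predict(t) for t in corpus] == [again.predict(t) for t in corpus]

    def test_predict_detail_exposes_gate_and_posterior(self, trained):
        model = trained["PAMT"]
        doc = Transcript(id="x", tokens=sorted(model.gate.keywords)[:2])
        detail = model.predict_detail(doc)
        assert detail["gate"]["fired"] is True
        assert detail["label"] == POSITIVE
        assert sum(detail["bnb"]["posterior"].values()) == pytest.approx(1.0)


class TestParameterRecovery:
    def test_fitted_conditionals_approach_generator_probabilities(self):
        """On a large synthetic corpus, P(t|k) converges to the keyword rates."""
        from pamt import GeneratorConfig, generate_corpus
        from pamt.classifiers import build_feature_space

        cfg = GeneratorConfig(n_cases=1200, n_positive=600, seed=11,
                              background_vocab_size=500)
        corpus, truth = generate_corpus(cfg)
        terms = [kw["term"] for kw in truth["severity_keywords"]]
        fs = FeatureSpace(terms=terms, origin=[ORIGIN_TFIDF] * len(terms))
        from pamt import vectorize_corpus

        x, _ = vectorize_corpus(corpus, fs)
        params = fit_bnb(x, [t.label for t in corpus], fs)
        for i, kw in enumerate(truth["severity_keywords"]):
            for cls, p_true in ((POSITIVE, kw["p_pos"]), (NEGATIVE, kw["p_neg"])):
                half_width = 3.5 * math.sqrt(p_true * (1 - p_true) / 600 + 1e-6)
                assert abs(params.cond_prob[cls][i] - p_true) < half_width + 2 / 600
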