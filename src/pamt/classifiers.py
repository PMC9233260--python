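"""Bernoulli naive Bayes, the expert-keyword rule gate, and model variants.

The classifier is a Bernoulli naive Bayes over boolean term-presence
features.  For document vector x and class k,

    score(k) = log pi_k + sum_t [ x_t log P(t|k) + (1 - x_t) log(1 - P(t|k)) ]

with Laplace-smoothed conditionals P(t|k) = (n_kt + alpha) / (n_k + 2 alpha),
where n_kt counts class-k training documents containing term t and n_k
counts class-k documents.  alpha defaults to 1 (add-one smoothing), which
keeps every conditional strictly inside (0, 1).  The predicted label is
the maximum a posteriori class; an exact tie goes to the positive class,
the convention that favours sensitivity in a triage setting (undertriage
is the costly error).  Class priors are empirical frequencies by default.

The rule gate implements the hybrid enhancement: a document containing at
least ``m`` (default 2) distinct expert keywords is labelled positive
outright; everything else is deferred.  Four variants combine the pieces:

    A     expert-keyword features, gate only (defer => negative)
    B     TF-IDF features, BNB only
    C     TF-IDF + expert features, BNB only
    PAMT  TF-IDF + expert features, gate first, BNB on deferral
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .corpus import NEGATIVE, POSITIVE, Corpus, Transcript
from .features import (
    ORIGIN_EXPERT,
    FeatureConfig,
    FeatureSpace,
    rank_and_select,
    union_with_expert,
    vectorize,
    vectorize_corpus,
)

__all__ = [
    "BNBParams",
    "RuleGate",
    "ModelVariant",
    "VariantModel",
    "VARIANTS",
    "FIRE_POSITIVE",
    "DEFER",
    "fit_bnb",
    "bnb_log_posterior",
    "bnb_posterior_matrix",
    "predict_bnb",
    "rule_gate",
    "predict_variant",
    "build_feature_space",
    "train_variant",
]

FIRE_POSITIVE = "fire_positive"
DEFER = "defer"


@dataclass
class BNBParams:
    """Fitted Bernoulli naive Bayes parameters.

    ``cond_prob[k]`` is the vector of P(t|k) aligned to
    ``feature_space.terms``; ``class_log_prior[k]`` is log pi_k.
    """

    feature_space: FeatureSpace
    class_log_prior: dict[str, float]
    cond_prob: dict[str, np.ndarray]
    alpha: float = 1.0

    def __post_init__(self) -> None:
        for k in (POSITIVE, NEGATIVE):
            p = np.asarray(self.cond_prob[k], dtype=float)
            if p.shape != (len(self.feature_space),):
                raise ValueError("cond_prob not aligned to feature space")
            if np.any(p <= 0) or np.any(p >= 1):
                raise ValueError("conditional probabilities must lie in (0, 1)")
            self.cond_prob[k] = p
        total = sum(np.exp(v) for v in self.class_log_prior.values())
        if not np.isclose(total, 1.0):
            raise ValueError("class priors must exponentiate and sum to 1")


def fit_bnb(
    vectors: np.ndarray | Sequence[np.ndarray],
    labels: Sequence[str],
    feature_space: FeatureSpace,
    alpha: float = 1.0,
    priors: str = "empirical",
) -> BNBParams:
    """Fit Laplace-smoothed Bernoulli conditionals and class priors.

    ``priors="empirical"`` uses the training class frequencies;
    ``"uniform"`` fixes both priors at 1/2.  Training requires both
    classes to be represented.
    """
    x = np.asarray(vectors, dtype=bool)
    y = np.asarray([lab == POSITIVE for lab in labels], dtype=bool)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("vectors and labels must align")
    if x.shape[1] != len(feature_space):
        raise ValueError("vectors not aligned to feature space")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training set must contain both classes")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    cond = {
        POSITIVE: (x[y].sum(axis=0) + alpha) / (n_pos + 2 * alpha),
        NEGATIVE: (x[~y].sum(axis=0) + alpha) / (n_neg + 2 * alpha),
    }
    if priors == "empirical":
        log_prior = {
            POSITIVE: float(np.log(n_pos / (n_pos + n_neg))),
            NEGATIVE: float(np.log(n_neg / (n_pos + n_neg))),
        }
    elif priors == "uniform":
        log_prior = {POSITIVE: float(np.log(0.5)), NEGATIVE: float(np.log(0.5))}
    else:
        raise ValueError(f"priors must be 'empirical' or 'uniform', got {priors!r}")
    return BNBParams(
        feature_space=feature_space,
        class_log_prior=log_prior,
        cond_prob=cond,
        alpha=alpha,
    )


def bnb_log_posterior(params: BNBParams, v: np.ndarray) -> dict[str, float]:
    """Unnormalised per-class log posterior for one document vector."""
    v = np.asarray(v, dtype=bool)
    if v.shape != (len(params.feature_space),):
        raise ValueError("vector not aligned to the model's feature space")
    out = {}
    for k in (POSITIVE, NEGATIVE):
        p = params.cond_prob[k]
        out[k] = params.class_log_prior[k] + float(
            np.where(v, np.log(p), np.log1p(-p)).sum()
        )
    return out


def bnb_posterior_matrix(params: BNBParams, x: np.ndarray) -> np.ndarray:
    """Log-posterior scores for a (n_docs, n_terms) matrix.

    Returns shape (n_docs, 2), columns ordered (positive, negative).
    """
    x = np.asarray(x, dtype=bool)
    cols = []
    for k in (POSITIVE, NEGATIVE):
        p = params.cond_prob[k]
        log_p, log_q = np.log(p), np.log1p(-p)
        cols.append(params.class_log_prior[k] + x @ (log_p - log_q) + log_q.sum())
    return np.column_stack(cols)


def predict_bnb(
    params: BNBParams, v: np.ndarray, tie_break: str = POSITIVE
) -> str:
    """MAP label; exact score ties resolve to ``tie_break`` (default positive)."""
    scores = bnb_log_posterior(params, v)
    if scores[POSITIVE] > scores[NEGATIVE]:
        return POSITIVE
    if scores[POSITIVE] < scores[NEGATIVE]:
        return NEGATIVE
    return tie_break


@dataclass
class RuleGate:
    """Keyword-count pre-classifier.

    Fires positive when a document contains at least ``m`` expert
    keywords; ``count_mode`` decides whether repeated occurrences of the
    same keyword count once (``distinct_types``, default) or each time
    (``token_occurrences``).  Keywords should be in canonical
    (post-synonym-grouping) form, since gating runs on preprocessed
    tokens.
    """

    keywords: set[str]
    m: int = 2
    count_mode: str = "distinct_types"

    def __post_init__(self) -> None:
        self.keywords = set(self.keywords)
        if not self.keywords:
            raise ValueError("rule gate requires a non-empty keyword set")
        if self.m < 1:
            raise ValueError("gate threshold m must be >= 1")
        if self.count_mode not in ("distinct_types", "token_occurrences"):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")

    def count(self, tokens: Sequence[str]) -> int:
        if self.count_mode == "distinct_types":
            return len(self.keywords.intersection(tokens))
        return sum(tok in self.keywords for tok in tokens)


def rule_gate(tokens: Sequence[str], gate: RuleGate) -> str:
    """``fire_positive`` when the keyword count reaches the threshold, else ``defer``."""
    return FIRE_POSITIVE if gate.count(tokens) >= gate.m else DEFER


@dataclass(frozen=True)
class ModelVariant:
    name: str
    uses_tfidf_features: bool
    uses_expert_features: bool
    uses_rule_gate: bool
    uses_bnb: bool


VARIANTS: dict[str, ModelVariant] = {
    "A": ModelVariant("A", False, True, True, False),
    "B": ModelVariant("B", True, False, False, True),
    "C": ModelVariant("C", True, True, False, True),
    "PAMT": ModelVariant("PAMT", True, True, True, True),
}


def predict_variant(
    variant: ModelVariant,
    fitted: BNBParams | None,
    gate: RuleGate | None,
    doc: Transcript,
    fs: FeatureSpace,
) -> str:
    """Apply one variant's decision procedure to a preprocessed transcript.

    Variant A answers by the gate alone (no fallback classifier, so a
    deferral is negative); B and C are pure BNB; the PAMT variant runs
    the gate first and falls back to BNB on deferral.
    """
    if variant.uses_rule_gate and gate is None:
        raise ValueError(f"variant {variant.name} requires a rule gate")
    if variant.uses_bnb and fitted is None:
        raise ValueError(f"variant {variant.name} requires fitted BNB parameters")
    if variant.uses_rule_gate:
        if rule_gate(doc.tokens, gate) == FIRE_POSITIVE:
            return POSITIVE
        if not variant.uses_bnb:
            return NEGATIVE
    return predict_bnb(fitted, vectorize(doc.tokens, fs))


def build_feature_space(
    corpus: Corpus,
    variant: ModelVariant,
    expert_keywords: set[str],
    k: int = 160,
    config: FeatureConfig = FeatureConfig(),
) -> FeatureSpace:
    """Feature space for a variant: TF-IDF top-k, expert list, or their union."""
    if variant.uses_tfidf_features:
        fs = rank_and_select(corpus, k, config)
        if variant.uses_expert_features:
            fs = union_with_expert(fs, expert_keywords)
        return fs
    terms = sorted(expert_keywords)
    return FeatureSpace(terms=terms, origin=[ORIGIN_EXPERT] * len(terms))


@dataclass
class VariantModel:
    """A trained variant: feature space plus whichever of gate/BNB it uses."""

    variant: ModelVariant
    feature_space: FeatureSpace
    bnb: BNBParams | None = None
    gate: RuleGate | None = None

    def predict(self, doc: Transcript) -> str:
        return predict_variant(
            self.variant, self.bnb, self.gate, doc, self.feature_space
        )

    def predict_detail(self, doc: Transcript) -> dict:
        """Label plus the gate/BNB evidence behind it (decision transparency)."""
        detail: dict = {"id": doc.id, "variant": self.variant.name}
        deferred = True
        if self.variant.uses_rule_gate and self.gate is not None:
            n = self.gate.count(doc.tokens)
            fired = n >= self.gate.m
            detail["gate"] = {
                "keyword_count": n,
                "threshold": self.gate.m,
                "matched": sorted(self.gate.keywords.intersection(doc.tokens)),
                "fired": fired,
            }
            deferred = not fired
        if self.variant.uses_bnb and self.bnb is not None:
            scores = bnb_log_posterior(self.bnb, vectorize(doc.tokens, self.feature_space))
            shift = max(scores.values())
            z = sum(np.exp(s - shift) for s in scores.values())
            detail["bnb"] = {
                "log_posterior": scores,
                "posterior": {k: float(np.exp(s - shift) / z) for k, s in scores.items()},
            }
        detail["label"] = (
            POSITIVE
            if not deferred
            else (
                predict_bnb(self.bnb, vectorize(doc.tokens, self.feature_space))
                if self.variant.uses_bnb
                else NEGATIVE
            )
        )
        return detail

    # -- serialization: probabilities as repr() strings, bit-exact reload --

    def to_json(self) -> str:
        d: dict = {
            "variant": self.variant.name,
            "feature_space": {
                "terms": self.feature_space.terms,
                "origin": self.feature_space.origin,
                "config": self.feature_space.config,
            },
        }
        if self.bnb is not None:
            d["bnb"] = {
                "alpha": self.bnb.alpha,
                "class_log_prior": {
                    k: repr(v) for k, v in self.bnb.class_log_prior.items()
                },
                "cond_prob": {
                    k: [repr(float(p)) for p in v]
                    for k, v in self.bnb.cond_prob.items()
                },
            }
        if self.gate is not None:
            d["gate"] = {
                "keywords": sorted(self.gate.keywords),
                "m": self.gate.m,
                "count_mode": self.gate.count_mode,
            }
        return json.dumps(d, ensure_ascii=False, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "VariantModel":
        d = json.loads(text)
        fs = FeatureSpace(
            terms=d["feature_space"]["terms"],
            origin=d["feature_space"]["origin"],
            config=d["feature_space"].get("config", {}),
        )
        bnb = None
        if "bnb" in d:
            b = d["bnb"]
            bnb = BNBParams(
                feature_space=fs,
                class_log_prior={k: float(v) for k, v in b["class_log_prior"].items()},
                cond_prob={
                    k: np.array([float(p) for p in v])
                    for k, v in b["cond_prob"].items()
                },
                alpha=b["alpha"],
            )
        gate = None
        if "gate" in d:
            g = d["gate"]
            gate = RuleGate(set(g["keywords"]), m=g["m"], count_mode=g["count_mode"])
        return cls(variant=VARIANTS[d["variant"]], feature_space=fs, bnb=bnb, gate=gate)


def train_variant(
    train: Sequence[Transcript],
    variant: ModelVariant | str,
    expert_keywords: set[str],
    feature_space: FeatureSpace | None = None,
    k: int = 160,
    alpha: float = 1.0,
    priors: str = "empirical",
    gate_m: int = 2,
    gate_count_mode: str = "distinct_types",
    feature_config: FeatureConfig = FeatureConfig(),
) -> VariantModel:
    """Fit a variant on preprocessed transcripts.

    When ``feature_space`` is given it is reused as-is (the shared-space
    evaluation mode); otherwise it is built from the training documents.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    train_corpus = Corpus(train)
    if feature_space is None:
        feature_space = build_feature_space(
            train_corpus, variant, expert_keywords, k=k, config=feature_config
        )
    gate = None
    if variant.uses_rule_gate:
        gate = RuleGate(set(expert_keywords), m=gate_m, count_mode=gate_count_mode)
    bnb = None
    if variant.uses_bnb:
        x, _ = vectorize_corpus(train_corpus, feature_space)
        bnb = fit_bnb(
            x, [t.label for t in train], feature_space, alpha=alpha, priors=priors
        )
    return VariantModel(variant=variant, feature_space=feature_space, bnb=bnb, gate=gate)


ModelBuilder = Callable[[Sequence[Transcript]], Callable[[Transcript], str]]
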