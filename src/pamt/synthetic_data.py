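"""Synthetic emergency-call corpus generator.

Emulates the statistical structure the classifier assumes in a corpus of
short dispatch-call transcripts: a Zipf-distributed background
vocabulary that carries no class signal, plus a small set of *severity
keywords* that occur more often in positive (major-trauma) calls than in
negative ones, conditionally independently given the class — exactly the
Bernoulli naive Bayes generative model, which makes parameter recovery a
meaningful test.  A correlated-pair mode breaks that independence on
demand to exercise robustness and co-occurrence analysis.

Defaults mirror the corpus the method was designed for: 114 cases with
42 positives, a ~7000-term vocabulary, and token counts calibrated so
that rendered texts (5-character pseudo-words joined by spaces) average
about 241 characters with SD about 107.

Six rater certainty votes per case are simulated as Bernoulli draws
whose certainty probability increases with the document's distinct
severity-keyword count, optionally perturbed by noise.

``bayes_optimal_accuracy`` computes, by exact enumeration over keyword
presence patterns, the expected accuracy of the Bayes rule implied by
the generator under a fixed-composition validation fold — the analytic
ceiling that a well-trained classifier should approach.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .corpus import NEGATIVE, POSITIVE, N_RATERS, Corpus, Transcript

__all__ = [
    "KeywordSpec",
    "GeneratorConfig",
    "DEFAULT_SEVERITY_KEYWORDS",
    "generate_corpus",
    "generate_certainty_votes",
    "expert_keyword_list",
    "bayes_optimal_accuracy",
]


@dataclass(frozen=True)
class KeywordSpec:
    """One severity keyword with class-conditional occurrence probabilities."""

    term: str
    p_pos: float
    p_neg: float

    def __post_init__(self) -> None:
        # equality makes the keyword carry no class signal; permitted so
        # degenerate/uninformative configurations remain expressible
        if not 0.0 <= self.p_neg <= self.p_pos <= 1.0:
            raise ValueError(
                f"keyword {self.term!r} needs 0 <= p_neg <= p_pos <= 1, "
                f"got p_pos={self.p_pos}, p_neg={self.p_neg}"
            )


# Moderate class-conditional gaps: positive calls mention severity cues
# noticeably but not overwhelmingly more often, keeping the classes
# overlapping the way real triage calls are.
DEFAULT_SEVERITY_KEYWORDS: tuple[KeywordSpec, ...] = (
    KeywordSpec("unconscious", 0.30, 0.06),
    KeywordSpec("not_breathing", 0.12, 0.02),
    KeywordSpec("heavy_bleeding", 0.35, 0.12),
    KeywordSpec("trapped", 0.22, 0.06),
    KeywordSpec("rollover", 0.18, 0.07),
    KeywordSpec("ejected", 0.10, 0.02),
    KeywordSpec("head_injury", 0.33, 0.14),
    KeywordSpec("chest_pain", 0.20, 0.09),
    KeywordSpec("pale_face", 0.25, 0.10),
    KeywordSpec("high_speed", 0.30, 0.14),
    KeywordSpec("amputation", 0.08, 0.01),
    KeywordSpec("cannot_move", 0.35, 0.15),
)


@dataclass
class GeneratorConfig:
    """Study-condition parameters for corpus simulation.

    doc_length_* are token counts; with the default renderer (5-char
    pseudo-words + separating space, ~6 chars per token) mean 40 / SD
    17.8 yields character lengths around mean 241, SD 107.
    ``expert_overlap_fraction`` is the share of severity keywords the
    simulated experts hand to the rule gate (the most discriminative
    ones first).  ``certainty_rule`` is "logistic" (probability of a
    certain vote rises linearly with distinct keyword count) or "step"
    (certain iff the count reaches ``certainty_step_threshold``);
    ``certainty_noise`` replaces each vote by a fair coin with that
    probability.  ``correlated_pairs`` lists (term_a, term_b, boost)
    triples: whenever a is present, b's probability is raised by boost.
    """

    n_cases: int = 114
    n_positive: int = 42
    background_vocab_size: int = 7000
    zipf_exponent: float = 1.1
    severity_keywords: tuple[KeywordSpec, ...] = DEFAULT_SEVERITY_KEYWORDS
    doc_length_mean: float = 40.0
    doc_length_sd: float = 17.8
    doc_length_min: int = 5
    expert_overlap_fraction: float = 0.8
    certainty_rule: str = "logistic"
    certainty_base: float = 0.15
    certainty_slope: float = 0.15
    certainty_step_threshold: int = 3
    certainty_noise: float = 0.1
    correlated_pairs: tuple[tuple[str, str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        self.severity_keywords = tuple(
            kw if isinstance(kw, KeywordSpec) else KeywordSpec(*kw)
            for kw in self.severity_keywords
        )
        self.correlated_pairs = tuple(tuple(p) for p in self.correlated_pairs)
        self.validate()

    def validate(self) -> None:
        if not 0 < self.n_positive < self.n_cases:
            raise ValueError("need 0 < n_positive < n_cases")
        if self.background_vocab_size < 1:
            raise ValueError("background vocabulary must be non-empty")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be > 0")
        if self.doc_length_min < 1 or self.doc_length_mean < self.doc_length_min:
            raise ValueError("document lengths must be >= 1 token")
        if not 0.0 <= self.expert_overlap_fraction <= 1.0:
            raise ValueError("expert_overlap_fraction must be in [0, 1]")
        if not 0.0 <= self.certainty_noise <= 1.0:
            raise ValueError("certainty_noise must be in [0, 1]")
        if self.certainty_rule not in ("logistic", "step"):
            raise ValueError(f"unknown certainty_rule {self.certainty_rule!r}")
        terms = {kw.term for kw in self.severity_keywords}
        if len(terms) != len(self.severity_keywords):
            raise ValueError("duplicate severity keyword terms")
        for a, b, boost in self.correlated_pairs:
            if a not in terms or b not in terms or a == b:
                raise ValueError(f"correlated pair ({a!r}, {b!r}) invalid")
            if not 0.0 <= boost <= 1.0:
                raise ValueError("correlation boost must be in [0, 1]")

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        d = json.loads(text)
        if "severity_keywords" in d:
            d["severity_keywords"] = tuple(
                KeywordSpec(**kw) if isinstance(kw, dict) else KeywordSpec(*kw)
                for kw in d["severity_keywords"]
            )
        return cls(**d)


def expert_keyword_list(cfg: GeneratorConfig) -> list[str]:
    """Severity keywords the simulated experts hand to the gate.

    The most discriminative fraction (by p_pos - p_neg, ties broken by
    term) of the keyword list, modelling experts who name the strong
    cues but miss some weaker ones.
    """
    n = round(cfg.expert_overlap_fraction * len(cfg.severity_keywords))
    ranked = sorted(
        cfg.severity_keywords, key=lambda kw: (-(kw.p_pos - kw.p_neg), kw.term)
    )
    return sorted(kw.term for kw in ranked[:n])


def _background_probs(cfg: GeneratorConfig) -> np.ndarray:
    ranks = np.arange(1, cfg.background_vocab_size + 1, dtype=float)
    w = ranks ** (-cfg.zipf_exponent)
    return w / w.sum()


def generate_corpus(
    cfg: GeneratorConfig, render: bool = False
) -> tuple[Corpus, dict]:
    """Draw a labelled corpus and return it with its ground-truth record.

    Class counts are exact (``n_positive`` positives), with label order
    shuffled.  Each document draws its token count from a truncated
    normal, includes each severity keyword independently with its
    class-conditional probability (correlated pairs applied after the
    independent draws), and fills the rest with Zipf-distributed
    background words; positions are shuffled.  With ``render=True`` the
    token list is additionally joined into ``raw_text`` so the full
    preprocessing path can run end-to-end.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = np.array(
        [POSITIVE] * cfg.n_positive + [NEGATIVE] * (cfg.n_cases - cfg.n_positive)
    )
    rng.shuffle(labels)
    bg_probs = _background_probs(cfg)
    vocab_ids = np.arange(cfg.background_vocab_size)
    pad = len(str(cfg.background_vocab_size))
    kw_terms = [kw.term for kw in cfg.severity_keywords]
    kw_index = {t: i for i, t in enumerate(kw_terms)}
    transcripts = []
    for i, label in enumerate(labels):
        p = np.array(
            [kw.p_pos if label == POSITIVE else kw.p_neg for kw in cfg.severity_keywords]
        )
        present = rng.random(len(p)) < p
        for a, b, boost in cfg.correlated_pairs:
            if present[kw_index[a]] and not present[kw_index[b]]:
                present[kw_index[b]] = rng.random() < boost
        kws = [t for t, on in zip(kw_terms, present) if on]
        length = max(
            cfg.doc_length_min,
            int(round(rng.normal(cfg.doc_length_mean, cfg.doc_length_sd))),
            len(kws),
        )
        n_bg = length - len(kws)
        bg = rng.choice(vocab_ids, size=n_bg, p=bg_probs)
        tokens = [f"w{j:0{pad}d}" for j in bg] + kws
        order = rng.permutation(length)
        tokens = [tokens[j] for j in order]
        transcripts.append(
            Transcript(
                id=f"case{i:04d}",
                raw_text=" ".join(tokens) if render else "",
                tokens=[] if render else tokens,
                label=str(label),
            )
        )
    truth = {
        "seed": cfg.seed,
        "n_cases": cfg.n_cases,
        "n_positive": cfg.n_positive,
        "prevalence": cfg.n_positive / cfg.n_cases,
        "severity_keywords": [
            {"term": kw.term, "p_pos": kw.p_pos, "p_neg": kw.p_neg}
            for kw in cfg.severity_keywords
        ],
        "expert_keywords": expert_keyword_list(cfg),
        "background_vocab_size": cfg.background_vocab_size,
        "zipf_exponent": cfg.zipf_exponent,
        "correlated_pairs": [list(p) for p in cfg.correlated_pairs],
    }
    corpus = Corpus(
        transcripts,
        provenance={"generator": "pamt.synthetic_data", "seed": cfg.seed},
    )
    return corpus, truth


def _certainty_prob(cfg: GeneratorConfig, n_keywords: int) -> float:
    if cfg.certainty_rule == "step":
        return 1.0 if n_keywords >= cfg.certainty_step_threshold else 0.0
    return min(1.0, max(0.0, cfg.certainty_base + cfg.certainty_slope * n_keywords))


def generate_certainty_votes(cfg: GeneratorConfig, corpus: Corpus) -> Corpus:
    """Attach six simulated rater certainty votes to every case.

    Each rater votes *certain* with a probability that increases with
    the document's distinct severity-keyword count; with probability
    ``certainty_noise`` a vote is replaced by a fair coin.  Uses an rng
    stream derived from (seed, 1), independent of the corpus draw.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    kw_terms = {kw.term for kw in cfg.severity_keywords}
    out = []
    for t in corpus:
        n_kw = len(kw_terms.intersection(t.tokens or t.raw_text.split()))
        p = _certainty_prob(cfg, n_kw)
        votes = []
        for _ in range(N_RATERS):
            v = 1 if rng.random() < p else 0
            if cfg.certainty_noise and rng.random() < cfg.certainty_noise:
                v = 1 if rng.random() < 0.5 else 0
            votes.append(v)
        out.append(replace(t, certainty_votes=votes))
    return Corpus(out, provenance=dict(corpus.provenance))


def bayes_optimal_accuracy(
    cfg: GeneratorConfig,
    val_pos: int = 3,
    val_neg: int = 7,
    decision_prior_pos: float | None = None,
    max_exact_keywords: int = 20,
    mc_samples: int = 200_000,
    mc_seed: int = 0,
) -> float:
    """Expected accuracy of the generator-implied Bayes rule.

    The Bayes classifier observes only the keyword presence pattern
    (background words carry no signal) and predicts positive when
    log-likelihood-ratio + log-prior-odds >= 0, the positive tie-break
    matching the classifier's convention.  ``decision_prior_pos``
    defaults to the corpus prevalence n_positive/n_cases — what an
    empirically-primed model trained on this corpus converges to.
    Expected accuracy weights the two class-conditional correctness
    probabilities by the fixed validation composition (default 3:7).

    Exact enumeration over the 2^K presence patterns is used for up to
    ``max_exact_keywords`` keywords; beyond that a Monte-Carlo estimate
    over ``mc_samples`` pattern draws per class is returned.
    """
    if decision_prior_pos is None:
        decision_prior_pos = cfg.n_positive / cfg.n_cases
    if not 0.0 < decision_prior_pos < 1.0:
        raise ValueError("decision prior must be in (0, 1)")
    p_pos = np.array([kw.p_pos for kw in cfg.severity_keywords])
    p_neg = np.array([kw.p_neg for kw in cfg.severity_keywords])
    log_prior_odds = math.log(decision_prior_pos) - math.log1p(-decision_prior_pos)
    w_pos = val_pos / (val_pos + val_neg)
    w_neg = val_neg / (val_pos + val_neg)
    k = len(p_pos)

    with np.errstate(divide="ignore"):
        term_on = np.log(p_pos) - np.log(p_neg)
        term_off = np.log1p(-p_pos) - np.log1p(-p_neg)

    def _llr(x: np.ndarray) -> np.ndarray:
        # elementwise select avoids 0 * inf = nan at degenerate probabilities
        return np.where(x == 1, term_on, term_off).sum(axis=1)

    if k <= max_exact_keywords:
        patterns = np.array(list(itertools.product((0, 1), repeat=k)), dtype=float)
        pred_pos = _llr(patterns) + log_prior_odds >= 0
        lik_pos = np.prod(np.where(patterns == 1, p_pos, 1 - p_pos), axis=1)
        lik_neg = np.prod(np.where(patterns == 1, p_neg, 1 - p_neg), axis=1)
        return float(
            w_pos * lik_pos[pred_pos].sum() + w_neg * lik_neg[~pred_pos].sum()
        )
    rng = np.random.default_rng(mc_seed)
    x_pos = (rng.random((mc_samples, k)) < p_pos).astype(float)
    x_neg = (rng.random((mc_samples, k)) < p_neg).astype(float)
    acc_pos = float((_llr(x_pos) + log_prior_odds >= 0).mean())
    acc_neg = float((_llr(x_neg) + log_prior_odds < 0).mean())
    return w_pos * acc_pos + w_neg * acc_neg
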