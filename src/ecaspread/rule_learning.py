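"""Learning ECA evolution rules from image pairs.

The corpus protocol: for each of the 128 even rules, random 20×20 presence
images are seeded with 100, 200, and 300 ones (500 per density by default),
evolved one step under the rule, and the (before, after) pair is labelled
with the generating rule — 500 × 3 × 128 = 192,000 pairs at full scale.

A one-step ECA transition is fully determined by purely local evidence: for
each of the 8 three-cell neighbourhoods that occurs in the flattened
``before`` state, the ``after`` state reveals the rule's output bit.  The
classifier therefore summarises a pair into 16 transition-pattern features
(per neighbourhood, the fraction of positions showing that neighbourhood
with after-bit 0 and with after-bit 1) and feeds them to a small multilayer
perceptron with a 128-way softmax.  Pairs in which some neighbourhood never
occurs are genuinely ambiguous — several rules reproduce them exactly — and
set the (sub-1%) ceiling on attainable accuracy; alongside plain held-out
accuracy, an "oracle-consistent" accuracy (argmax lies in the exact
consistent-rule set) is available via :func:`oracle_consistent_accuracy`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

from . import eca_engine
from .rasterization import ImageSequence, PresenceImage

__all__ = [
    "CorpusConfig",
    "TrainingCorpus",
    "RuleDistribution",
    "RuleClassifier",
    "generate_training_corpus",
    "validate_corpus",
    "train_rule_classifier",
    "predict_pair_distribution",
    "cluster_rule_distribution",
    "oracle_consistent_accuracy",
]

_N_CELLS = 400
_NORMALIZATION_TOL = 1e-9


@dataclass(frozen=True)
class CorpusConfig:
    """Corpus protocol: seeds per density × densities × 128 even rules."""

    seeds_per_density: int = 500
    densities: tuple[int, ...] = (100, 200, 300)
    split_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seeds_per_density < 1:
            raise ValueError("seeds_per_density must be >= 1")
        if any(not 0 < d <= _N_CELLS for d in self.densities):
            raise ValueError(f"densities must be in (0, {_N_CELLS}]")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")

    @property
    def size(self) -> int:
        return self.seeds_per_density * len(self.densities) * eca_engine.N_EVEN_RULES


@dataclass
class TrainingCorpus:
    """Labelled one-step transitions: flattened before/after states plus the
    generating rule number per pair."""

    before: np.ndarray  # (n, 400) uint8
    after: np.ndarray  # (n, 400) uint8
    labels: np.ndarray  # (n,) int rule numbers

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class RuleDistribution:
    """A probability vector over even rule numbers; sums to 1."""

    probs: dict[int, float]

    def __post_init__(self) -> None:
        if any(r % 2 for r in self.probs):
            raise ValueError("rule distribution supported on an odd rule")
        if any(p < 0 for p in self.probs.values()):
            raise ValueError("rule probabilities must be non-negative")
        total = sum(self.probs.values())
        if abs(total - 1.0) > _NORMALIZATION_TOL:
            raise ValueError(f"rule distribution sums to {total}, not 1")

    def __getitem__(self, rule: int) -> float:
        return self.probs.get(rule, 0.0)

    @property
    def support(self) -> list[int]:
        return sorted(r for r, p in self.probs.items() if p > 0)

    def argmax(self) -> int:
        return max(self.probs, key=lambda r: (self.probs[r], -r))


def _neighborhood_index(states: np.ndarray) -> np.ndarray:
    """Per-position 3-cell neighbourhood code (0..7) with zero boundaries,
    for each row of a (n, cells) state array."""
    zeros = np.zeros((states.shape[0], 1), dtype=np.uint8)
    left = np.concatenate((zeros, states[:, :-1]), axis=1)
    right = np.concatenate((states[:, 1:], zeros), axis=1)
    return 4 * left + 2 * states + right


def pair_features(before: np.ndarray, after: np.ndarray) -> np.ndarray:
    """16 transition-pattern features per pair.

    Feature ``2*n + b`` is the fraction of positions whose neighbourhood in
    ``before`` is ``n`` and whose ``after`` bit is ``b``.  Accepts (400,)
    single pairs or (n, 400) batches; returns (16,) or (n, 16).
    """
    b = np.atleast_2d(np.asarray(before, dtype=np.uint8))
    a = np.atleast_2d(np.asarray(after, dtype=np.uint8))
    if b.shape != a.shape:
        raise ValueError(f"before/after shape mismatch: {b.shape} vs {a.shape}")
    n, cells = b.shape
    idx = _neighborhood_index(b)
    code = (np.arange(n)[:, None] * 16 + idx * 2 + a).ravel()
    feats = np.bincount(code, minlength=n * 16).reshape(n, 16) / cells
    return feats[0] if np.asarray(before).ndim == 1 else feats


def generate_training_corpus(config: CorpusConfig = CorpusConfig()) -> TrainingCorpus:
    """Generate and validate the labelled transition corpus.

    For each rule and density, ``seeds_per_density`` random states with
    exactly that many ones are drawn and evolved one step.  Every pair is
    checked to be the exact one-step evolution of its ``before`` under its
    label.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    blocks_before, blocks_after, blocks_label = [], [], []
    for rule in eca_engine.even_rules():
        for density in config.densities:
            # exactly `density` ones per row, positions uniform without replacement
            scores = rng.random((config.seeds_per_density, _N_CELLS))
            before = (scores.argsort(axis=1) < density).astype(np.uint8)
            after = eca_engine.step_batch(before, rule)
            blocks_before.append(before)
            blocks_after.append(after)
            blocks_label.append(np.full(config.seeds_per_density, rule.number))
    corpus = TrainingCorpus(
        before=np.concatenate(blocks_before),
        after=np.concatenate(blocks_after),
        labels=np.concatenate(blocks_label),
    )
    ok = validate_corpus(corpus)
    if not ok.all():
        raise AssertionError(f"{(~ok).sum()} corpus pairs fail the rule-consistency check")
    return corpus


def validate_corpus(corpus: TrainingCorpus) -> np.ndarray:
    """Boolean mask: pair i's label is consistent with its transition.

    Equivalent to ``label in consistent_rules(pair)`` for every pair, but
    vectorised: the label rule's truth-table bit must match the observed
    after-bit at every position.
    """
    idx = _neighborhood_index(corpus.before)
    expected = (corpus.labels[:, None] >> idx) & 1
    return (expected == corpus.after).all(axis=1)


class RuleClassifier:
    """Image-pair → rule-probability classifier.

    A multilayer perceptron over the 16 transition-pattern features; emits a
    normalized probability vector over the even rules seen in training.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (64, 64),
        max_iter: int = 300,
        seed: int = 0,
    ):
        self._mlp = MLPClassifier(
            hidden_layer_sizes=hidden_layer_sizes,
            max_iter=max_iter,
            random_state=seed,
            early_stopping=True,
            n_iter_no_change=10,
        )
        self._fitted = False

    def fit(self, before: np.ndarray, after: np.ndarray, labels: np.ndarray) -> "RuleClassifier":
        # early stopping needs a meaningful validation split
        self._mlp.set_params(early_stopping=len(labels) >= 200)
        self._mlp.fit(pair_features(before, after), labels)
        self._fitted = True
        return self

    @property
    def classes_(self) -> np.ndarray:
        self._require_fitted()
        return self._mlp.classes_

    def _require_fitted(self) -> None:
        if not self._fitted:
            raise RuntimeError("classifier has not been trained; call fit() first")

    def predict_proba_pairs(self, before: np.ndarray, after: np.ndarray) -> np.ndarray:
        """(n, n_classes) probability matrix for a batch of pairs."""
        self._require_fitted()
        feats = np.atleast_2d(pair_features(before, after))
        return self._mlp.predict_proba(feats)

    def accuracy(self, before: np.ndarray, after: np.ndarray, labels: np.ndarray) -> float:
        self._require_fitted()
        return float(self._mlp.score(pair_features(before, after), labels))

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "RuleClassifier":
        clf = joblib.load(path)
        if not isinstance(clf, RuleClassifier):
            raise TypeError(f"{path} does not contain a RuleClassifier")
        return clf


def train_rule_classifier(
    corpus: TrainingCorpus,
    split_fraction: float = 0.8,
    seed: int = 0,
    **classifier_kwargs,
) -> tuple[RuleClassifier, float]:
    """Train on a stratified split and report held-out accuracy.

    ``split_fraction`` of the corpus trains the model; accuracy is measured
    on the remaining held-out pairs, stratified by rule label.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must be in (0, 1)")
    n_classes = len(np.unique(corpus.labels))
    if n_classes < 2:
        # degenerate single-class corpus: nothing to separate
        clf = RuleClassifier(seed=seed)
        clf.fit(corpus.before, corpus.after, corpus.labels)
        return clf, 1.0
    idx_train, idx_test = train_test_split(
        np.arange(len(corpus)),
        train_size=split_fraction,
        stratify=corpus.labels,
        random_state=seed,
    )
    clf = RuleClassifier(seed=seed, **classifier_kwargs)
    clf.fit(corpus.before[idx_train], corpus.after[idx_train], corpus.labels[idx_train])
    acc = clf.accuracy(corpus.before[idx_test], corpus.after[idx_test], corpus.labels[idx_test])
    return clf, acc


def _pair_states(
    pair: tuple[PresenceImage | np.ndarray, PresenceImage | np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    first, second = pair
    a = eca_engine.flatten(first) if isinstance(first, PresenceImage) else np.asarray(first, np.uint8)
    b = eca_engine.flatten(second) if isinstance(second, PresenceImage) else np.asarray(second, np.uint8)
    if a.shape != b.shape:
        raise ValueError(f"pair shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def _to_distribution(classes: np.ndarray, proba: np.ndarray) -> RuleDistribution:
    proba = np.clip(proba, 0.0, None)
    proba = proba / proba.sum()
    return RuleDistribution(probs={int(c): float(p) for c, p in zip(classes, proba)})


def predict_pair_distribution(
    classifier: RuleClassifier,
    pair: tuple[PresenceImage | np.ndarray, PresenceImage | np.ndarray],
) -> RuleDistribution:
    """Normalized rule distribution for one (before, after) image pair."""
    a, b = _pair_states(pair)
    proba = classifier.predict_proba_pairs(a[None, :], b[None, :])[0]
    return _to_distribution(classifier.classes_, proba)


def cluster_rule_distribution(
    classifier: RuleClassifier,
    seq: ImageSequence,
    mode: str = "aggregate",
) -> RuleDistribution:
    """Rule distribution for a cluster's image sequence C0 → … → Cn.

    mode="aggregate" (default) averages the softmax over every consecutive
    pair; mode="final_pair" uses only (C(n-1), Cn).  The two coincide for a
    2-image sequence.
    """
    if len(seq) < 2:
        raise ValueError("image sequence must contain at least 2 images")
    if mode not in ("aggregate", "final_pair"):
        raise ValueError(f"unknown mode {mode!r}")
    states = np.array([eca_engine.flatten(img) for img in seq])
    if mode == "final_pair":
        before, after = states[-2:-1], states[-1:]
    else:
        before, after = states[:-1], states[1:]
    proba = classifier.predict_proba_pairs(before, after).mean(axis=0)
    return _to_distribution(classifier.classes_, proba)


def oracle_consistent_accuracy(
    classifier: RuleClassifier, corpus: TrainingCorpus
) -> float:
    """Fraction of pairs whose predicted argmax lies in the exact
    consistent-rule set — the accuracy notion robust to label degeneracy."""
    proba = classifier.predict_proba_pairs(corpus.before, corpus.after)
    argmax = classifier.classes_[proba.argmax(axis=1)]
    hits = sum(
        int(argmax[i]) in eca_engine.consistent_rules((corpus.before[i], corpus.after[i]))
        for i in range(len(corpus))
    )
    return hits / len(corpus)
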