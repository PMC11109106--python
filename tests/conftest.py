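import numpy as np
import pytest

from ecaspread import eca_engine, rule_learning

# Printed per-cluster assessment table used as input for arithmetic audits:
# (cluster_id, n_presence, SI, HS, SA, lon, lat)
TABLE1 = [
    (1, 77, 3.25, 0.331892778, 1.078651528, 127.99, 36.42),
    (2, 83, 2.87, 0.336620682, 0.966101357, 127.27, 36.42),
    (3, 267, 3.1, 0.772864513, 2.395879991, 128.47, 35.36),
    (4, 202, 1.0, 0.740367631, 0.740367631, 126.64, 35.47),
    (5, 168, 2.48, 0.794083093, 1.96932607, 126.43, 34.58),
    (6, 103, 1.51, 0.594828446, 0.898190953, 127.2, 35.3),
    (7, 127, 3.25, 0.713751758, 2.319693214, 126.77, 36.1),
    (8, 125, 3.24, 0.65006152, 2.106199325, 128.33, 36.0),
    (9, 96, 2.08, 0.460205108, 0.957226626, 126.47, 36.71),
    (10, 58, 3.46, 0.473968133, 1.639929741, 128.6, 36.33),
    (11, 205, 1.26, 0.791182732, 0.996890243, 126.46, 35.08),
    (12, 135, 3.25, 0.781342992, 2.539364724, 126.76, 35.93),
    (13, 98, 3.42, 0.621743520, 2.12636284, 128.14, 35.4),
    (14, 68, 2.23, 0.634174926, 1.414210085, 127.36, 34.73),
    (15, 87, 1.35, 0.690117529, 0.931658665, 128.88, 35.18),
    (16, 113, 3.16, 0.673967381, 2.129736922, 127.01, 35.78),
    (17, 136, 2.91, 0.701436489, 2.041180182, 127.91, 35.11),
    (18, 107, 1.1, 0.625008290, 0.687509118, 129.21, 35.57),
    (19, 70, 2.66, 0.697356021, 1.854967015, 126.11, 34.73),
    (20, 65, 2.86, 0.619350400, 1.771342144, 128.88, 35.89),
    (21, 58, 2.14, 0.617724528, 1.321930491, 126.88, 34.58),
    (22, 30, 3.33, 0.573416667, 1.9094775, 129.28, 35.99),
    (23, 37, 2.02, 0.364914600, 0.737127492, 127.81, 35.53),
    (24, 37, 2.21, 0.575529162, 1.271919448, 127.03, 34.99),
    (25, 65, 2.22, 0.804474672, 1.785933772, 126.66, 34.98),
]

# Published four-level grouping of the same 25 clusters
TABLE2_GROUPS = {
    "I": {3, 7, 8, 12, 13, 16, 17},
    "II": {5, 10, 19, 20, 22, 25},
    "III": {1, 14, 21, 24},
    "IV": {2, 4, 6, 9, 11, 15, 18, 23},
}


@pytest.fixture(scope="session")
def rule_intensities():
    """Per-rule intensities for all 128 even rules under the study protocol."""
    return eca_engine.all_rule_intensities(eca_engine.SimConfig(seed=0))


@pytest.fixture(scope="session")
def trained_classifier():
    """A rule classifier trained at 150 pairs per rule (50 per density)."""
    corpus = rule_learning.generate_training_corpus(
        rule_learning.CorpusConfig(seeds_per_density=50, seed=0)
    )
    clf, acc = rule_learning.train_rule_classifier(corpus, seed=0)
    return clf, acc, corpus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
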