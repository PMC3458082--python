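"""Shared synthetic fixtures.

One seeded fixture set (50 designed hairpin positives, 50 pseudohairpin
negatives, a toy genome with known loci, a profile library and a trained
committee) is built once per session and reused across the suite.
"""

import numpy as np
import pytest

from premirna.datasets import build_negative, build_positive
from premirna.model import BaggingConfig, bag_train
from premirna.features import feature_names
from premirna.pipeline import feature_matrix, library_from_positives
from premirna.synthetic import gen_hairpin_set, gen_pseudohairpins

N_PER_CLASS = 50
SEED = 2012


@pytest.fixture(scope="session")
def hairpin_set():
    return gen_hairpin_set(n=N_PER_CLASS, seed=SEED)


@pytest.fixture(scope="session")
def positives(hairpin_set):
    pos = build_positive(hairpin_set.precursors, hairpin_set.matures,
                         hairpin_set.genome)
    assert len(pos) == N_PER_CLASS
    return pos


@pytest.fixture(scope="session")
def negatives():
    groups = {}
    for rec, cat in gen_pseudohairpins(n=N_PER_CLASS, seed=SEED + 1):
        groups.setdefault(cat, []).append(rec)
    neg = build_negative(groups)
    assert len(neg) == N_PER_CLASS
    return neg


@pytest.fixture(scope="session")
def library(positives):
    return library_from_positives(positives)


@pytest.fixture(scope="session")
def labeled_matrix(positives, negatives, library):
    X, y = feature_matrix(positives + negatives, library)
    return X, y


@pytest.fixture(scope="session")
def trained_model(labeled_matrix):
    X, y = labeled_matrix
    return bag_train(X, y, BaggingConfig(n_bags=10, seed=SEED),
                     feature_names=feature_names())


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
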