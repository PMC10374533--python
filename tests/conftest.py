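"""Shared fixtures: synthetic corpora and (expensively) trained models.

The full-scale corpus and the trained scaled-down models are session-scoped
because training dominates the suite's runtime; every test that needs a
fitted classifier shares them.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

CORPUS_SEED = 7
TRAIN_SEEDS = (1, 2, 3)
TRAIN_EPOCHS = 5

#: reduced architecture used throughout the suite
SMALL_FILTERS = (8, 16, 24, 32, 40)
SMALL_HEAD = 64


@pytest.fixture(scope="session")
def corpus():
    """Full synthetic corpus (~600 segments) shared across the session."""
    from botopam.synth import make_training_corpus

    return make_training_corpus(seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def corpus_split(corpus):
    """Deterministic train/test partition of the session corpus."""
    from botopam.annotations import split_train_test

    train_df, test_df = split_train_test(corpus.manifest, "varzea", seed=CORPUS_SEED)
    train_mask = corpus.manifest["segment_id"].isin(train_df["segment_id"]).to_numpy()
    return train_mask, train_df, test_df


def _train_one(corpus, train_mask, seed):
    from botopam.augmentation import AugmentPolicy
    from botopam.cnn import SpectrogramCNN

    labelsets = [ls for ls, m in zip(corpus.labelsets, train_mask) if m]
    clf = SpectrogramCNN(
        block_filters=SMALL_FILTERS,
        head_filters=SMALL_HEAD,
        epochs=TRAIN_EPOCHS,
        seed=seed,
        augment=AugmentPolicy(min_labels_per_epoch=100, seed=seed),
    )
    clf.fit(corpus.X[train_mask], corpus.y_columns[train_mask], labelsets=labelsets)
    return clf


@pytest.fixture(scope="session")
def trained_models(corpus, corpus_split):
    """Three scaled-down classifiers trained with different seeds."""
    train_mask, _, _ = corpus_split
    return {s: _train_one(corpus, train_mask, s) for s in TRAIN_SEEDS}


@pytest.fixture(scope="session")
def trained_model(trained_models):
    return trained_models[TRAIN_SEEDS[0]]


@pytest.fixture(scope="session")
def heldout_eval(corpus, corpus_split, trained_models):
    """Held-out Q75 scores and labels for every trained seed."""
    from botopam.annotations import TARGET_CLASSES
    from botopam.evaluation import q75_scores

    train_mask, _, _ = corpus_split
    X = corpus.X[~train_mask]
    y = corpus.y_segment[~train_mask]
    out = {}
    for seed, clf in trained_models.items():
        q75 = q75_scores(clf.predict_proba(X))
        out[seed] = (
            {c: y[:, i] for i, c in enumerate(TARGET_CLASSES)},
            {c: q75[:, i] for i, c in enumerate(TARGET_CLASSES)},
        )
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
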