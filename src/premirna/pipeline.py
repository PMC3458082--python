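"""Glue between candidates, profile scoring, features and the classifier."""

from __future__ import annotations

import numpy as np

from .datasets import LabeledCandidate
from .encoding import encode
from .features import assemble, feature_names
from .folding import HairpinCandidate
from .model import BaggedModel, BaggingConfig, bag_train, layout_hash
from .profiles import ProfileLibrary, build_library, scan


def candidate_vector(candidate: HairpinCandidate, library: ProfileLibrary) -> np.ndarray:
    """Full 6,622-value feature vector, profile score included."""
    return assemble(candidate, scan(library, candidate.structure))


def feature_matrix(
    candidates: list[LabeledCandidate], library: ProfileLibrary
) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([candidate_vector(c.candidate, library) for c in candidates])
    y = np.array([c.label for c in candidates], dtype=int)
    return X, y


def library_from_positives(
    positives: list[LabeledCandidate],
    threshold: float = 0.80,
    species: str = "synthetic",
) -> ProfileLibrary:
    """Profile library from mature-annotated positive candidates."""
    encodings = [
        encode(c.candidate.structure, c.candidate.mature, source_id=c.source_id)
        for c in positives
        if c.candidate.mature is not None
    ]
    return build_library(encodings, threshold=threshold, species=species)


def train_candidates(
    train: list[LabeledCandidate],
    library: ProfileLibrary,
    cfg: BaggingConfig | None = None,
) -> BaggedModel:
    X, y = feature_matrix(train, library)
    model = bag_train(X, y, cfg, feature_names=feature_names())
    return model


def check_layout(model: BaggedModel) -> None:
    """Refuse to use a model trained against a different feature layout."""
    expected = layout_hash(feature_names())
    if model.layout_hash and model.layout_hash != expected:
        raise ValueError(
            f"model feature-layout hash {model.layout_hash} does not match "
            f"this package's layout {expected}"
        )
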