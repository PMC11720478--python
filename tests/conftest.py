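import numpy as np
import pandas as pd
import pytest

import freeassoc as fa


@pytest.fixture
def toy_frame() -> pd.DataFrame:
    """Hand-countable two-participant mini-snowball table."""
    rows = [
        # participant, gender, cue, response, level
        ("p1", "male", "risk", "danger", "first"),
        ("p1", "male", "risk", "chance", "first"),
        ("p1", "male", "danger", "fear", "second"),
        ("p1", "male", "danger", "threat", "second"),
        ("p1", "male", "chance", "luck", "second"),
        ("p2", "female", "risk", "danger", "first"),
        ("p2", "female", "risk", "reward", "first"),
        ("p2", "female", "danger", "threat", "second"),
        ("p2", "female", "reward", "money", "second"),
    ]
    return pd.DataFrame(
        rows, columns=["participant_id", "gender", "cue", "response", "level"]
    )


@pytest.fixture
def toy_study(toy_frame) -> fa.AssociationStudy:
    return fa.import_study(
        toy_frame, participant_vars=["gender"], response_vars=["level"]
    )


@pytest.fixture(scope="session")
def small_config() -> fa.GeneratorConfig:
    return fa.default_config(
        n_participants=60, n_topics=3, vocab_size=30, seed=11
    )


@pytest.fixture(scope="session")
def small_study(small_config) -> fa.AssociationStudy:
    """Generated 3-topic study taken through targets + counting."""
    study = fa.generate_study(small_config)
    study = fa.normalize(study)
    study = fa.set_targets(study, "cues")
    return fa.count_targets(study)


@pytest.fixture(scope="session")
def embedded_study(small_study) -> fa.AssociationStudy:
    study = fa.embed_targets(small_study, n_dim=20)
    return fa.cluster_targets(study, method="louvain", seed=5)


@pytest.fixture
def blob_study() -> fa.AssociationStudy:
    """Study whose embedding is three well-separated Gaussian blobs."""
    rng = np.random.default_rng(7)
    centers = np.array([[10.0, 0, 0], [0, 10.0, 0], [0, 0, 10.0]])
    vectors, labels, truth = [], [], []
    for c in range(3):
        pts = centers[c] + 0.1 * rng.standard_normal((12, 3))
        vectors.append(pts)
        labels += [f"w{c}_{i}" for i in range(12)]
        truth += [c] * 12
    vectors = np.vstack(vectors)
    frame = pd.DataFrame(
        {"participant_id": "p1", "cue": "top", "response": labels}
    )
    study = fa.import_study(frame)
    study = fa.set_targets(study, "responses")
    study.embedding = fa.EmbeddingMatrix(labels=labels, vectors=vectors)
    study.targets.attrs["truth"] = truth
    return study
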