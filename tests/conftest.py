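import numpy as np
import pytest

import squatcheck as sq


@pytest.fixture(scope="session")
def clean_squat():
    """One noiseless correct squat at 90 deg depth, 60 frames."""
    return sq.simulate_squat(
        sq.SquatSimParams(noise_px=0.0, depth_deg=90.0, seed=7)
    ).seq


@pytest.fixture(scope="session")
def noisy_squat():
    return sq.simulate_squat(
        sq.SquatSimParams(noise_px=1.0, depth_deg=95.0, seed=11)
    ).seq


@pytest.fixture(scope="session")
def separation_dataset():
    """Balanced correct (95+-5 deg) vs shallow (45+-5 deg) dataset, noise 1 px.

    Preprocessed once and shared: (features, labels, subject groups).
    """
    data = sq.simulate_dataset(100, seed=3)
    feats = [sq.preprocess(d.seq) for d in data]
    labels = [d.label for d in data]
    groups = [d.subject for d in data]
    return feats, labels, groups


@pytest.fixture(scope="session")
def trained_full_model(separation_dataset):
    """Full-variant model trained on the separation dataset (subject-wise split)."""
    feats, labels, groups = separation_dataset
    tr, va, te = sq.subject_split(len(feats), groups, seed=0)
    model = sq.build_model(sq.ModelConfig(seed=0, max_epochs=40))
    sq.train(
        model,
        [(feats[i], labels[i]) for i in tr],
        [(feats[i], labels[i]) for i in va],
    )
    return model, (tr, va, te)
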