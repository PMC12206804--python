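import numpy as np
import pytest

from iemg.features import FeatureMatrix
from iemg.synth import (MixingModel, Movement, ProtocolSpec,
                        crosstalk_mixing, generate_recording,
                        one_hot_activation)


@pytest.fixture
def small_protocol():
    movements = (Movement("open_hand", "gross"),
                 Movement("close_hand", "gross"),
                 Movement("flex_index", "finger"))
    return ProtocolSpec(movements=movements, repetitions_per_movement=2,
                        contraction_duration_s=1.5, rest_duration_s=0.8,
                        sampling_rate_hz=500)


@pytest.fixture
def small_mixing(small_protocol):
    return MixingModel(
        mixing_matrix=crosstalk_mixing(3, 0.2),
        activation_map=one_hot_activation(small_protocol.movements, 3),
        noise_rms=0.05)


@pytest.fixture
def small_recording(small_protocol, small_mixing):
    return generate_recording(small_protocol, small_mixing, seed=7)


def random_feature_matrix(rng, n_classes=3, n_features=2, n_reps=2,
                          windows_per_group=None, spread=3.0):
    """Well-conditioned random feature matrix: Gaussian classes with
    random means and SPD covariances, enough windows per (class, rep)
    group for the sample covariance to be positive definite."""
    if windows_per_group is None:
        windows_per_group = n_features + 6
    X, movement, repetition = [], [], []
    for c in range(n_classes):
        mu = rng.normal(0, spread, n_features)
        A = rng.normal(0, 1, (n_features, n_features))
        cov_root = A + n_features * np.eye(n_features)
        for r in range(1, n_reps + 1):
            block = mu + rng.normal(0, 1, (windows_per_group, n_features)) @ cov_root.T * 0.3
            X.append(block)
            movement += [f"class{c}"] * windows_per_group
            repetition += [r] * windows_per_group
    columns = [(f"E{i + 1}", "MAV") for i in range(n_features)]
    return FeatureMatrix(X=np.vstack(X), columns=columns,
                         movement=np.array(movement, dtype=object),
                         repetition=np.array(repetition, dtype=int))
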