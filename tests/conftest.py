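import numpy as np
import pytest

from ensemblehue import categorize

STIM_GRID = np.arange(72) * 5.0  # the 72-hue categorization grid


@pytest.fixture
def stim_grid():
    return STIM_GRID.copy()


def two_category_model(kappa: float) -> categorize.CategoryModel:
    """Green vs. everything else, split at the reported mean yellow-green
    (78.1) and green-blue (168.1) boundaries."""
    return categorize.CategoryModel(
        kappa,
        boundaries=np.array([168.1, 78.1]),
        centroids=np.array([123.1, 303.1]),
        category_names=["green", "other"],
    )


def vector_sum_mean(angles, weights=None):
    """Brute-force circular-mean oracle: angle of the weighted resultant."""
    a = np.radians(np.asarray(angles, float))
    w = np.ones_like(a) if weights is None else np.asarray(weights, float)
    s = np.sum(w * np.sin(a))
    c = np.sum(w * np.cos(a))
    return np.degrees(np.arctan2(s, c)) % 360.0
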