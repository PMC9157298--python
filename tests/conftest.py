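import numpy as np
import pytest

from neonet import AnalysisParams, BandSpec, StudyConfig

HIGH_DELTA = BandSpec("high_delta", 1.5, 4.0)


@pytest.fixture
def band_hd() -> BandSpec:
    return HIGH_DELTA


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config() -> StudyConfig:
    """Small but complete study: 10 parcels, short recordings."""
    return StudyConfig(n_group_a=6, n_group_b=7, n_sensors=12, n_sources=40,
                       n_parcels=10, epoch_windows=2, window_length=10.0,
                       bands=(HIGH_DELTA,), planted_band="high_delta", seed=7)


@pytest.fixture
def fast_params() -> AnalysisParams:
    return AnalysisParams(n_permutations=200, fidelity_iterations=10,
                          fidelity_seconds=4.0, n_surrogates=100,
                          fidelity_weight_iterations=10)
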