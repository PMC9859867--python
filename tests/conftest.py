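import numpy as np
import pytest

from collateraltime import (ExtractionParams, PhantomConfig, PhantomModel,
                            SegmentationParams, extract_tics)


def make_model(**kw) -> PhantomModel:
    kw.setdefault("noise_sd_hu", 0.0)
    return PhantomModel(PhantomConfig(**kw))


@pytest.fixture(scope="session")
def symmetric_model():
    """Noise-free phantom with full symmetric collateral filling."""
    return make_model(collateral_fraction=1.0, collateral_delay_s=0.0)


@pytest.fixture(scope="session")
def symmetric_series(symmetric_model):
    return symmetric_model.simulate_series()


@pytest.fixture(scope="session")
def symmetric_tics(symmetric_model, symmetric_series):
    return extract_tics(symmetric_series, symmetric_model.region_spec(),
                        SegmentationParams(), ExtractionParams())


@pytest.fixture(scope="session")
def delayed_model():
    """Noise-free phantom with attenuated, delayed collateral filling."""
    return make_model(collateral_fraction=0.6, collateral_delay_s=3.2)


@pytest.fixture(scope="session")
def delayed_tics(delayed_model):
    return extract_tics(delayed_model.simulate_series(),
                        delayed_model.region_spec(),
                        SegmentationParams(), ExtractionParams())


def random_curve_config(rng: np.random.Generator) -> PhantomConfig:
    """A randomized enhancement-curve parameterization (noise-free)."""
    return PhantomConfig(
        aif_t0_s=float(rng.uniform(4, 12)),
        aif_alpha=float(rng.uniform(2.2, 4.0)),
        aif_beta_s=float(rng.uniform(1.5, 2.8)),
        aif_amplitude_hu=float(rng.uniform(250, 450)),
        venous_delay_s=float(rng.uniform(5.0, 8.0)),
        venous_early_fraction=float(rng.uniform(0.03, 0.08)),
        recirc_fraction=float(rng.uniform(0.2, 0.3)),
        noise_sd_hu=0.0,
    )
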