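import numpy as np
import pytest

from dcs2l.forward_models import DEFAULT_LAGS, LayerOptics, TwoLayerMedium


@pytest.fixture(scope="session")
def lags():
    return DEFAULT_LAGS


@pytest.fixture(scope="session")
def brain_optics():
    return LayerOptics(mua=0.02, musp=1.21, Db=6e-6)


@pytest.fixture(scope="session")
def baseline_medium(brain_optics):
    """Extracerebral slab (10 mm) over brain, ρ = 35 mm, β = 0.5."""
    return TwoLayerMedium(
        layer1=LayerOptics(mua=0.019, musp=0.86, Db=1.05e-6, thickness=10.0),
        layer2=brain_optics, rho=35.0, beta=0.5)


@pytest.fixture(scope="session")
def midpoint_medium():
    """Mid-grid medium: brain μa 0.015, μs' 1.1, l=11 mm, Db 2.5e-5, fraction 0.175."""
    return TwoLayerMedium(
        layer1=LayerOptics(mua=0.019, musp=0.86, Db=0.175 * 2.5e-5, thickness=11.0),
        layer2=LayerOptics(mua=0.015, musp=1.1, Db=2.5e-5), rho=35.0, beta=0.5)


@pytest.fixture(scope="session")
def table_media_sample():
    """Deterministic sample of media across the training-grid parameter box."""
    rng = np.random.default_rng(42)
    media = []
    for _ in range(10):
        mua = rng.uniform(0.005, 0.025)
        musp = rng.uniform(0.9, 1.3)
        Db = 10 ** rng.uniform(np.log10(5e-7), np.log10(5e-5))
        frac = rng.uniform(0.05, 0.3)
        thick = rng.uniform(8.0, 15.0)
        media.append(TwoLayerMedium(
            layer1=LayerOptics(0.019, 0.86, frac * Db, thickness=thick),
            layer2=LayerOptics(mua, musp, Db), rho=35.0, beta=0.5))
    return media
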