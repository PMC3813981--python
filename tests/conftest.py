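import numpy as np
import pytest

from seamest import DesignConfig, ParameterVector, TrialData
from seamest.configio import load_example


@pytest.fixture(scope="session")
def example_trial() -> TrialData:
    """Bundled anxiety-trial worked example (k=3, sigma=6, n1=n2=71, b=0)."""
    return load_example()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_trial(
    k=2, n1=50, n2=50, sigma=1.0, b=-np.inf, x=None, y0=0.0, yS=0.2
) -> TrialData:
    design = DesignConfig(k=k, n1=n1, n2=n2, sigma=sigma, b=float(b))
    if x is None:
        x = [0.0] + [0.1 * (i + 1) for i in range(k)]
    S = 1 + int(np.argmax(np.asarray(x)[1:]))
    if x[S] - x[0] >= design.b:
        return TrialData(design=design, x=x, y0=y0, yS=yS)
    return TrialData(design=design, x=x)
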