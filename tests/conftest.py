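import numpy as np
import pytest
from hypothesis import settings

from renodki import TissueParams, build_scheme, calibrate_tensors

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme():
    """The study acquisition: b = 0/400/800 s/mm², 25 shared directions."""
    return build_scheme(25, [0, 400, 800], seed=7)


@pytest.fixture(scope="session")
def os_baseline_tensors():
    """Tensors calibrated to the outer-stripe baseline control triple."""
    return calibrate_tensors(TissueParams(2.735, 0.444, 0.760, "OS"))


@pytest.fixture(scope="session")
def is_baseline_tensors():
    """Tensors calibrated to the inner-stripe baseline control triple."""
    return calibrate_tensors(TissueParams(2.628, 0.748, 0.640, "IS"))


def random_plausible_tensors(rng):
    """Random diffusion/kurtosis pair in the physiological regime.

    Diffusion eigenvalues in [0.5, 3.0]e-3 mm²/s with a random orientation;
    kurtosis = isotropic level in [0.3, 1.5] plus a small anisotropic
    perturbation, keeping directional kurtosis positive and bounded.
    """
    from renodki import DiffusionTensor, isotropic_kurtosis, random_rotation
    from renodki.tensors import KurtosisTensor

    lam = np.sort(rng.uniform(0.5e-3, 3.0e-3, size=3))[::-1]
    r = random_rotation(rng)
    d = DiffusionTensor.from_matrix(r @ np.diag(lam) @ r.T)
    w0 = rng.uniform(0.3, 1.5)
    w = isotropic_kurtosis(w0).components + rng.normal(0.0, 0.05 * w0, size=15)
    return d, KurtosisTensor(w)
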