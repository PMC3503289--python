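import numpy as np
import pytest

from immobead import AxiMesh


@pytest.fixture(scope="session")
def mesh32() -> AxiMesh:
    return AxiMesh.build(32)


@pytest.fixture(scope="session")
def mesh64() -> AxiMesh:
    return AxiMesh.build(64)


def first_order_profile(rho: np.ndarray, phi: float) -> np.ndarray:
    """Closed-form steady profile C(rho) = sinh(3*phi*rho)/(rho*sinh(3*phi))
    for first-order kinetics (beta = 0); the independent PDE oracle."""
    k = 3.0 * phi
    rho = np.asarray(rho, dtype=float)
    out = np.empty_like(rho)
    nz = rho > 1e-12
    out[nz] = np.sinh(k * rho[nz]) / (rho[nz] * np.sinh(k))
    out[~nz] = k / np.sinh(k)
    return out
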