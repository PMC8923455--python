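import numpy as np
import pytest

from autocrine_allee.meanfield import MechanisticParams, PhenomParams


@pytest.fixture(scope="session")
def baseline_mech() -> MechanisticParams:
    return MechanisticParams()


@pytest.fixture(scope="session")
def small_mech() -> MechanisticParams:
    """Scaled-down lattice: N=50 keeping the 20 um site size (L = N*d)."""
    return MechanisticParams(N=50, L=50 * 20e-4)


@pytest.fixture(scope="session")
def strong_params() -> PhenomParams:
    """Fitted strong-Allee parameter set (per hour)."""
    return PhenomParams(A=1.787, B=2.202, mu=1.792, time_unit="hours")


@pytest.fixture(scope="session")
def weak_params() -> PhenomParams:
    """Fitted weak-Allee parameter set (per hour)."""
    return PhenomParams(A=0.082, B=0.254, mu=0.074, time_unit="hours")


def random_phenom(rng: np.random.Generator) -> PhenomParams:
    """Random valid phenomenological parameters spanning all regimes."""
    A = rng.uniform(0.01, 2.0)
    B = rng.uniform(-A, 3.0)
    mu = rng.uniform(0.0, 2.5)
    return PhenomParams(A=A, B=B, mu=mu, time_unit="hours")


def bisect_root(f, lo: float, hi: float, tol: float = 1e-12, max_iter: int = 200) -> float:
    """Plain bisection; requires a sign change on [lo, hi]."""
    flo, fhi = f(lo), f(hi)
    assert flo * fhi <= 0, "no sign change in bracket"
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fhi * fm <= 0:
            lo, flo = mid, fm
        else:
            hi, fhi = mid, fm
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
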