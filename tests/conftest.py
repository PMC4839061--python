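"""Shared fixtures: canonical parameter sets for the three surfactants."""

import pytest
from hypothesis import settings

from tensiofit import IsothermParams, RegionAnchor

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

GAMMA0 = 72.0
TEMPERATURE = 298.15


@pytest.fixture
def surfactin_params() -> IsothermParams:
    """Lipopeptide-like truth: small Gamma_inf, attractive beta."""
    return IsothermParams(gamma_inf=1.16e-6, K=30.0, beta=2.8)


@pytest.fixture
def surfactin_anchor(surfactin_params) -> RegionAnchor:
    """Region-1/region-2 break of the lipopeptide-like curve.

    C_12 = 0.01 mol/m^3 (1e-5 M) and gamma_12 = 45 mN/m put the CMC near
    7e-5 M with a plateau around 39 mN/m; anchor coverage at 60 % of
    saturation.
    """
    return RegionAnchor(c_12=0.01, gamma_12=45.0,
                        coverage_12=0.6 * surfactin_params.gamma_inf)


@pytest.fixture
def sdbs_params() -> IsothermParams:
    """Anionic-synthetic-like truth: large Gamma_inf, mild repulsion."""
    return IsothermParams(gamma_inf=3.67e-6, K=3.0, beta=-0.8)


@pytest.fixture
def c14e8_params() -> IsothermParams:
    """Nonionic-synthetic-like truth: Gamma_inf 2.84 umol/m^2, beta -2.1."""
    return IsothermParams(gamma_inf=2.84e-6, K=100.0, beta=-2.1)
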