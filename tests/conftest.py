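import numpy as np
import pytest

from lamkit import (
    SyntheticOracle,
    TorsionDomain,
    build_grid_lamset,
    coupled_2d_preset,
    double_well_1d_preset,
    quadratic_preset,
    regular_grid,
)


@pytest.fixture(scope="session")
def quad_oracle():
    spec, domain = quadratic_preset()
    return SyntheticOracle(spec, domain, oracle_id="preset:quadratic")


@pytest.fixture(scope="session")
def dw_oracle():
    spec, domain = double_well_1d_preset()
    return SyntheticOracle(spec, domain, oracle_id="preset:double_well_1d")


@pytest.fixture(scope="session")
def c2d_oracle():
    spec, domain = coupled_2d_preset()
    return SyntheticOracle(spec, domain, oracle_id="preset:coupled_2d")


@pytest.fixture(scope="session")
def dw_node_lamset(dw_oracle):
    """Node-grid models at -90, -30, +30, +90 on the double well."""
    pts = regular_grid(dw_oracle.domain, "nodes")
    return build_grid_lamset(dw_oracle, dw_oracle.domain, pts)


@pytest.fixture(scope="session")
def quad_lamset(quad_oracle):
    pts = regular_grid(quad_oracle.domain, "centered")
    return build_grid_lamset(quad_oracle, quad_oracle.domain, pts)


from lamkit.experiments import example_domain_7d_coarse, example_domain_7d_fine  # noqa: F401
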