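import numpy as np
import pytest

import ppsim


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def micro_config():
    """A deliberately tiny configuration for fast engine-level tests.

    Six simulated hours on a 600 x 300 um domain with a dense motile-cell
    input; one run takes a few hundredths of a second.
    """
    return ppsim.default_config("test").replace(
        environment={"width_um": 600.0, "height_um": 300.0, "lto_count": 3},
        input={"fraction_pct": 2.0, "lti_fraction_pct": 2.0, "t_end_hours": 6.0},
        patches={"min_size": 2},
    )


def make_environment(
    width=1000.0,
    height=400.0,
    lto_positions=(),
    expressions=None,
    differentiated=None,
    lto_radius=10.0,
    r_chem=150.0,
    threshold=0.3,
    fd_step=1.0,
):
    """Hand-build an Environment with explicit LTo state (placement bypassed)."""
    xy = np.array(lto_positions, dtype=float).reshape(-1, 2)
    n = len(xy)
    expr = np.zeros(n) if expressions is None else np.asarray(expressions, float)
    diff = expr > 0 if differentiated is None else np.asarray(differentiated, bool)
    return ppsim.Environment(
        width=width,
        height=height,
        lto_xy=xy,
        lto_radius=lto_radius,
        lto_differentiated=diff.copy(),
        lto_expression=expr.copy(),
        lto_lti_contacts=np.zeros(n, dtype=np.int64),
        r_chem=r_chem,
        chemokine_threshold=threshold,
        fd_step=fd_step,
    )


@pytest.fixture
def bare_environment():
    return make_environment()
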