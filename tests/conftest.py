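import numpy as np
import pytest

from cabc import ItemSet, compute_abc_curve


@pytest.fixture
def simple_items():
    return ItemSet.from_values([4.0, 3.0, 2.0, 1.0])


@pytest.fixture
def uniform_items():
    rng = np.random.default_rng(202)
    return ItemSet.from_values(rng.uniform(0.0, 100.0, 1000))


def analytic_uniform_curve(n_knots: int = 4000):
    """ABC curve of the closed-form uniform law Y(p) = -p^2 + 2p.

    Built from dense exact knots so the interpolant tracks the analytic
    curve to well below the tolerances it is used at.
    """
    from scipy.interpolate import PchipInterpolator

    from cabc.core import ABCCurve

    p = np.linspace(0.0, 1.0, n_knots + 1)
    y = -p**2 + 2 * p
    return ABCCurve(efforts=p, yields=y, kind="pchip", n=n_knots,
                    _interp=PchipInterpolator(p, y))


def diagonal_curve():
    return compute_abc_curve(ItemSet.from_values(np.full(50, 3.0)))
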