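"""Shared fixtures: the worked parameter set and its exact-rational twin.

The worked set (eps=1/2, a0=3/10, a1=3/5, alpha=2/5) has fully rational
closed forms -- t0=3/10, t1=sigma=2/15, tau=14/15 -- which makes it the
reference point for every hand-derived expectation in the suite.
"""

from fractions import Fraction

import pytest

from oscwave import ModelParams, build_tw, strobe_decompose


@pytest.fixture(scope="session")
def worked_params() -> ModelParams:
    return ModelParams(0.5, 0.3, 0.6)


@pytest.fixture(scope="session")
def worked_params_rational() -> ModelParams:
    return ModelParams(Fraction(1, 2), Fraction(3, 10), Fraction(3, 5))


@pytest.fixture(scope="session")
def worked_tw(worked_params):
    return build_tw(worked_params, 0.4)


@pytest.fixture(scope="session")
def worked_tw_rational(worked_params_rational):
    return build_tw(worked_params_rational, Fraction(2, 5))


@pytest.fixture(scope="session")
def worked_strobe_model(worked_tw, worked_params):
    return strobe_decompose(worked_tw.shape, worked_params)
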