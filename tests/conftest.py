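import numpy as np
import pytest

from ripetime.likelihood import RipeningModelParams


@pytest.fixture
def two_genotype_params() -> RipeningModelParams:
    return RipeningModelParams(
        mu=np.array([42.0, 52.0]),
        alpha={"WT": np.zeros(2), "mut": np.array([4.0, 3.0])},
        sigma0=np.array([[3.0, 1.0], [1.0, 3.0]]),
        sigma=np.array([[2.0, 0.5], [0.5, 2.0]]),
    )


@pytest.fixture
def twice_weekly_days() -> tuple:
    """Twice-weekly scoring over four weeks starting day 30."""
    return (30.0, 33.0, 37.0, 40.0, 44.0, 47.0, 51.0, 54.0, 58.0)
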