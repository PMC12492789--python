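import numpy as np
import pytest

from todacc.synthetic import LPA, MVPA, SB, AxisCountParams, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240506)


@pytest.fixture
def tiny_config():
    """Small, fast cohort config (2 days, moderate ambiguity)."""
    return SimConfig(n_subjects=3, n_days=2, seed=7, ambiguity=0.5)


def make_config(**kw) -> SimConfig:
    defaults = dict(n_subjects=2, n_days=2, seed=11)
    defaults.update(kw)
    return SimConfig(**defaults)


def sb_only_transition() -> np.ndarray:
    return np.array([[1.0, 0, 0], [1.0, 0, 0], [1.0, 0, 0]])


def zero_count_params() -> dict:
    zero = AxisCountParams(0.0, 1.0, 0.0)
    return {s: {ax: zero for ax in ("y", "x", "z")} for s in (SB, LPA, MVPA)}
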