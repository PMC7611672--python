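import numpy as np
import pandas as pd
import pytest

from lcstop import ExGauss, RaceParams, TaskConfig


@pytest.fixture(scope="session")
def generic_params() -> RaceParams:
    """Well-behaved race parameters used across likelihood/simulation tests."""
    return RaceParams(
        stop=ExGauss(0.2, 0.03, 0.05),
        go_match=ExGauss(0.5, 0.05, 0.1),
        go_mismatch=ExGauss(0.6, 0.07, 0.12),
        p_tf=0.1,
        p_gf=0.05,
    )


@pytest.fixture(scope="session")
def task_config() -> TaskConfig:
    return TaskConfig()


def make_trial(kind="go", ssd=np.nan, stimulus="left", response="left", rt=0.45):
    return {
        "kind": kind,
        "ssd": ssd,
        "stimulus": stimulus,
        "response": response,
        "rt": rt,
    }


def trials_frame(records) -> pd.DataFrame:
    df = pd.DataFrame.from_records(records)
    df.insert(0, "trial", np.arange(len(df)))
    df.insert(0, "block", 0)
    return df


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
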