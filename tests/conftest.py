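import pandas as pd
import pytest

from mibgdose import load_i131_scheme
from mibgdose.pipeline import dce_summaries
from mibgdose.synth import SynthConfig


@pytest.fixture(scope="session")
def scheme():
    return load_i131_scheme()


@pytest.fixture()
def config():
    return SynthConfig()


def dce_session_summaries(dce_df: pd.DataFrame, injection_index: int) -> dict:
    """(animal, region, session) -> normalised-enhancement summary."""
    nested = dce_summaries(dce_df, injection_index)
    return {
        (aid, region, session): v
        for region, sessions in nested.items()
        for session, animals in sessions.items()
        for aid, v in animals.items()
    }
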