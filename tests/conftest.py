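import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from snailheat.haplotypes import AlignedSequenceSet, SequenceRecord
from snailheat.simulate import (
    SimulationConfig,
    generate_physiology,
    generate_sequences,
)


@pytest.fixture
def toy_seqs() -> AlignedSequenceSet:
    """Two populations, three haplotypes over a short alignment."""
    return AlignedSequenceSet([
        SequenceRecord("s1", "A", "ACGTACGT"),
        SequenceRecord("s2", "A", "ACGTACGT"),
        SequenceRecord("s3", "A", "ACGTACGA"),
        SequenceRecord("s4", "B", "ACGTACGT"),
        SequenceRecord("s5", "B", "ACGCACGT"),
    ])


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def synthetic_seqs(default_config):
    return generate_sequences(default_config)


@pytest.fixture(scope="session")
def synthetic_phys(default_config):
    return generate_physiology(default_config)


@pytest.fixture
def phys_df(synthetic_phys) -> pd.DataFrame:
    return synthetic_phys[0]


def make_records(pop_scores: dict[str, list[float]], variable: str,
                 temperature: int) -> pd.DataFrame:
    """Tidy physiology frame from per-population value lists at one temperature."""
    rows = []
    for pop, values in pop_scores.items():
        for k, v in enumerate(values):
            rows.append({
                "individual_id": f"{pop}_{temperature}_{k}",
                "population_id": pop, "temperature": temperature,
                "hsp70_rel": v if variable == "hsp70_rel" else np.nan,
                "tubule_score": v if variable == "tubule_score" else np.nan,
                "digestive_score": v if variable == "digestive_score" else np.nan,
                "calcium_score": v if variable == "calcium_score" else np.nan,
            })
    return pd.DataFrame(rows)
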