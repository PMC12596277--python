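import numpy as np
import pytest

from triobench.frequencies import sample_frequency_table
from triobench.reference import synthesize_reference
from triobench.types import DnmCall, SimulationConfig
from triobench.evaluate import CallTable


@pytest.fixture(scope="session")
def small_reference():
    """50 kb synthetic chromosome shared across unit tests."""
    return synthesize_reference(50_000, seed=101)


@pytest.fixture(scope="session")
def small_afs(small_reference):
    return sample_frequency_table(small_reference, 200, seed=101)


@pytest.fixture()
def small_config():
    return SimulationConfig(
        seed=101,
        n_dnsnv=9,
        n_dnindel=3,
        reference_length=50_000,
        n_inherited_sites=200,
    )


def make_call_table(
    rng: np.random.Generator,
    n_calls: int,
    truth_keys: set,
    caller: str = "c",
    orientation: str = "higher_is_better",
    p_match: float = 0.4,
) -> CallTable:
    """Random call table mixing truth hits and misses with random scores."""
    truth_list = sorted(truth_keys)
    records = []
    used = set()
    pos = 1
    while len(records) < n_calls:
        if truth_list and rng.random() < p_match:
            key = truth_list[int(rng.integers(len(truth_list)))]
        else:
            pos += int(rng.integers(1, 50))
            key = ("chr1", pos, "A", "T")
        if key in used:
            continue
        used.add(key)
        records.append(
            DnmCall(*key, "0/0", "0/0", "0/1",
                    score=float(np.round(rng.random(), 3)),
                    score_orientation=orientation, caller_name=caller)
        )
    return CallTable(caller, orientation, records)
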