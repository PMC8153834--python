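import pytest

from lcdscan import SearchCriteria, planted_proteome


@pytest.fixture
def q_criteria():
    """Default-style search: Q >= 40%, w=20, dispersion >= 0.5."""
    return SearchCriteria(groups=[{"Q"}], thresholds=[40.0])


@pytest.fixture
def n_criteria():
    return SearchCriteria(groups=[{"N"}], thresholds=[40.0])


@pytest.fixture(scope="session")
def planted_n_proteome():
    """20 background proteins plus 3 proteins with planted 30aa poly-N LCDs."""
    criteria = SearchCriteria(groups=[{"N"}], thresholds=[40.0])
    return planted_proteome(
        n_background=20,
        background_composition=None,
        plants=[("N", 30, 3)],
        seed=7,
        reject_criteria=criteria,
    )


def write_fasta(path, records):
    with open(path, "w") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n{seq}\n")
    return path
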