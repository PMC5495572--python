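import numpy as np
import pytest

from exactrna.refindex import ReferenceSet, build_index


def naive_find(refs: ReferenceSet, query: str):
    """O(n*m) sliding-window oracle for exact substring occurrence."""
    hits = []
    for name, seq in refs.records.items():
        start = 0
        while True:
            i = seq.find(query, start)
            if i < 0:
                break
            hits.append((name, i))
            start = i + 1
    return sorted(hits)


def random_refs(rng: np.random.Generator, lengths: dict[str, int]) -> ReferenceSet:
    return ReferenceSet(
        {
            name: "".join(rng.choice(list("ACGT"), size=length))
            for name, length in lengths.items()
        }
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def toy_refs(rng):
    return random_refs(rng, {"chrA": 3000, "chrB": 1500})


@pytest.fixture(scope="session")
def toy_index(toy_refs):
    return build_index(toy_refs)
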