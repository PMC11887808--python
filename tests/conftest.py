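import numpy as np
import pandas as pd
import pytest

from mitolineage.calling import AlleleCountTable
from mitolineage.reference import CircularReference
from mitolineage.simulate import synthetic_reference


@pytest.fixture(scope="session")
def toy_ref() -> CircularReference:
    return CircularReference("toy", "ACGTT")


@pytest.fixture(scope="session")
def mid_ref() -> CircularReference:
    """A 2 kb synthetic circular genome with embedded homopolymer tracts."""
    return synthetic_reference(length=2000, seed=42)


@pytest.fixture(scope="session")
def full_ref() -> CircularReference:
    """Full-length (16,569 bp) synthetic circular genome."""
    return synthetic_reference(length=16569, seed=7)


def make_count_table(
    cell_id: str,
    run_id: str,
    ref: CircularReference,
    overrides: dict[int, dict[str, int]] | None = None,
    base_depth: int = 1000,
) -> AlleleCountTable:
    """All-reference counts at uniform depth with per-position overrides.

    ``overrides`` maps position -> full {A,C,G,T} count dict.
    """
    rows = []
    for pos in range(1, ref.length + 1):
        counts = {b: 0 for b in "ACGT"}
        counts[ref.base(pos)] = base_depth
        if overrides and pos in overrides:
            counts = dict(overrides[pos])
        rows.append({"pos": pos, "ref": ref.base(pos), **counts})
    return AlleleCountTable(cell_id=cell_id, run_id=run_id, counts=pd.DataFrame(rows))


@pytest.fixture
def make_counts():
    return make_count_table


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
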