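from __future__ import annotations

import numpy as np
import pytest

from promoterz import (
    FragmentSet,
    GenomeLayout,
    SimulationConfig,
    TSSRecord,
    simulate_experiment,
)


@pytest.fixture
def toy_layout() -> GenomeLayout:
    return GenomeLayout({"chr1": 10_000, "chr2": 5_000})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_fragments(rng: np.random.Generator, layout: GenomeLayout, n: int) -> FragmentSet:
    chroms = list(layout.chrom_names)
    rows = []
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        size = layout.size(c)
        start = int(rng.integers(0, size - 1))
        end = int(rng.integers(start + 1, min(size, start + 400) + 1))
        rows.append((c, start, min(end, size)))
    return FragmentSet.from_intervals(rows)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact simulated experiment shared across tests (n=300 promoters)."""
    cfg = SimulationConfig(n_promoters=300, seed=1234)
    return simulate_experiment(cfg)


@pytest.fixture
def plus_tss() -> TSSRecord:
    return TSSRecord(chrom="chr1", tss=5_000, strand="+", gene_id="geneP")
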