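import numpy as np
import pytest

from fluidcnv import (
    CNVSpec,
    GenomeModel,
    SimulationParams,
    make_bins,
    simulate_sample,
    synthetic_gc,
)


@pytest.fixture(scope="session")
def genome():
    return GenomeModel.desk_scale()


@pytest.fixture(scope="session")
def bins(genome):
    """Desk-scale bin table with synthetic GC attached."""
    return synthetic_gc(make_bins(genome, 1000), genome, seed=1)


@pytest.fixture(scope="session")
def reference(bins, genome):
    """The single healthy reference specimen all fluids normalize against."""
    return simulate_sample(
        bins,
        CNVSpec.diploid(),
        SimulationParams(noise_chr_extra_sd=2.0, seed=99),
        genome,
        sample_id="reference",
    )


@pytest.fixture
def toy_genome():
    return GenomeModel(
        (("A", 100_000), ("B", 60_000), ("noise", 20_000), ("X", 30_000)),
        frozenset({"X"}),
        "noise",
    )


@pytest.fixture
def toy_bins(toy_genome):
    return make_bins(toy_genome, 1000)


def brute_force_max_arc(x):
    """Independent exhaustive maximization of the circular split statistic.

    Scans every arc with plain slicing and per-arc means/SSDs; ties break
    to the leftmost start, then the shortest arc, by scan order.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    best, bi, bj = 0.0, 0, 0
    for i in range(n):
        for j in range(i + 1, n + 1):
            if j - i == n:
                continue
            arc = x[i:j]
            out = np.concatenate([x[:i], x[j:]])
            d = arc.mean() - out.mean()
            ssd = ((arc - arc.mean()) ** 2).sum() + ((out - out.mean()) ** 2).sum()
            if n - 2 <= 0 or ssd < 1e-12 * n:
                t2 = float("inf") if d != 0.0 else 0.0
            else:
                t2 = d * d / ((ssd / (n - 2)) * (1.0 / len(arc) + 1.0 / len(out)))
            if t2 > best:
                best, bi, bj = t2, i, j
    return best, bi, bj
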