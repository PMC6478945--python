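import numpy as np
import pytest

from cnkit.genome import (Chromosome, GenomeLayout, GenomicInterval,
                          HG19_SIZES, toy_layout)
from cnkit.track_io import TrackTable


@pytest.fixture
def toy3():
    """3 chromosomes x 10 Mb with simple p/q cytobands."""
    return toy_layout(n_chrom=3, length=10_000_000)


@pytest.fixture
def small_layout():
    """3 chromosomes x 100 kb — small enough for per-base oracles."""
    return GenomeLayout([Chromosome(str(i + 1), 100_000, i) for i in range(3)])


@pytest.fixture
def hg19_sizes_file(tmp_path):
    p = tmp_path / "hg19.chrom.sizes"
    with open(p, "w") as fh:
        for name, length in HG19_SIZES.items():
            fh.write(f"chr{name}\t{length}\n")
    return p


def random_track(rng, layout, n, kind="counts", with_sd=False, with_gc=False):
    """Seeded random non-overlapping-free track (rows may overlap)."""
    chroms = layout.chrom_names()
    rows = []
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        ln = layout.chromosome(c).length
        start = int(rng.integers(0, ln - 1000))
        end = start + int(rng.integers(1, 1000))
        rows.append((c, start, end))
    import pandas as pd

    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["N"] = np.round(rng.gamma(2.0, 50.0, size=n), 4)
    if with_sd:
        df["sd"] = np.round(rng.uniform(0, 5, size=n), 4)
    if with_gc:
        df["gc"] = np.round(rng.uniform(0.2, 0.8, size=n), 4)
    return TrackTable(df, kind=kind, layout=layout)
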