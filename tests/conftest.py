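import numpy as np
import pandas as pd
import pytest

from fieldscape.io_formats import MatrixTable, SegRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def beta_matrices(rng):
    """Small tumor/normal beta matrices with a planted differential block."""
    n_probes, n_samples = 60, 8
    probes = [f"cg{i:04d}" for i in range(n_probes)]
    samples = [f"S{i}" for i in range(n_samples)]
    normal = rng.uniform(0.2, 0.4, size=(n_probes, n_samples))
    tumor = normal.copy()
    tumor[:20] += 0.4   # hyper block
    tumor[20:40] -= 0.15  # hypo block
    tumor = np.clip(tumor, 0, 1)
    mk = lambda a: MatrixTable(pd.DataFrame(a, index=probes, columns=samples), "beta")
    return mk(tumor), mk(normal)


def random_profile(rng, sample_id, n_segments, coord_max=2000, chroms=("1", "2")):
    """Small random segment profile on a toy coordinate system."""
    records = []
    for _ in range(n_segments):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, coord_max - 2))
        end = int(rng.integers(start + 1, coord_max))
        seg_mean = float(rng.uniform(-1, 1))
        records.append(SegRecord(sample_id, chrom, start, end, seg_mean))
    return records
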