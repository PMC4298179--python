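import numpy as np
import pandas as pd
import pytest

from erhaplo.io import HaplotypeMatrix, PoolCounts, RecombMap


def make_matrix(rows, ids=None, chrom="2L", positions=None, ref=None):
    """Build a HaplotypeMatrix from call strings, e.g. ["AC", "AT", "NT"]."""
    calls = np.array([list(r) for r in rows], dtype="<U1")
    n_hap, n_sites = calls.shape
    if ids is None:
        ids = [f"h{i + 1}" for i in range(n_hap)]
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    sites = pd.DataFrame({"chrom": chrom, "pos": positions})
    if ref is not None:
        sites["ref"] = list(ref)
    return HaplotypeMatrix(ids, calls, sites)


def make_pool(freqs, alleles_alt, alleles_ref, design, depth=100,
              chrom="2L", positions=None):
    """PoolCounts with exact (noise-free) counts: alt reads = freq * depth."""
    freqs = np.asarray(freqs, dtype=float)  # sites x samples
    n_sites, n_samples = freqs.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    counts = np.zeros((n_sites, n_samples, 6), dtype=np.int64)
    order = {"A": 0, "T": 1, "C": 2, "G": 3}
    for i in range(n_sites):
        alt = np.rint(freqs[i] * depth).astype(int)
        counts[i, :, order[alleles_alt[i]]] = alt
        counts[i, :, order[alleles_ref[i]]] = depth - alt
    sites = pd.DataFrame({"chrom": chrom, "pos": positions,
                          "ref": list(alleles_ref)})
    return PoolCounts(sites, counts, design)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_map():
    return RecombMap.uniform({"2L": 10_000_000, "2R": 10_000_000}, 2.0)
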