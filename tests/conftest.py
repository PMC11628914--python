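import numpy as np
import pytest

from sweepscan.genotype_io import HaplotypePanel, MarkerMap


def make_panel(alleles, positions=None, chrom="chr1", variety_ids=None):
    """Panel from a list-of-lists allele matrix on a single chromosome."""
    H = np.asarray(alleles, dtype=np.int8)
    n, m = H.shape
    if positions is None:
        positions = [(i + 1) * 1000 for i in range(m)]
    mm = MarkerMap(
        np.array([f"m{i + 1}" for i in range(m)], dtype=object),
        np.array([chrom] * m, dtype=object),
        np.array(positions, dtype=np.int64),
    )
    if variety_ids is None:
        variety_ids = [f"v{i + 1}" for i in range(n)]
    return HaplotypePanel(variety_ids, H, mm)


@pytest.fixture
def rng():
    return np.random.default_rng(20240925)


def random_panel(rng, n_hap, n_markers, maf_low=0.1):
    """Random complete biallelic panel with intermediate frequencies."""
    freqs = rng.uniform(maf_low, 1 - maf_low, size=n_markers)
    H = (rng.random((n_hap, n_markers)) < freqs).astype(np.int8)
    return make_panel(H)
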