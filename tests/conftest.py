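import numpy as np
import pandas as pd
import pytest

from stemqc.containers import CoverageMatrix
from stemqc.sim import SimConfig, TruthEvent, gen_coverage


def make_matrix(cn: np.ndarray, chrom: str = "chr1", bin_size: int = 100_000) -> CoverageMatrix:
    """Wrap a plain (samples x bins) array as a CoverageMatrix."""
    cn = np.asarray(cn, dtype=float)
    n_bins = cn.shape[1]
    starts = np.arange(n_bins, dtype=np.int64) * bin_size
    bins = pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + bin_size})
    samples = [f"S{i:03d}" for i in range(cn.shape[0])]
    return CoverageMatrix(bins=bins, samples=samples, cn=cn)


@pytest.fixture
def flat_matrix():
    """10 samples x 60 bins of exactly diploid coverage."""
    return make_matrix(np.full((10, 60), 2.0))


@pytest.fixture
def event_matrix():
    """20 samples, 1000 bins, one fixed CN-3 duplication of 50 bins in
    sample S003 (bins 400-450), simulated at depth 30."""
    cfg = SimConfig(
        seed=42,
        n_samples=20,
        n_bins=1000,
        events=[TruthEvent("S003", "chr1", 400, 450, 3, 1.0, "dup")],
    )
    matrix, truth = gen_coverage(cfg)
    return matrix, truth[0]
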