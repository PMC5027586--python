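import numpy as np
import pandas as pd
import pytest

from groseqtk.coverage import StrandedCoverage
from groseqtk.simulate import SimConfig, generate_truth


@pytest.fixture
def small_config() -> SimConfig:
    return SimConfig(
        n_chromosomes=1,
        chrom_length=2_000_000,
        n_genes=40,
        n_intergenic_enhancers=10,
        n_intragenic_enhancers=10,
        n_tf_extra_sites=20,
        seed=11,
    )


@pytest.fixture
def small_truth(small_config):
    return generate_truth(small_config)


def make_coverage(plus, minus, bin_width=50, chrom="chr1", **kwargs) -> StrandedCoverage:
    return StrandedCoverage(
        chroms={chrom: (np.asarray(plus, dtype=np.int64), np.asarray(minus, dtype=np.int64))},
        bin_width=bin_width,
        **kwargs,
    )


def genes_frame(*rows) -> pd.DataFrame:
    return pd.DataFrame(list(rows), columns=["gene_id", "chrom", "start", "end", "strand"])
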