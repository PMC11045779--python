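import os

# Single-threaded BLAS keeps training and attribution bitwise reproducible
# across machines with different core counts (must run before numpy loads).
for _v in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS",
           "NUMEXPR_NUM_THREADS"):
    os.environ.setdefault(_v, "1")

import numpy as np
import pytest

from epmkit.classifier import ModelConfig
from epmkit.regions import RegionConfig
from epmkit.synth import EditSpec, MotifSpec, SyntheticConfig, generate_genome

HIGH_MOTIF = "CACCTGTC"
LOW_MOTIF = "AGATCCGA"


@pytest.fixture(scope="session")
def small_region_cfg():
    return RegionConfig(promoter_len=200, utr5_len=100, utr3_len=100,
                        terminator_len=200, spacer_len=10)


@pytest.fixture(scope="session")
def small_synth_cfg():
    return SyntheticConfig(
        n_chroms=2, genes_per_chrom=100, gene_len=600, intergenic_len=1200,
        motif_specs=(MotifSpec(HIGH_MOTIF, "high", offset_range=(10, 80)),
                     MotifSpec(LOW_MOTIF, "low", offset_range=(10, 80))),
        n_genotypes=8,
        edit_spec=EditSpec(target_motif=HIGH_MOTIF, indel_len=12,
                           fraction_of_genotypes=0.4, edited_gene_fraction=0.5),
        seed=3,
    )


@pytest.fixture(scope="session")
def small_model_cfg():
    return ModelConfig(filters_per_block=(8, 16, 8), kernel_size=5, pool_size=4,
                       fc_sizes=(16, 8), max_epochs=8, early_stop_patience=4,
                       lr_reduce_patience=2, batch_size=32, seed=3)


@pytest.fixture(scope="session")
def small_dataset(small_synth_cfg):
    return generate_genome(small_synth_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
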