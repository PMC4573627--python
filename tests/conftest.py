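import pytest

from mirtss.classifier import SvmConfig
from mirtss.model import MirnaPromoterModel
from mirtss.simulate import SimConfig, simulate_dataset

TINY_CONFIG = SimConfig(
    genome=(("chr1", 600_000),),
    n_genes=80,
    n_mirnas=12,
    category_fractions=(0.25, 0.25, 0.25, 0.25),
    library_size=15_000,
    seed=7,
)

SMALL_SVM = SvmConfig(C_grid=(1.0, 10.0), gamma_grid=(1e-3, 1e-2), cv_folds=3)


@pytest.fixture(scope="session")
def tiny_sim():
    """A small synthetic dataset with three miRNAs per category."""
    return simulate_dataset(TINY_CONFIG)


@pytest.fixture(scope="session")
def tiny_results(tiny_sim):
    """A promoter model fitted on the tiny synthetic dataset."""
    model = MirnaPromoterModel(
        tiny_sim.tracks,
        tiny_sim.genes,
        tiny_sim.genome,
        n_random=400,
        svm=SMALL_SVM,
        seed=0,
    )
    return model.fit()
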