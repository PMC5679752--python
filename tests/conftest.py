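import numpy as np
import pytest

from molarmap import lmm, simdata


@pytest.fixture(scope="session")
def tooth_template():
    """Small synthetic crown (about 130 semi-landmarks) shared across tests."""
    return simdata.make_tooth_template(grid=(18, 11), seed=0)


@pytest.fixture(scope="session")
def sim_study(tooth_template):
    """One small mapping study: 60 sibs, 800 SNPs, two QTL, shapes + ages."""
    sc = simdata.SimConfig(
        n_individuals=60,
        n_families=10,
        n_snps=800,
        n_qtl=2,
        qtl_effect_fractions=(0.05, 0.03),
        polygenic_h2=0.5,
        seed=1,
    )
    panel = simdata.simulate_genotypes(sc)
    configs, ages, truth = simdata.simulate_shapes(panel, sc, tooth_template)
    return sc, panel, configs, ages, truth


@pytest.fixture(scope="session")
def small_kinship(sim_study):
    _, panel, *_ = sim_study
    return lmm.centered_kinship(panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
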