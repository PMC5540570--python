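import numpy as np
import pytest

import ggmnet


@pytest.fixture(scope="session")
def small_scenario():
    """A compact but fully structured scenario shared across test modules:
    3 planted modules of 12 genes among 60, 150 samples."""
    return ggmnet.generate_scenario(
        n_genes=60,
        n_modules=3,
        module_size=12,
        within_pcor=0.3,
        n_samples=150,
        seed=7,
    )


@pytest.fixture(scope="session")
def recovered_small(small_scenario):
    """Aggregated associations + selected network + MCL modules for the
    small scenario, using a reduced sampling plan."""
    logm = ggmnet.log_transform(
        ggmnet.filter_low_expression(small_scenario.expression)
    )
    plan = ggmnet.SamplingPlan(n_iterations=80, subset_size=30, seed=17)
    assoc = ggmnet.sampled_pcor_estimation(logm, plan)
    net = ggmnet.select_edges(assoc, ggmnet.EdgeSelectionParams(0.04, 0.15))
    modules = ggmnet.mcl_cluster(net)
    return logm, assoc, net, modules


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
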