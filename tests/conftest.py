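import numpy as np
import pytest

from mifhh.data import DyadReport, ModelSpec, build_design
from mifhh.priors import default_hyperparameters, prevalence_to_intercept_mean
from mifhh.sampler import SamplerConfig
from mifhh.simulate import SimulationConfig, simulate_mifhh


@pytest.fixture
def four_reports():
    """Two informants of one family, each reporting on two members (one self)."""
    return [
        DyadReport("F1", "A", "A", 1, degree_of_relation=0, same_gender=1),
        DyadReport("F1", "A", "B", 0, degree_of_relation=1, same_gender=0),
        DyadReport("F1", "B", "A", 1, degree_of_relation=1, same_gender=0,
                   informant_female=1),
        DyadReport("F1", "B", "B", 0, degree_of_relation=0, same_gender=1,
                   informant_female=1),
    ]


@pytest.fixture
def tiny_design():
    """Intercept-only design, no clustering, for oracle comparisons."""
    y = [1, 0, 1, 1, 0]
    records = [DyadReport("F1", "I1", f"M{k}", s) for k, s in enumerate(y)]
    spec = ModelSpec(name="oracle", cluster_level="none", estimate_sigma2=False)
    return build_design(records, spec)


@pytest.fixture(scope="session")
def faithful_dataset():
    """Moderate model-faithful dataset with nonzero behaviour effects."""
    beta = np.array([prevalence_to_intercept_mean(0.12), 0.3, 0.2, 1.2, 0.9, -1.0])
    config = SimulationConfig(
        n_families=45,
        members_per_family=(8, 14),
        true_beta=beta,
        true_D=np.array([[0.6]]),
        sigma2=1.0,
        seed=11,
    )
    records, truth = simulate_mifhh(config)
    return records, truth, config


@pytest.fixture
def quick_config():
    """Short chain for unit-level behaviour checks."""
    return SamplerConfig(n_iterations=600, burn_in=300, thin=1, seed=5)


@pytest.fixture
def default_hyper_for():
    def _make(design, prevalence=0.12):
        return default_hyperparameters(p=design.p, q=design.q, prevalence=prevalence)

    return _make
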