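import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from esam_methpipe.simulate import SimulationConfig, simulate_study
from esam_methpipe.study import MethylationStudy

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_samples_per_group=40,
        n_dl_samples_per_group=15,
        n_probes=800,
        n_chromosomes=4,
        n_true_dmcs=3,
        n_snps=40,
        n_additive_meqtls=2,
        n_interaction_meqtls=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


def make_study(beta, samples=None, chromosome=None, position=None):
    """Hand-build a MethylationStudy from a probes x samples beta frame."""
    beta = pd.DataFrame(beta)
    beta.index = [f"cg{i:04d}" for i in range(beta.shape[0])]
    beta.columns = [f"S{i:03d}" for i in range(beta.shape[1])]
    n_s = beta.shape[1]
    if samples is None:
        half = n_s // 2
        samples = pd.DataFrame(
            {
                "group": ["ESAM"] * half + ["NESAM"] * (n_s - half),
                "timepoint": "DC",
                "age": np.linspace(1, 4, n_s),
                "sex": ["M", "F"] * (n_s // 2) + ["M"] * (n_s % 2),
                "PC1": np.zeros(n_s),
            },
            index=beta.columns,
        )
    else:
        samples = pd.DataFrame(samples, index=beta.columns)
    probes = pd.DataFrame(
        {
            "chromosome": chromosome if chromosome is not None else "chr1",
            "position": position if position is not None else np.arange(1, beta.shape[0] + 1) * 100,
            "gene_links": [()] * beta.shape[0],
            "flags": [frozenset()] * beta.shape[0],
        },
        index=beta.index,
    )
    return MethylationStudy(beta=beta, samples=samples, probes=probes)
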