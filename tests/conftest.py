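import dataclasses

import pytest

from cernaflow.diffexpr import DEConfig, differential_expression, quantile_normalize
from cernaflow.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def study():
    """One fully simulated study shared across tests (seed 1)."""
    return simulate_all(SimulationConfig(seed=1))


def run_de(matrices, de_config: DEConfig = DEConfig()):
    """The pipeline's per-class DE convention: quantile-normalize array
    classes, log2(count+1) for miRNA counts."""
    records = {}
    for cls, matrix in matrices.items():
        if cls != "miRNA":
            matrix = quantile_normalize(matrix)
        cfg = (dataclasses.replace(de_config, count_data=True)
               if cls == "miRNA" else de_config)
        records[cls] = differential_expression(matrix, cfg)
    return records


@pytest.fixture(scope="session")
def de_records(study):
    return run_de(study.matrices)
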