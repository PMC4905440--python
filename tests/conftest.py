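import numpy as np
import pandas as pd
import pytest

from lncnet.core import CASE, CONTROL, ExpressionMatrix
from lncnet.datasets import load_af_worked_example
from lncnet.simulate import SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def worked_example():
    """The bundled 50-probe AF worked example: matrix, annotation, reference."""
    return load_af_worked_example()


@pytest.fixture(scope="session")
def null_sim():
    """A no-signal simulation: 1000 probes, nothing planted."""
    cfg = SimulationConfig(
        n_lncRNA=500, n_mRNA=500, n_de_lncRNA=0, n_de_mRNA=0, n_modules=0,
        n_tf=0, seed=11,
    )
    return cfg, simulate_expression(cfg)


@pytest.fixture(scope="session")
def module_sim():
    """A module-rich simulation for co-expression / TF recovery tests."""
    cfg = SimulationConfig(
        n_lncRNA=400, n_mRNA=400, n_de_lncRNA=40, n_de_mRNA=40,
        n_modules=3, module_size=(3, 10), module_beta=3.0, module_noise_sd=0.15,
        n_tf=8, tf_set_size=40, tf_target_frac_in_module=0.9, seed=5,
    )
    return cfg, simulate_expression(cfg)


def toy_matrix(values: np.ndarray, n_ctrl: int, n_case: int) -> ExpressionMatrix:
    probes = [f"P{i}" for i in range(values.shape[0])]
    samples = [f"N{i+1}" for i in range(n_ctrl)] + [f"AF{i+1}" for i in range(n_case)]
    groups = {s: (CONTROL if s.startswith("N") else CASE) for s in samples}
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples), groups)
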