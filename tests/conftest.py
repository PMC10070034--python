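import numpy as np
import pytest

from cellforge.hybrid_engine import SimConfig, run_hybrid
from cellforge.integrated_engine import run_integrated
from cellforge.sbml_compile import build_biochem_sbml, build_integrated_sbml
from cellforge.toygen import ToySpec, make_constitutive_benchmark, make_toy


@pytest.fixture(scope="session")
def toy2():
    """2-gene, 3-signal-species toy model, fixed seed."""
    return make_toy(ToySpec(n_genes=2, seed=1))


@pytest.fixture(scope="session")
def toy2_biochem(toy2):
    return build_biochem_sbml(toy2)


@pytest.fixture(scope="session")
def toy2_integrated(toy2):
    return build_integrated_sbml(toy2)


@pytest.fixture(scope="session")
def short_mean_cfg():
    return SimConfig(duration=3600, dt=30, mode="mean")


@pytest.fixture(scope="session")
def toy2_mean_run(toy2, toy2_biochem, short_mean_cfg):
    return run_hybrid(toy2_biochem, toy2, short_mean_cfg)


@pytest.fixture(scope="session")
def toy2_integrated_run(toy2_integrated, short_mean_cfg):
    return run_integrated(toy2_integrated, short_mean_cfg)


@pytest.fixture(scope="session")
def benchmark_model():
    return make_constitutive_benchmark()
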