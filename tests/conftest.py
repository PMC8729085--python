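import numpy as np
import pandas as pd
import pytest

from pistilgrn.expression import ExpressionMatrix
from pistilgrn.pipeline import PipelineConfig, run_all
from pistilgrn.simulate import SimulationConfig, simulate_dataset

#: small study used by most unit tests: same design, fewer genes
SMALL_SIM = dict(
    n_genes=600,
    n_tfs=3,
    n_modules=3,
    module_size=12,
    n_stage_specific=3,
    n_de=45,
    seed=11,
)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(SimulationConfig(**SMALL_SIM))


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A complete pipeline run on the small synthetic study."""
    outdir = tmp_path_factory.mktemp("small_run")
    cfg = PipelineConfig(seed=SMALL_SIM["seed"], simulation=dict(SMALL_SIM))
    report = run_all(cfg, outdir)
    return cfg, outdir, report


def toy_matrix(values, groups, unit="fpkm", lengths=None):
    """Build an ExpressionMatrix from a dict of sample -> column values and a
    matching dict of sample -> (sex, stage, replicate)."""
    df = pd.DataFrame(values)
    df.index = [f"g{i + 1}" for i in range(len(df))]
    meta = pd.DataFrame(
        [(s, *groups[s]) for s in df.columns],
        columns=["sample", "sex", "stage", "replicate"],
    ).set_index("sample")
    gl = None
    if lengths is not None:
        gl = pd.Series(lengths, index=df.index)
    return ExpressionMatrix(values=df, samples=meta, unit=unit, gene_lengths=gl)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
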