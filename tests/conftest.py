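import numpy as np
import pytest

from txfidelity.io import generate_random_template
from txfidelity.params import (ModelParams, NTPPool, PolymeraseEffectConfig,
                               default_params)
from txfidelity.thermo import NNTable, NNTableSet, load_default_tables

TMPL_TO_RNA = {"A": "U", "C": "G", "G": "C", "T": "A"}


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def seq50():
    return str(generate_random_template(50, 0.5, 21).seq)


@pytest.fixture(scope="session")
def seq300():
    return str(generate_random_template(300, 0.5, 7).seq)


def make_neutral_params(base: ModelParams | None = None) -> ModelParams:
    """Parameter set with no cognate/non-cognate discrimination anywhere:
    mismatch steps get Watson-Crick energies, the polymerase factor is 1 and
    the BACK stabilization 0."""
    base = base or default_params()
    tables = load_default_tables()
    wc = tables.rna_dna_wc
    neutral = {}
    for (top, bottom) in tables.rna_dna_mismatch.entries:
        ctop = "".join(TMPL_TO_RNA[b] for b in bottom)
        neutral[(top, bottom)] = wc[(ctop, bottom)]
    tables = NNTableSet(
        tables.dna_dna, wc,
        NNTable(tables.rna_dna_mismatch.duplex_class, neutral, "neutralized"))
    return ModelParams(barriers=base.barriers,
                       pe=PolymeraseEffectConfig(factor=1.0, back_stabilization_ddG=0.0),
                       pool=base.pool, geometry=base.geometry, tables=tables,
                       dG_pol=base.dG_pol, name="neutral")


@pytest.fixture(scope="session")
def neutral_params():
    return make_neutral_params()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
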