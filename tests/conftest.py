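import numpy as np
import pytest

from clonkit import (
    MutationCall,
    default_catalog,
    load_jup3_fixture,
    preset,
    simulate_case,
)


@pytest.fixture(scope="session")
def jup3_calls():
    """Packaged JuP3 case fixture (mutation identities from the case narrative)."""
    return load_jup3_fixture()


@pytest.fixture(scope="session")
def sim_case():
    """One simulated three-lesion case under the default study conditions."""
    return simulate_case(preset("jup3_like", seed=7)[0])


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def make_call(**kw) -> MutationCall:
    """A valid mutation call with overridable fields, for terse test setup."""
    defaults = dict(
        sample_id="S1",
        chrom="1",
        pos=1000,
        ref="C",
        alt="T",
        gene="GENE1",
        protein_change="A100V",
        effect="nonsynonymous",
        t_ref=60,
        t_alt=40,
        n_ref=50,
        n_alt=0,
        pop_maf=None,
        context="ACA",
    )
    defaults.update(kw)
    return MutationCall(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
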