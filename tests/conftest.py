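import pytest

from omdpipe.attribution import attribute
from omdpipe.digestion import build_peptide_index
from omdpipe.quantification import pivot_peptides, rollup_to_protein, zero_fill
from omdpipe.synthetic_data import make_bundle


@pytest.fixture(scope="session")
def bundle():
    """One moderately sized synthetic cohort shared across tests."""
    return make_bundle(seed=11)


@pytest.fixture(scope="session")
def index(bundle):
    return build_peptide_index(bundle.microbial)


@pytest.fixture(scope="session")
def attrib(bundle, index):
    return attribute(sorted(set(bundle.quant["peptide"])), index,
                     bundle.annotations)


@pytest.fixture(scope="session")
def protein_matrix(bundle, attrib):
    wide, _ = zero_fill(pivot_peptides(bundle.quant))
    return rollup_to_protein(wide, attrib, warn_empty=False)
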