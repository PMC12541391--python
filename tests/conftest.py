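import pytest

from editoform.digest import DigestConfig, default_mass_table
from editoform.peptides import find_editing_specific_peptides
from editoform.proteoforms import enumerate_proteoforms
from editoform.simulate import toy_reference_system


@pytest.fixture(scope="session")
def mass_table():
    return default_mass_table()


@pytest.fixture(scope="session")
def reference_system():
    """Synthetic genes embedding the biological tryptic contexts of the
    three editing sites with printed peptide evidence."""
    return toy_reference_system()


@pytest.fixture(scope="session")
def reference_pairs(reference_system):
    """site_id -> the single 0-missed-cleavage editing-specific pair."""
    cds_by_gene, sites = reference_system
    out = {}
    for site in sites:
        pfs = enumerate_proteoforms(
            cds_by_gene[site.gene_id],
            [s for s in sites if s.gene_id == site.gene_id],
        )
        pairs = find_editing_specific_peptides(pfs, site, DigestConfig(max_missed=0))
        assert len(pairs) == 1
        out[site.site_id] = pairs[0]
    return out
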