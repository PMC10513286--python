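import numpy as np
import pytest

from serpinas import synthetic_data as sd
from serpinas.gene_models import GeneModel, Isoform


@pytest.fixture(scope="session")
def clade_census_genes():
    """Gene set reproducing the reported serpin-clade counts (731 genes)."""
    return sd.build_reported_clade_census()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_family():
    cfg = sd.SimConfig(
        parasitoid=sd.LifestyleParams(n_species=4, genes_per_species_mean=6.0,
                                      p_c_as=0.15, c_as_extra_mean=2.0,
                                      p_domain_dup=0.1),
        nonparasitoid=sd.LifestyleParams(n_species=4, genes_per_species_mean=3.0,
                                         p_c_as=0.5, c_as_extra_mean=5.0,
                                         p_domain_dup=0.03),
    )
    return sd.simulate_gene_family(cfg, seed=11)


def make_gene(gene_id, proteins, species="Testus examplei", domain_count=1,
              signal=None, genus=""):
    """Minimal gene with one single-exon isoform per protein string."""
    isoforms = []
    for i, p in enumerate(proteins):
        isoforms.append(Isoform(
            id=f"{gene_id}_p{i + 1}", exon_intervals=[], cds_intervals=[],
            protein=p,
            has_signal_peptide=None if signal is None else signal[i]))
    return GeneModel(id=gene_id, species=species, isoforms=isoforms,
                     domain_count=domain_count,
                     taxonomy=(genus or species.split()[0], "Fam", "Ord"))
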