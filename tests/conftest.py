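import pytest

from r2scout import simulate as sim


@pytest.fixture(scope="session")
def rdna():
    return sim.make_reference_rdna(3)


@pytest.fixture(scope="session")
def small_genome(rdna):
    """Six-unit array with one A-lineage, one offset D, one truncated D,
    one Utopia-like, and one non-site-specific homolog."""
    specs = [
        sim.ElementSpec(arch_label="A", lineage="A", family="famA"),
        sim.ElementSpec(arch_label="D", lineage="D", family="famD", insertion_offset=-11),
        sim.ElementSpec(arch_label="D", lineage="D", family="famD", truncate5_nt=250),
        sim.ElementSpec(arch_label="no-Myb", lineage="D"),
        sim.ElementSpec(arch_label="D+Myb2", lineage="D", placement="random"),
    ]
    contigs, truth = sim.build_genome_and_truth(specs, 6, seed=11, rdna=sim.make_reference_rdna(3))
    return contigs, truth, specs


@pytest.fixture(scope="session")
def element_d():
    """A plain lineage-D element: (spec, protein, element_nt)."""
    spec = sim.ElementSpec(arch_label="D", lineage="D", orf_len_aa=1000)
    prot, nt = sim.make_element(spec, 1)
    return spec, prot, nt
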