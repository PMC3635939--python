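import pytest

from lenspipe import simdata as sd
from lenspipe import snpdiscover as snp


@pytest.fixture(scope="session")
def small_ref():
    """A small reference with plenty of planted structure."""
    return sd.generate_reference(sd.ContigSpec(
        n_contigs=60, seed=101, ssr_rate=0.25, dup_rate=0.05))


@pytest.fixture(scope="session")
def small_panel(small_ref):
    return sd.mutate_panel(small_ref, sd.PanelSpec(seed=101))


@pytest.fixture(scope="session")
def clean_pileups(small_panel):
    """Error-free pileups with full >=3x coverage everywhere."""
    return sd.simulate_pileups(small_panel, depth_means=12.0, error_rate=0.0,
                               seed=101, min_depth=3)


@pytest.fixture(scope="session")
def ref_contigs(small_ref):
    return {cid: snp.ReferenceContig(cid, seq)
            for cid, seq in small_ref.contigs.items()}


@pytest.fixture(scope="session")
def clean_calls(clean_pileups, ref_contigs):
    return {g: snp.call_snps_per_genotype(clean_pileups[g], ref_contigs)
            for g in clean_pileups}


@pytest.fixture(scope="session")
def snp_table(clean_calls, clean_pileups, ref_contigs):
    return snp.merge_nonredundant(clean_calls, clean_pileups, ref_contigs)
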