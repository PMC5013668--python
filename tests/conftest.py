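import pytest

from cfemerge import SampleRecord, SimulationConfig, VariantCall


def make_variant(
    sample_id="S1",
    contig="TP53",
    pos=760,
    ref="A",
    alt="G",
    depth=10000,
    alt_fwd=100,
    alt_rev=100,
    effect="missense",
    protein_change="Y220C",
    vaf=None,
):
    if vaf is None:
        vaf = (alt_fwd + alt_rev) / depth
    return VariantCall(
        sample_id, contig, pos, ref, alt, depth, alt_fwd, alt_rev, vaf,
        effect, protein_change,
    )


@pytest.fixture
def variant():
    return make_variant()


@pytest.fixture
def plasma_sample():
    return SampleRecord(
        sample_id="S1", patient_id="P1", material="plasma_cfdna",
        timepoint_weeks=12, variants=[make_variant()],
    )


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=11)
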