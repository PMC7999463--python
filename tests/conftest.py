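import pytest

from virotriage import (
    AnnotationRecord,
    ContigSet,
    ReadMappingSummary,
    SampleBundle,
    TaxonomyIndex,
    assign_contigs,
)
from virotriage.fixtures import MINI_TAXONOMY


@pytest.fixture
def mini_index() -> TaxonomyIndex:
    """Miniature taxonomy: two superkingdoms, a shared-family genus pair
    (Norovirus/Sapovirus in Caliciviridae), and a sparse entry."""
    return TaxonomyIndex(by_taxid=dict(MINI_TAXONOMY))


def make_record(contig_id="c1", taxid=11983, pident=95.0, aln_len=600,
                bitscore=800.0, evalue=1e-50, subject_id="ref"):
    return AnnotationRecord(
        contig_id=contig_id, subject_id=subject_id, percent_identity=pident,
        alignment_length=aln_len, mismatches=10, gap_opens=0,
        qstart=1, qend=aln_len, sstart=1, send=aln_len,
        evalue=evalue, bitscore=bitscore, subject_taxid=taxid,
    )


@pytest.fixture
def calici_bundle(mini_index) -> SampleBundle:
    """One sample: c1,c2 -> Norovirus, c3 -> Sapovirus, with read counts
    {c1: 50, c2: 150, c3: 300} out of 1000 total."""
    contigs = ContigSet(entries={c: "A" * 800 for c in ("c1", "c2", "c3")})
    annotations = [
        make_record("c1", taxid=11983),
        make_record("c2", taxid=11983),
        make_record("c3", taxid=95342),
    ]
    reads = ReadMappingSummary(
        per_contig_reads={"c1": 50, "c2": 150, "c3": 300}, total_reads=1000,
        source_sample="s1",
    )
    bundle = SampleBundle(sample_id="s1", contigs=contigs,
                          annotations=annotations, reads=reads,
                          metadata_row={"group": "patient"})
    bundle.assignments = assign_contigs(annotations, mini_index)
    return bundle
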