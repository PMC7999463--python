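"""Resolve a selection plus thresholds to contig sequences on disk.

This is the batch equivalent of "download all filtered": the same
filter -> LCA -> selection pipeline that builds the abundance matrix is
replayed, and the surviving contigs are written as FASTA together with
a provenance manifest (sample, assigned taxon, supporting annotation
count, best bitscore) so downstream primer design or phylogenetics can
trace every sequence back.

Output is deterministic: contigs are ordered by (sample, contig id),
and ids are prefixed with ``<sample>|`` only when two samples share a
contig id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .aggregation import Selection, apply_selection, taxon_at_rank
from .io_formats import SampleBundle, write_fasta
from .pipeline import filter_and_assign
from .quality_filter import QualityThresholds, default_thresholds
from .taxonomy import TaxonomyIndex

logger = logging.getLogger(__name__)


@dataclass
class ExtractionRequest:
    """What to extract and where to write it."""

    selection: Selection = field(default_factory=Selection)
    thresholds: QualityThresholds = field(default_factory=default_thresholds)
    rank: str = "family"
    samples: Optional[list[str]] = None  # scope; None = all bundles
    output_path: Union[str, Path] = "extracted.fasta"
    manifest_path: Optional[Union[str, Path]] = None


@dataclass
class ExtractionResult:
    fasta_path: Path
    manifest_path: Path
    #: (sample_id, contig_id) pairs actually written, in output order
    written: list[tuple[str, str]]


def extract(
    request: ExtractionRequest,
    bundles: Sequence[SampleBundle],
    index: TaxonomyIndex,
) -> ExtractionResult:
    """Run filter -> LCA -> selection and write FASTA plus manifest.

    An empty result is a warning, not an error, so batch scripts can
    probe selections safely.
    """
    scope = (bundles if request.samples is None
             else [b for b in bundles if b.sample_id in set(request.samples)])

    assigned, _ = filter_and_assign(scope, index, request.thresholds)
    selected = apply_selection(assigned, request.selection, rank=request.rank)
    by_sample = {b.sample_id: b for b in assigned}

    rows: list[tuple[str, str]] = []  # (sample, contig)
    for sample_id in sorted(selected):
        for assignment in sorted(selected[sample_id], key=lambda a: a.contig_id):
            rows.append((sample_id, assignment.contig_id))

    # disambiguate only ids shared across samples
    id_owners: dict[str, set[str]] = {}
    for sample_id, contig_id in rows:
        id_owners.setdefault(contig_id, set()).add(sample_id)

    fasta_path = Path(request.output_path)
    manifest_path = (Path(request.manifest_path) if request.manifest_path
                     else fasta_path.with_suffix(".manifest.tsv"))

    entries: dict[str, str] = {}
    assignment_of = {
        (sid, a.contig_id): a for sid, alist in selected.items() for a in alist
    }
    with manifest_path.open("w", newline="\n") as fh:
        fh.write("contig_id\tsample\ttaxon\tsupporting_annotations\tbest_bitscore\n")
        for sample_id, contig_id in rows:
            out_id = (f"{sample_id}|{contig_id}"
                      if len(id_owners[contig_id]) > 1 else contig_id)
            entries[out_id] = by_sample[sample_id].contigs[contig_id]
            a = assignment_of[(sample_id, contig_id)]
            taxon = taxon_at_rank(a, request.rank)
            fh.write(f"{out_id}\t{sample_id}\t{taxon}\t"
                     f"{a.supporting_annotations}\t{a.best_bitscore:.1f}\n")

    write_fasta(entries, fasta_path)
    if not rows:
        logger.warning("extraction produced no sequences (selection %s)",
                       request.selection)
    return ExtractionResult(fasta_path=fasta_path, manifest_path=manifest_path,
                            written=rows)
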