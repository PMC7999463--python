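"""Glue: run quality filtering and LCA assignment over sample bundles.

Ordering matters and is fixed here: the LCA of a contig is computed
from exactly the annotations that survive the quality filter, so
spurious sub-threshold hits cannot drag assignments toward root.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .io_formats import SampleBundle
from .quality_filter import QualityThresholds, apply_filter
from .taxonomy import TaxonomyIndex, assign_contigs


def filter_and_assign(
    bundles: Sequence[SampleBundle],
    index: TaxonomyIndex,
    thresholds: Optional[QualityThresholds] = None,
) -> tuple[list[SampleBundle], dict[str, dict[str, int]]]:
    """Return new bundles holding only retained annotations, with
    per-contig LCA assignments attached, plus per-sample drop reports."""
    assigned: list[SampleBundle] = []
    reports: dict[str, dict[str, int]] = {}
    for bundle in bundles:
        retained, report = apply_filter(bundle.annotations, bundle.contigs,
                                        thresholds)
        new = SampleBundle(
            sample_id=bundle.sample_id,
            contigs=bundle.contigs,
            annotations=retained,
            reads=bundle.reads,
            metadata_row=bundle.metadata_row,
            dropped_annotations=bundle.dropped_annotations,
        )
        new.assignments = assign_contigs(retained, index)
        assigned.append(new)
        reports[bundle.sample_id] = report
    return assigned, reports
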