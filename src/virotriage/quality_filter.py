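"""Annotation quality filtering applied before any LCA or aggregation.

The default profile highlights contigs larger than 500 nucleotides with
more than 90 percent identity over an alignment of 500 nucleotides or
more.  Boundary semantics follow that wording literally: the contig
length and identity bounds are strict (>), the alignment-length bound is
inclusive (>=).  Optional e-value and bitscore bounds are absent by
default so the default profile matches the three documented criteria
exactly; workflows with different quality conventions can load a profile
from a config file instead of editing code.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .io_formats import AnnotationRecord, ContigSet

#: drop-report categories, in attribution order (first failing wins)
CRITERIA = ("missing_contig", "contig_length", "percent_identity",
            "alignment_length", "evalue", "bitscore")


@dataclass(frozen=True)
class QualityThresholds:
    """An annotation quality profile.

    ``min_contig_length`` (nt) and ``min_percent_identity`` (%) are
    exclusive lower bounds; ``min_alignment_length`` (nt) is inclusive.
    ``max_evalue`` / ``min_bitscore`` are optional inclusive bounds.
    """

    min_contig_length: float = 500
    min_percent_identity: float = 90.0
    min_alignment_length: float = 500
    max_evalue: Optional[float] = None
    min_bitscore: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("min_contig_length", "min_percent_identity",
                     "min_alignment_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.max_evalue is not None and self.max_evalue < 0:
            raise ValueError("max_evalue must be non-negative")
        if self.min_bitscore is not None and self.min_bitscore < 0:
            raise ValueError("min_bitscore must be non-negative")


def default_thresholds() -> QualityThresholds:
    """The built-in profile: contig length > 500 nt, identity > 90 %,
    alignment length >= 500 nt, no e-value or bitscore bound."""
    return QualityThresholds()


def load_thresholds(path: Union[str, Path]) -> QualityThresholds:
    """Load a threshold profile from a YAML (or flat ``key: value``)
    config file; keys absent from the file keep their defaults."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: threshold config must be a mapping")
    known = {"min_contig_length", "min_percent_identity", "min_alignment_length",
             "max_evalue", "min_bitscore"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown threshold keys {sorted(unknown)}")
    return QualityThresholds(**data)


def failing_criterion(
    record: AnnotationRecord,
    contigs: ContigSet,
    t: QualityThresholds,
) -> Optional[str]:
    """Name of the first criterion the record fails, or None if retained.

    A record whose contig is missing from the FASTA cannot satisfy the
    contig-length criterion; it is counted under ``missing_contig``.
    """
    if record.contig_id not in contigs:
        return "missing_contig"
    if contigs.length_of(record.contig_id) <= t.min_contig_length:
        return "contig_length"
    if record.percent_identity <= t.min_percent_identity:
        return "percent_identity"
    if record.alignment_length < t.min_alignment_length:
        return "alignment_length"
    if t.max_evalue is not None and record.evalue > t.max_evalue:
        return "evalue"
    if t.min_bitscore is not None and record.bitscore < t.min_bitscore:
        return "bitscore"
    return None


def apply_filter(
    annotations: Sequence[AnnotationRecord],
    contigs: ContigSet,
    t: Optional[QualityThresholds] = None,
) -> tuple[list[AnnotationRecord], dict[str, int]]:
    """Split annotations into the retained set and a per-criterion drop
    report.

    Each dropped record is attributed to the first criterion it fails,
    in the fixed order of :data:`CRITERIA`, so reports are deterministic.
    ``retained + sum(report.values()) == len(annotations)`` always.
    """
    if t is None:
        t = default_thresholds()
    retained: list[AnnotationRecord] = []
    report = {c: 0 for c in CRITERIA}
    for record in annotations:
        fail = failing_criterion(record, contigs, t)
        if fail is None:
            retained.append(record)
        else:
            report[fail] += 1
    return retained, report
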