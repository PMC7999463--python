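"""Readers and writers for the external formats a virome study touches.

Five formats are handled: contig FASTA, BLAST-like tabular annotations
(12-column outfmt-6 plus an optional trailing subject-taxid column),
per-contig read counts (BAM/SAM or a two-column counts TSV), sample
metadata TSV, and — in :mod:`virotriage.taxonomy` — the NCBI
``rankedlineage.dmp`` dialect.

The cross-file contract is identifier equality: a FASTA header token (up
to the first whitespace) must match the ``qseqid`` of annotation rows and
the reference names of the read mapping for the same sample.
:func:`assemble_bundle` enforces that contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
# one-letter IUPAC ambiguity codes other than N; normalized to N with a warning
_AMBIGUITY_CODES = frozenset("RYSWKMBDHV")

#: default column order of the annotation table: NCBI outfmt 6 plus ``staxid``
BLAST_OUTFMT6_STAXID = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "staxid",
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ContigSet:
    """Ordered collection of contig sequences from one sample.

    ``entries`` maps contig id (FASTA header token up to the first
    whitespace) to an uppercase A/C/G/T/N nucleotide string.
    """

    entries: dict[str, str] = field(default_factory=dict)
    source_sample: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self.entries

    def __getitem__(self, contig_id: str) -> str:
        return self.entries[contig_id]

    def length_of(self, contig_id: str) -> int:
        return len(self.entries[contig_id])


@dataclass
class AnnotationRecord:
    """One BLAST-like hit of a contig against a reference sequence."""

    contig_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    subject_taxid: Optional[int] = None


@dataclass
class ReadMappingSummary:
    """Mapped-read counts per contig plus the total read count of the file.

    ``total_reads`` includes unmapped reads, so relative abundances are
    computed against the full read set of the sample.
    """

    per_contig_reads: dict[str, int] = field(default_factory=dict)
    total_reads: int = 0
    source_sample: str = ""


@dataclass
class SampleMetadata:
    """Sample characteristics table: file name -> {factor -> value}."""

    rows: dict[str, dict[str, str]] = field(default_factory=dict)
    factor_names: list[str] = field(default_factory=list)


@dataclass
class SampleBundle:
    """All inputs of one sample after cross-reference checking."""

    sample_id: str
    contigs: ContigSet
    annotations: list[AnnotationRecord]
    reads: Optional[ReadMappingSummary] = None
    metadata_row: dict[str, str] = field(default_factory=dict)
    dropped_annotations: int = 0
    #: filled in by the pipeline after filtering + LCA assignment
    assignments: Optional[list] = None


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: Union[str, Path], source_sample: str = "") -> ContigSet:
    """Parse a contig FASTA file into a :class:`ContigSet`.

    Headers are truncated at the first whitespace; sequences are
    uppercased, U is normalized to T, and IUPAC ambiguity codes other
    than N are mapped to N with a warning.  Duplicate ids, empty
    sequences and non-IUPAC characters are hard errors.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return ContigSet(entries={}, source_sample=source_sample)
    if text.lstrip()[0] != ">":
        raise FormatError(f"{path}: not a FASTA file (first character is not '>')")

    entries: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        contig_id = record.id  # Biopython already truncates at whitespace
        if contig_id in entries:
            raise FormatError(f"{path}: duplicate contig id {contig_id!r}")
        seq = str(record.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"{path}: empty sequence for contig {contig_id!r}")
        bad = set(seq) - _VALID_BASES
        ambiguous = bad & _AMBIGUITY_CODES
        invalid = bad - _AMBIGUITY_CODES
        if invalid:
            raise FormatError(
                f"{path}: contig {contig_id!r} contains non-IUPAC characters "
                f"{sorted(invalid)}"
            )
        if ambiguous:
            logger.warning(
                "%s: contig %s: IUPAC ambiguity codes %s normalized to N",
                path, contig_id, sorted(ambiguous),
            )
            seq = "".join("N" if c in _AMBIGUITY_CODES else c for c in seq)
        entries[contig_id] = seq
    return ContigSet(entries=entries, source_sample=source_sample)


def write_fasta(
    entries: dict[str, str], path: Union[str, Path], line_width: int = 70
) -> None:
    """Write an ordered id->sequence map as FASTA (UTF-8, LF endings).

    Round-trips through :func:`read_fasta` for any valid
    :class:`ContigSet`.  Ids containing whitespace are rejected because
    they would not survive the header-token contract.
    """
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        for contig_id, seq in entries.items():
            if not contig_id or any(c.isspace() for c in contig_id):
                raise ValueError(f"invalid FASTA id {contig_id!r}: empty or contains whitespace")
            fh.write(f">{contig_id}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular annotations

_NUMERIC_FIELDS = {
    "pident": float, "length": int, "mismatch": int, "gapopen": int,
    "qstart": int, "qend": int, "sstart": int, "send": int,
    "evalue": float, "bitscore": float, "staxid": int,
}

_FIELD_TO_ATTR = {
    "qseqid": "contig_id", "sseqid": "subject_id", "pident": "percent_identity",
    "length": "alignment_length", "mismatch": "mismatches", "gapopen": "gap_opens",
    "qstart": "qstart", "qend": "qend", "sstart": "sstart", "send": "send",
    "evalue": "evalue", "bitscore": "bitscore", "staxid": "subject_taxid",
}


def read_blast_tab(
    path: Union[str, Path],
    column_map: Optional[Sequence[str]] = None,
) -> list[AnnotationRecord]:
    """Parse a headerless BLAST-like tab-separated annotation file.

    ``column_map`` rebinds field names to column positions; the default
    is outfmt 6 plus a trailing ``staxid``.  When the last mapped field
    is ``staxid``, rows without that final column are accepted with the
    taxid absent.  Lines starting with ``#`` are skipped.  A ``staxid``
    cell holding several ';'-separated taxids keeps the first.
    """
    columns = tuple(column_map) if column_map is not None else BLAST_OUTFMT6_STAXID
    unknown = set(columns) - set(_FIELD_TO_ATTR)
    if unknown:
        raise ValueError(f"unknown annotation fields in column_map: {sorted(unknown)}")
    staxid_trailing = columns and columns[-1] == "staxid"

    records: list[AnnotationRecord] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) != len(columns):
                if not (staxid_trailing and len(cells) == len(columns) - 1):
                    raise FormatError(
                        f"{path}: line {lineno}: expected {len(columns)} columns, "
                        f"found {len(cells)}"
                    )
            kwargs: dict[str, object] = {}
            for name, cell in zip(columns, cells):
                if name == "staxid":
                    if ";" in cell:
                        logger.warning(
                            "%s: line %d: multiple taxids %r, keeping the first",
                            path, lineno, cell,
                        )
                        cell = cell.split(";")[0]
                    if cell == "" or cell == "N/A":
                        continue
                caster = _NUMERIC_FIELDS.get(name, str)
                try:
                    value = caster(cell)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: field {name!r}: "
                        f"cannot parse {cell!r} as {caster.__name__}"
                    ) from exc
                kwargs[_FIELD_TO_ATTR[name]] = value
            records.append(AnnotationRecord(**kwargs))  # type: ignore[arg-type]
    return records


def write_blast_tab(records: Sequence[AnnotationRecord], path: Union[str, Path]) -> None:
    """Write annotation records in the 13-column dialect read by
    :func:`read_blast_tab` (taxid column left empty when absent)."""
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        for r in records:
            taxid = "" if r.subject_taxid is None else str(r.subject_taxid)
            fh.write(
                "\t".join([
                    r.contig_id, r.subject_id, f"{r.percent_identity:.1f}",
                    str(r.alignment_length), str(r.mismatches), str(r.gap_opens),
                    str(r.qstart), str(r.qend), str(r.sstart), str(r.send),
                    f"{r.evalue:.3e}", f"{r.bitscore:.1f}", taxid,
                ]) + "\n"
            )


# ---------------------------------------------------------------------------
# Read counts

def read_read_counts(
    path: Union[str, Path],
    dialect: str = "counts_tsv",
    source_sample: str = "",
) -> ReadMappingSummary:
    """Load per-contig mapped-read counts.

    dialect ``"bam"``
        Any SAM/BAM alignment file readable by pysam.  Mapped primary
        alignments (not secondary, not supplementary) are counted per
        reference; ``total_reads`` counts every read once, including
        unmapped ones.

    dialect ``"counts_tsv"``
        Two tab-separated columns ``contig_id<TAB>count`` with a final
        ``*<TAB>unmapped_count`` row, so the relative-read metric is
        reproducible without a BAM.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "bam":
        return _read_counts_bam(path, source_sample)
    if dialect == "counts_tsv":
        return _read_counts_tsv(path, source_sample)
    raise ValueError(f"unknown read-count dialect {dialect!r}")


def _read_counts_bam(path: Path, source_sample: str) -> ReadMappingSummary:
    import pysam

    per_contig: dict[str, int] = {}
    total = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for aln in af.fetch(until_eof=True):
            if aln.is_secondary or aln.is_supplementary:
                continue
            total += 1  # each read counted once, unmapped included
            if not aln.is_unmapped:
                per_contig[aln.reference_name] = per_contig.get(aln.reference_name, 0) + 1
    return ReadMappingSummary(per_contig_reads=per_contig, total_reads=total,
                              source_sample=source_sample)


def _read_counts_tsv(path: Path, source_sample: str) -> ReadMappingSummary:
    per_contig: dict[str, int] = {}
    unmapped = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 columns, found {len(cells)}"
                )
            name, count_str = cells
            try:
                count = int(count_str)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer count {count_str!r}"
                ) from exc
            if count < 0:
                raise FormatError(f"{path}: line {lineno}: negative count {count}")
            if name == "*":
                unmapped += count
            else:
                if name in per_contig:
                    raise FormatError(f"{path}: line {lineno}: duplicate contig {name!r}")
                per_contig[name] = count
    total = sum(per_contig.values()) + unmapped
    return ReadMappingSummary(per_contig_reads=per_contig, total_reads=total,
                              source_sample=source_sample)


def write_read_counts(summary: ReadMappingSummary, path: Union[str, Path]) -> None:
    """Write the counts-TSV dialect (per-contig rows plus a ``*`` row)."""
    path = Path(path)
    unmapped = summary.total_reads - sum(summary.per_contig_reads.values())
    with path.open("w", newline="\n") as fh:
        for contig_id, count in summary.per_contig_reads.items():
            fh.write(f"{contig_id}\t{count}\n")
        fh.write(f"*\t{unmapped}\n")


# ---------------------------------------------------------------------------
# Metadata

def read_metadata(path: Union[str, Path]) -> SampleMetadata:
    """Parse the sample metadata TSV: header line, file names in the
    first column, one factor per additional column."""
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln != ""]
    if len(lines) < 2:
        raise FormatError(f"{path}: metadata needs a header and at least one row")
    header = lines[0].split("\t")
    factor_names = header[1:]
    rows: dict[str, dict[str, str]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise FormatError(
                f"{path}: line {lineno}: expected {len(header)} columns, "
                f"found {len(cells)}"
            )
        key = cells[0]
        if key in rows:
            raise FormatError(f"{path}: line {lineno}: duplicate file name {key!r}")
        rows[key] = dict(zip(factor_names, cells[1:]))
    return SampleMetadata(rows=rows, factor_names=factor_names)


def write_metadata(metadata: SampleMetadata, path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write("\t".join(["file"] + metadata.factor_names) + "\n")
        for key, row in metadata.rows.items():
            fh.write("\t".join([key] + [row.get(f, "") for f in metadata.factor_names]) + "\n")


# ---------------------------------------------------------------------------
# Study directory loading

METADATA_FASTA_SUFFIX = ".contigs.fasta"


def load_study(data_dir: Union[str, Path], strict: bool = False) -> list["SampleBundle"]:
    """Load every sample of a study directory into bundles.

    Convention: the directory holds ``metadata.tsv`` (first column =
    contig FASTA file name) and, per sample ``S`` derived by stripping
    ``.contigs.fasta`` from that name, the files ``S.contigs.fasta``,
    ``S.annotations.tsv`` and optionally ``S.counts.tsv`` (or
    ``S.bam``/``S.sam``).
    """
    data_dir = Path(data_dir)
    metadata = read_metadata(data_dir / "metadata.tsv")
    bundles: list[SampleBundle] = []
    for fasta_name, row in metadata.rows.items():
        sample_id = (fasta_name[: -len(METADATA_FASTA_SUFFIX)]
                     if fasta_name.endswith(METADATA_FASTA_SUFFIX)
                     else Path(fasta_name).stem)
        contigs = read_fasta(data_dir / fasta_name, source_sample=sample_id)
        annotations = read_blast_tab(data_dir / f"{sample_id}.annotations.tsv")
        reads: Optional[ReadMappingSummary] = None
        counts_path = data_dir / f"{sample_id}.counts.tsv"
        if counts_path.exists():
            reads = read_read_counts(counts_path, "counts_tsv", sample_id)
        else:
            for suffix, dialect in ((".bam", "bam"), (".sam", "bam")):
                aln = data_dir / f"{sample_id}{suffix}"
                if aln.exists():
                    reads = read_read_counts(aln, dialect, sample_id)
                    break
        bundles.append(assemble_bundle(contigs, annotations, reads, row,
                                       sample_id, strict=strict))
    return bundles


# ---------------------------------------------------------------------------
# Bundle assembly

def assemble_bundle(
    contigs: ContigSet,
    annotations: Sequence[AnnotationRecord],
    reads: Optional[ReadMappingSummary] = None,
    metadata_row: Optional[dict[str, str]] = None,
    sample_id: str = "",
    strict: bool = False,
) -> SampleBundle:
    """Cross-check identifiers and assemble one sample's inputs.

    Annotations or read counts referring to contig ids absent from the
    FASTA are dropped with a warning (lenient mode) or abort the run
    listing up to 10 offenders (``strict=True``).
    """
    unknown_ann = sorted({a.contig_id for a in annotations if a.contig_id not in contigs})
    unknown_reads = sorted(
        c for c in (reads.per_contig_reads if reads else {}) if c not in contigs
    )
    if strict and (unknown_ann or unknown_reads):
        offenders = (unknown_ann + unknown_reads)[:10]
        raise FormatError(
            f"sample {sample_id!r}: annotations/read counts reference contigs "
            f"absent from the FASTA: {offenders}"
        )
    kept = [a for a in annotations if a.contig_id in contigs]
    dropped = len(annotations) - len(kept)
    if dropped:
        logger.warning(
            "sample %s: dropped %d annotation(s) for unknown contigs %s",
            sample_id, dropped, unknown_ann[:10],
        )
    if reads is not None and unknown_reads:
        logger.warning(
            "sample %s: read counts for unknown contigs %s ignored",
            sample_id, unknown_reads[:10],
        )
        reads = ReadMappingSummary(
            per_contig_reads={c: n for c, n in reads.per_contig_reads.items()
                              if c in contigs},
            total_reads=reads.total_reads,
            source_sample=reads.source_sample,
        )
    return SampleBundle(
        sample_id=sample_id,
        contigs=contigs,
        annotations=kept,
        reads=reads,
        metadata_row=dict(metadata_row or {}),
        dropped_annotations=dropped,
    )
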