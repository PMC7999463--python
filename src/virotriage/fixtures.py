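"""Deterministic synthetic mini-study generator with known ground truth.

The generator emulates the file set a virome annotation workflow hands
to downstream triage: per-sample contig FASTA, 13-column BLAST-like
annotation TSV, a read-count TSV, one metadata TSV, and a miniature
``rankedlineage.dmp``.  Every contig's intended fate is recorded while
generating, so the whole filter -> LCA -> aggregate -> extract pipeline
can be checked cell-for-cell against intent rather than against itself.

The built-in taxonomy embeds the branch structure the LCA logic has to
survive: two superkingdoms (so cross-superkingdom hits force a root
assignment), a shared-family / different-genus pair (Norovirus and
Sapovirus inside Caliciviridae), and sparsely ranked entries (a
crAss-like phage named only at superkingdom level).

Noise annotations violate exactly one quality criterion each (identity
or alignment length), so the filter's per-criterion drop report is
itself checkable.  Contig lengths are drawn above the default length
bound; sub-threshold evidence lives in the annotation columns, which is
where real spurious hits carry it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io_formats import (
    AnnotationRecord,
    ReadMappingSummary,
    SampleMetadata,
    write_blast_tab,
    write_fasta,
    write_metadata,
    write_read_counts,
)
from .taxonomy import RANKS, Lineage, ROOT, TaxonomyIndex, make_lineage, write_rankedlineage

_BASES = np.array(list("ACGT"))

# -- built-in miniature taxonomy -------------------------------------------

_CALICI = dict(superkingdom="Viruses", kingdom="Orthornavirae",
               phylum="Pisuviricota", **{"class": "Pisoniviricetes"},
               order="Picornavirales", family="Caliciviridae")

MINI_TAXONOMY: dict[int, Lineage] = {
    11983: make_lineage("Norwalk virus", taxid=11983, genus="Norovirus",
                        species="Norwalk virus", **_CALICI),
    95342: make_lineage("Sapporo virus", taxid=95342, genus="Sapovirus",
                        species="Sapporo virus", **_CALICI),
    11320: make_lineage("Influenza A virus", taxid=11320,
                        superkingdom="Viruses", kingdom="Orthornavirae",
                        phylum="Negarnaviricota",
                        **{"class": "Insthoviricetes"},
                        order="Articulavirales", family="Orthomyxoviridae",
                        genus="Alphainfluenzavirus",
                        species="Influenza A virus"),
    # sparse: named at superkingdom level only
    1211417: make_lineage("crAss-like phage", taxid=1211417,
                          superkingdom="Viruses"),
    # second superkingdom, used for cross-superkingdom (root-forcing) hits
    562: make_lineage("Escherichia coli", taxid=562,
                      superkingdom="Bacteria", phylum="Pseudomonadota",
                      **{"class": "Gammaproteobacteria"},
                      order="Enterobacterales", family="Enterobacteriaceae",
                      genus="Escherichia", species="Escherichia coli"),
}

_OFFTARGET_TAXID = 562
_DEFAULT_TAXA: tuple[tuple[int, float], ...] = (
    (11983, 0.35), (95342, 0.25), (11320, 0.25), (1211417, 0.15),
)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study.

    ``annotation_noise`` is the fraction of annotation records pushed
    below the default quality thresholds (each violating exactly one
    criterion); ``offtarget_fraction`` is the fraction of contigs given
    cross-superkingdom hit pairs, which must resolve to root.
    """

    seed: int = 0
    n_samples: int = 4
    taxa: tuple[tuple[int, float], ...] = _DEFAULT_TAXA
    contigs_per_sample: int = 30
    contig_length_range: tuple[int, int] = (600, 2500)
    annotation_noise: float = 0.2
    offtarget_fraction: float = 0.1

    def __post_init__(self) -> None:
        weights = [w for _, w in self.taxa]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("taxon abundance weights must sum to 1")
        lo, hi = self.contig_length_range
        if lo < 3 or hi < lo:
            raise ValueError("invalid contig_length_range")


@dataclass
class GroundTruth:
    """The generator's intent, for checking the pipeline against."""

    samples: list[str]
    #: sample -> contig -> intended post-LCA lineage; contigs whose
    #: annotations were all sub-threshold are absent
    expected_lineage: dict[str, dict[str, Lineage]]
    #: sample -> per-record failing criterion (None = survives defaults)
    record_fates: dict[str, list[Optional[str]]]
    read_counts: dict[str, dict[str, int]]
    total_reads: dict[str, int]
    metadata_rows: dict[str, dict[str, str]]
    files: dict[str, dict[str, Path]] = field(default_factory=dict)
    taxonomy: TaxonomyIndex = field(default_factory=TaxonomyIndex)

    # -- independent expectation builders ---------------------------------

    @staticmethod
    def _name_at_rank(lineage: Lineage, rank: str) -> str:
        depth = lineage.depth
        if depth == 0:
            return "root"
        idx = RANKS.index(rank)
        if idx < depth:
            return lineage.names[idx]  # type: ignore[return-value]
        return f"{lineage.names[depth - 1]} (at {RANKS[depth - 1]})"

    def expected_matrix(
        self,
        metric: str = "contigs",
        rank: str = "family",
        stratify_factor: Optional[str] = None,
    ) -> pd.DataFrame:
        """Per-intent tally of the abundance matrix (no pipeline code)."""
        per_sample: dict[str, dict[str, float]] = {}
        for sample in self.samples:
            cells: dict[str, float] = {}
            for contig, lineage in self.expected_lineage[sample].items():
                taxon = self._name_at_rank(lineage, rank)
                if metric == "contigs":
                    value = 1.0
                else:
                    value = float(self.read_counts[sample].get(contig, 0))
                cells[taxon] = cells.get(taxon, 0.0) + value
            if metric == "relative_reads":
                total = self.total_reads[sample]
                cells = {t: v / total for t, v in cells.items()}
            per_sample[sample] = cells
        frame = pd.DataFrame(per_sample).fillna(0.0)
        frame = frame.reindex(sorted(frame.index), axis=0)
        frame = frame.reindex(sorted(frame.columns), axis=1)
        if stratify_factor is not None:
            levels: dict[str, list[str]] = {}
            for sample in self.samples:
                level = self.metadata_rows[sample][stratify_factor]
                levels.setdefault(level, []).append(sample)
            grouped = {}
            for level in sorted(levels):
                members = frame[levels[level]]
                grouped[level] = (members.mean(axis=1)
                                  if metric == "relative_reads"
                                  else members.sum(axis=1))
            frame = pd.DataFrame(grouped)
        if metric == "contigs":
            frame = frame.astype(int)
        return frame

    def expected_extraction_ids(
        self,
        taxa: Optional[set[str]] = None,
        samples: Optional[set[str]] = None,
        rank: str = "family",
    ) -> set[tuple[str, str]]:
        """(sample, contig) pairs a selection should extract."""
        result: set[tuple[str, str]] = set()
        for sample in self.samples:
            if samples is not None and sample not in samples:
                continue
            for contig, lineage in self.expected_lineage[sample].items():
                taxon = self._name_at_rank(lineage, rank)
                if taxa is None or taxon in taxa:
                    result.add((sample, contig))
        return result


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _make_record(
    rng: np.random.Generator,
    contig_id: str,
    taxid: int,
    contig_length: int,
    noise_criterion: Optional[str],
) -> AnnotationRecord:
    """One annotation row; ``noise_criterion`` (if set) pushes exactly
    that field below the default thresholds."""
    if noise_criterion == "percent_identity":
        pident = round(float(rng.uniform(60.0, 89.9)), 1)
        aln_len = int(rng.integers(500, contig_length + 1))
    elif noise_criterion == "alignment_length":
        pident = round(float(rng.uniform(90.5, 99.9)), 1)
        aln_len = int(rng.integers(100, 500))
    elif noise_criterion is None:
        pident = round(float(rng.uniform(90.5, 99.9)), 1)
        aln_len = int(rng.integers(500, contig_length + 1))
    else:
        raise ValueError(f"unsupported noise criterion {noise_criterion!r}")
    qstart = 1
    qend = qstart + aln_len - 1
    mismatches = int(round(aln_len * (100.0 - pident) / 100.0))
    evalue = float(10.0 ** -rng.uniform(20.0, 180.0))
    bitscore = round(2.0 * aln_len * pident / 100.0, 1)
    return AnnotationRecord(
        contig_id=contig_id, subject_id=f"ref{taxid}",
        percent_identity=pident, alignment_length=aln_len,
        mismatches=mismatches, gap_opens=0,
        qstart=qstart, qend=qend, sstart=1, send=aln_len,
        evalue=evalue, bitscore=bitscore, subject_taxid=taxid,
    )


def generate(spec: FixtureSpec, out_dir: Union[str, Path]) -> GroundTruth:
    """Write a complete synthetic study to ``out_dir`` and return its
    :class:`GroundTruth`.  The same seed yields byte-identical files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    index = TaxonomyIndex(by_taxid=dict(MINI_TAXONOMY))
    taxids = [t for t, _ in spec.taxa]
    weights = np.array([w for _, w in spec.taxa])

    samples = [f"s{i + 1}" for i in range(spec.n_samples)]
    truth = GroundTruth(
        samples=samples, expected_lineage={}, record_fates={},
        read_counts={}, total_reads={}, metadata_rows={},
        taxonomy=index,
    )
    metadata = SampleMetadata(factor_names=["group", "location"])
    lo, hi = spec.contig_length_range

    for i, sample in enumerate(samples):
        contigs: dict[str, str] = {}
        annotations: list[AnnotationRecord] = []
        fates: list[Optional[str]] = []
        lineages: dict[str, Lineage] = {}
        reads: dict[str, int] = {}

        for j in range(spec.contigs_per_sample):
            cid = f"{sample}_c{j:03d}"
            length = int(rng.integers(lo, hi + 1))
            contigs[cid] = _random_sequence(rng, length)
            reads[cid] = int(rng.integers(10, 2001))

            if rng.random() < spec.offtarget_fraction:
                # clean hit pair spanning superkingdoms: LCA must be root
                virus_taxid = int(taxids[rng.integers(0, len(taxids))])
                for taxid in (virus_taxid, _OFFTARGET_TAXID):
                    annotations.append(
                        _make_record(rng, cid, taxid, length, None))
                    fates.append(None)
                lineages[cid] = ROOT
                continue

            taxid = int(rng.choice(taxids, p=weights))
            n_records = int(rng.integers(1, 4))
            survivors = 0
            for _ in range(n_records):
                if rng.random() < spec.annotation_noise:
                    criterion = ("percent_identity" if rng.random() < 0.5
                                 else "alignment_length")
                else:
                    criterion = None
                    survivors += 1
                annotations.append(
                    _make_record(rng, cid, taxid, length, criterion))
                fates.append(criterion)
            if survivors:
                # all surviving hits share one taxid: LCA = its ranked prefix
                lineages[cid] = index.by_taxid[taxid].prefix()

        unmapped = int(rng.integers(1000, 5001))
        total = sum(reads.values()) + unmapped

        fasta = out_dir / f"{sample}.contigs.fasta"
        ann = out_dir / f"{sample}.annotations.tsv"
        counts = out_dir / f"{sample}.counts.tsv"
        write_fasta(contigs, fasta)
        write_blast_tab(annotations, ann)
        write_read_counts(
            ReadMappingSummary(per_contig_reads=reads, total_reads=total,
                               source_sample=sample),
            counts,
        )
        row = {"group": "patient" if i % 2 == 0 else "control",
               "location": "siteA" if i < (len(samples) + 1) // 2 else "siteB"}
        metadata.rows[fasta.name] = row

        truth.expected_lineage[sample] = lineages
        truth.record_fates[sample] = fates
        truth.read_counts[sample] = reads
        truth.total_reads[sample] = total
        truth.metadata_rows[sample] = row
        truth.files[sample] = {"contigs": fasta, "annotations": ann,
                               "counts": counts}

    write_metadata(metadata, out_dir / "metadata.tsv")
    write_rankedlineage(index, out_dir / "rankedlineage.dmp")
    truth.files["_study"] = {
        "metadata": out_dir / "metadata.tsv",
        "taxdump": out_dir / "rankedlineage.dmp",
    }
    return truth
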