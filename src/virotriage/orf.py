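"""Six-frame stop-codon-delimited ORF prediction.

An ORF here is a maximal run of non-stop codons in one of the six
reading frames of a contig — a stop-to-stop fragment with no
start-codon requirement, which is the right notion for genome fragments
where true genes routinely run off the contig edge.  Fragments touching
a frame edge are kept and flagged open-ended rather than dropped.

Stops are the canonical table-1 set {TAA, TAG, TGA}.  Codons containing
N never split an ORF (a single low-quality base should not shred a long
reading frame) and translate to X.  Coordinates are 1-based inclusive
on the forward strand for all six frames; reverse-frame fragments map
back through the reverse complement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

from Bio.Data import CodonTable

from . import io_formats

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: frame scan order: forward offsets 0..2, then reverse offsets 0..2
FRAMES = (1, 2, 3, -1, -2, -3)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# codon -> amino acid for the standard code; anything else (N-containing) -> X
_TABLE1 = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_TABLE1.forward_table)
_CODON_TO_AA.update({codon: "*" for codon in _TABLE1.stop_codons})


def revcomp(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def translate(nt: str) -> str:
    """Translate a frame-oriented nucleotide string with the standard
    genetic code; codons containing N (or any non-ACGT base) become X."""
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} is not divisible by 3")
    return "".join(_CODON_TO_AA.get(nt[i:i + 3], "X") for i in range(0, len(nt), 3))


@dataclass
class OrfRecord:
    """One stop-codon-delimited fragment in one reading frame.

    ``start``/``end`` are 1-based inclusive forward-strand coordinates;
    ``nt_sequence`` is frame-oriented (already reverse-complemented for
    negative frames).  ``open_ended_5p``/``open_ended_3p`` mark sides
    not delimited by a stop codon (frame edge), in frame orientation.
    """

    contig_id: str
    frame: int
    start: int
    end: int
    nt_sequence: str
    aa_sequence: str
    open_ended_5p: bool
    open_ended_3p: bool

    @property
    def aa_length(self) -> int:
        return len(self.aa_sequence)

    @property
    def fasta_id(self) -> str:
        return f"{self.contig_id}|frame{self.frame:+d}|{self.start}-{self.end}"


def _scan_frame(frame_seq: str) -> list[tuple[int, int]]:
    """Maximal non-stop codon runs of one frame as half-open codon
    index ranges; trailing partial codons are ignored."""
    n_codons = len(frame_seq) // 3
    runs: list[tuple[int, int]] = []
    run_start = None
    for i in range(n_codons):
        if frame_seq[3 * i:3 * i + 3] in STOP_CODONS:
            if run_start is not None:
                runs.append((run_start, i))
                run_start = None
        elif run_start is None:
            run_start = i
    if run_start is not None:
        runs.append((run_start, n_codons))
    return runs


def predict_orfs(
    contig_id: str,
    sequence: str,
    min_orf_length_aa: int = 50,
) -> list[OrfRecord]:
    """Predict stop-codon-delimited ORFs on all six frames.

    Candidates shorter than ``min_orf_length_aa`` amino acids are
    dropped.  Output is ordered by frame (+1, +2, +3, -1, -2, -3) and
    forward-strand start within each frame.
    """
    sequence = sequence.upper()
    length = len(sequence)
    if length < 3:
        logger.warning("contig %s: sequence shorter than 3 nt; no ORFs", contig_id)
        return []
    reverse = revcomp(sequence)

    orfs: list[OrfRecord] = []
    for frame in FRAMES:
        offset = abs(frame) - 1
        strand_seq = sequence if frame > 0 else reverse
        frame_seq = strand_seq[offset:]
        n_codons = len(frame_seq) // 3
        for codon_start, codon_end in _scan_frame(frame_seq):
            aa_len = codon_end - codon_start
            if aa_len < min_orf_length_aa:
                continue
            nt = frame_seq[3 * codon_start:3 * codon_end]
            # 1-based inclusive positions on the scanned strand
            s_strand = offset + 3 * codon_start + 1
            e_strand = offset + 3 * codon_end
            if frame > 0:
                start, end = s_strand, e_strand
            else:
                start, end = length - e_strand + 1, length - s_strand + 1
            orfs.append(OrfRecord(
                contig_id=contig_id,
                frame=frame,
                start=start,
                end=end,
                nt_sequence=nt,
                aa_sequence=translate(nt),
                open_ended_5p=codon_start == 0,
                open_ended_3p=codon_end == n_codons,
            ))
    orfs.sort(key=lambda o: (FRAMES.index(o.frame), o.start))
    return orfs


def write_orfs(
    orfs: Sequence[OrfRecord], path: Union[str, Path], kind: str = "nt"
) -> None:
    """Save ORFs as FASTA; headers are ``<contig>|frame<±k>|<start>-<end>``."""
    if kind not in ("nt", "aa"):
        raise ValueError(f"kind must be 'nt' or 'aa', not {kind!r}")
    entries = {
        o.fasta_id: (o.nt_sequence if kind == "nt" else o.aa_sequence)
        for o in orfs
    }
    io_formats.write_fasta(entries, path)


def write_orf_table(orfs: Sequence[OrfRecord], path: Union[str, Path]) -> None:
    """Tabular companion to the FASTA output (one ORF per row)."""
    with Path(path).open("w", newline="\n") as fh:
        fh.write("contig_id\tframe\tstart\tend\taa_length\t"
                 "open_ended_5p\topen_ended_3p\n")
        for o in orfs:
            fh.write(f"{o.contig_id}\t{o.frame:+d}\t{o.start}\t{o.end}\t"
                     f"{o.aa_length}\t{o.open_ended_5p}\t{o.open_ended_3p}\n")
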