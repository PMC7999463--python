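"""Ranked-lineage taxonomy and per-contig lowest-common-ancestor assignment.

The taxonomy source is the ``rankedlineage.dmp`` file of the NCBI
new_taxdump distribution: one line per taxid giving the taxon's own name
plus its named ancestors at the eight canonical ranks.  Because that
file carries ranked names only — no parent pointers — the LCA of a set
of lineages is defined as the longest prefix of the rank ladder
(superkingdom -> species) on which every lineage has a present and
identical name.  An absent rank stops the walk: merging through a rank
one lineage does not name would invent ancestry the file does not
assert.  An empty common prefix yields the distinguished ``ROOT``
lineage, so a contig whose filtered hits span superkingdoms is reported
as "root" rather than dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .io_formats import AnnotationRecord, FormatError

logger = logging.getLogger(__name__)

#: fixed rank ladder, highest to lowest
RANKS = ("superkingdom", "kingdom", "phylum", "class", "order",
         "family", "genus", "species")

_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}


@dataclass(frozen=True)
class Lineage:
    """An ordered ranked taxon path.

    ``names`` holds one entry per rank of :data:`RANKS`; ``None`` marks
    an absent rank (taxdump lineages are sparse).  ``name`` is the
    taxon's own name, which may be deeper than any named rank (e.g. a
    strain).
    """

    taxid: Optional[int]
    name: str
    names: tuple[Optional[str], ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise ValueError(f"names must have {len(RANKS)} entries")

    def get(self, rank: str) -> Optional[str]:
        return self.names[_RANK_INDEX[rank]]

    @property
    def depth(self) -> int:
        """Length of the leading run of present ranks."""
        d = 0
        for n in self.names:
            if n is None:
                break
            d += 1
        return d

    def prefix(self) -> "Lineage":
        """The lineage truncated at its first absent rank (LCA shape)."""
        d = self.depth
        names = self.names[:d] + (None,) * (len(RANKS) - d)
        if names == self.names:
            return self
        name = names[d - 1] if d else "root"
        return Lineage(taxid=None, name=name, names=names)

    @property
    def is_root(self) -> bool:
        return self.depth == 0


#: distinguished lineage for "no common ancestor" / unknown taxid
ROOT = Lineage(taxid=1, name="root", names=(None,) * len(RANKS))


def make_lineage(name: str, taxid: Optional[int] = None, **ranks: Optional[str]) -> Lineage:
    """Convenience constructor: ``make_lineage("X", genus="G", family="F")``."""
    unknown = set(ranks) - set(RANKS)
    if unknown:
        raise ValueError(f"unknown ranks: {sorted(unknown)}")
    return Lineage(taxid=taxid, name=name,
                   names=tuple(ranks.get(r) for r in RANKS))


@dataclass
class TaxonomyIndex:
    """Pure taxid -> :class:`Lineage` lookup table."""

    by_taxid: dict[int, Lineage] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.by_taxid)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.by_taxid


@dataclass
class ContigAssignment:
    """LCA result for one contig with at least one surviving annotation."""

    contig_id: str
    lineage: Lineage
    supporting_annotations: int
    best_bitscore: float


# ---------------------------------------------------------------------------
# rankedlineage.dmp

# field order in rankedlineage.dmp after tax_id and tax_name,
# lowest rank first as NCBI writes it
_DMP_RANK_ORDER = ("species", "genus", "family", "order", "class",
                   "phylum", "kingdom", "superkingdom")


def read_rankedlineage(path: Union[str, Path]) -> TaxonomyIndex:
    """Parse a ``rankedlineage.dmp``-dialect file into a :class:`TaxonomyIndex`.

    Fields are separated by ``\\t|\\t`` and lines end with ``\\t|``;
    field order is tax_id, tax_name, species, genus, family, order,
    class, phylum, kingdom, superkingdom.  Empty fields become absent
    ranks.
    """
    path = Path(path)
    by_taxid: dict[int, Lineage] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.endswith("\t|"):
                line = line[:-2]
            fields = line.split("\t|\t")
            if len(fields) != 10:
                raise FormatError(
                    f"{path}: line {lineno}: expected 10 fields, found {len(fields)}"
                )
            try:
                taxid = int(fields[0])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer taxid {fields[0]!r}"
                ) from exc
            if taxid in by_taxid:
                raise FormatError(f"{path}: line {lineno}: duplicate taxid {taxid}")
            name = fields[1].strip()
            ranked = {rank: fields[2 + i].strip() or None
                      for i, rank in enumerate(_DMP_RANK_ORDER)}
            by_taxid[taxid] = Lineage(
                taxid=taxid, name=name,
                names=tuple(ranked[r] for r in RANKS),
            )
    return TaxonomyIndex(by_taxid=by_taxid)


def write_rankedlineage(index: TaxonomyIndex, path: Union[str, Path]) -> None:
    """Write an index back out in the taxdump dmp dialect."""
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        for taxid, lineage in index.by_taxid.items():
            ranked = [lineage.get(r) or "" for r in _DMP_RANK_ORDER]
            fields = [str(taxid), lineage.name] + ranked
            fh.write("\t|\t".join(fields) + "\t|\n")


def lineage_of(index: TaxonomyIndex, taxid: int) -> Lineage:
    """Total lookup: unknown taxids degrade to :data:`ROOT` with a warning
    so one stale identifier cannot abort a whole run."""
    lineage = index.by_taxid.get(taxid)
    if lineage is None:
        logger.warning("taxid %s not in taxonomy index; assigning root", taxid)
        return ROOT
    return lineage


# ---------------------------------------------------------------------------
# LCA

def lca(lineages: Sequence[Lineage]) -> Lineage:
    """Lowest common ancestor over the fixed rank ladder.

    Walk superkingdom -> species; a rank is kept while every input names
    it identically; the walk stops at the first disagreement or absence.
    The result is the kept prefix, its ``name`` taken from the deepest
    kept rank; an empty prefix is :data:`ROOT`.
    """
    if not lineages:
        raise ValueError("lca() requires at least one lineage")
    kept: list[str] = []
    for i in range(len(RANKS)):
        values = {ln.names[i] for ln in lineages}
        if len(values) != 1 or None in values:
            break
        kept.append(next(iter(values)))  # type: ignore[arg-type]
    if not kept:
        return ROOT
    names = tuple(kept) + (None,) * (len(RANKS) - len(kept))
    return Lineage(taxid=None, name=kept[-1], names=names)


def assign_contigs(
    filtered_annotations: Sequence[AnnotationRecord],
    index: TaxonomyIndex,
) -> list[ContigAssignment]:
    """Group already-filtered annotations by contig and compute each
    contig's LCA lineage.

    This function performs no quality filtering: callers must pass the
    retained set of :func:`virotriage.quality_filter.apply_filter`, so
    that spurious hits cannot drag assignments toward root.  Records
    without a usable taxid contribute no lineage; a contig whose records
    all lack taxids is assigned :data:`ROOT`.
    """
    groups: dict[str, list[AnnotationRecord]] = {}
    for record in filtered_annotations:
        groups.setdefault(record.contig_id, []).append(record)

    assignments: list[ContigAssignment] = []
    for contig_id, records in groups.items():
        lineages = [lineage_of(index, r.subject_taxid)
                    for r in records if r.subject_taxid is not None]
        lineage = lca(lineages) if lineages else ROOT
        assignments.append(ContigAssignment(
            contig_id=contig_id,
            lineage=lineage,
            supporting_annotations=len(records),
            best_bitscore=max(r.bitscore for r in records),
        ))
    return assignments
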