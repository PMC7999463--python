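"""Taxon-by-sample abundance matrices and declarative selections.

After filtering and LCA assignment, each contig carries one lineage.
This module tallies contigs into a taxon x sample (or taxon x
metadata-group) matrix under one of three fill metrics:

``CONTIG_COUNT``
    number of assigned contigs per taxon;
``READ_COUNT``
    sum of mapped reads over those contigs;
``RELATIVE_READS``
    that sum divided by the sample's total read count (mapped +
    unmapped), so per-sample columns always sum to <= 1.

Contigs whose LCA is shallower than the requested rank appear under
their deepest available name suffixed with its rank ("Caliciviridae (at
family)" when drawn at species level), and root-assigned contigs under
"root", so nothing the filter retained silently disappears.

The interactive tile selection of a heatmap UI is re-expressed here as
a declarative :class:`Selection` (sets of taxa and samples); an empty
selection selects everything.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io_formats import SampleBundle
from .taxonomy import RANKS, ContigAssignment, _RANK_INDEX

logger = logging.getLogger(__name__)


class FillMetric(enum.Enum):
    """The value heatmap tiles are colored by."""

    CONTIG_COUNT = "contigs"
    READ_COUNT = "reads"
    RELATIVE_READS = "relative_reads"

    @classmethod
    def parse(cls, value: Union[str, "FillMetric"]) -> "FillMetric":
        if isinstance(value, cls):
            return value
        for metric in cls:
            if value in (metric.value, metric.name, metric.name.lower()):
                return metric
        raise ValueError(
            f"unknown fill metric {value!r}; choose from "
            f"{[m.value for m in cls]}"
        )


@dataclass
class AbundanceMatrix:
    """Taxon x sample(-group) matrix under one metric and rank."""

    values: pd.DataFrame  # rows: taxa (alphabetical), columns: samples/groups
    metric: FillMetric
    rank: str
    stratify_factor: Optional[str] = None

    @property
    def row_labels(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_labels(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class Selection:
    """Declarative subset of the current view; both fields absent means
    everything is selected."""

    taxa: Optional[set[str]] = None
    samples: Optional[set[str]] = None

    @property
    def is_empty(self) -> bool:
        return self.taxa is None and self.samples is None


def taxon_at_rank(assignment: ContigAssignment, rank: str) -> str:
    """Display name of an assignment at a rank of the ladder.

    A lineage shallower than the rank falls back to its deepest
    available name suffixed "(at <rank>)"; a root assignment is "root".
    """
    if rank not in _RANK_INDEX:
        raise ValueError(f"unknown rank {rank!r}; valid ranks: {list(RANKS)}")
    lineage = assignment.lineage
    depth = lineage.depth
    if depth == 0:
        return "root"
    idx = _RANK_INDEX[rank]
    if idx < depth:
        return lineage.names[idx]  # type: ignore[return-value]
    deepest = depth - 1
    return f"{lineage.names[deepest]} (at {RANKS[deepest]})"


def _per_sample_values(
    bundle: SampleBundle, metric: FillMetric, rank: str
) -> dict[str, float]:
    if bundle.assignments is None:
        raise ValueError(f"sample {bundle.sample_id!r} has no LCA assignments")
    if metric is not FillMetric.CONTIG_COUNT and bundle.reads is None:
        raise ValueError(
            f"metric {metric.value!r} needs read counts, but sample "
            f"{bundle.sample_id!r} has none"
        )
    cells: dict[str, float] = {}
    for assignment in bundle.assignments:
        taxon = taxon_at_rank(assignment, rank)
        if metric is FillMetric.CONTIG_COUNT:
            value = 1.0
        else:
            value = float(bundle.reads.per_contig_reads.get(assignment.contig_id, 0))
        cells[taxon] = cells.get(taxon, 0.0) + value
    if metric is FillMetric.RELATIVE_READS:
        total = bundle.reads.total_reads
        if total <= 0:
            raise ValueError(
                f"sample {bundle.sample_id!r}: total read count is 0; cannot "
                "compute relative reads"
            )
        cells = {t: v / total for t, v in cells.items()}
    return cells


def aggregate(
    bundles: Sequence[SampleBundle],
    metric: Union[str, FillMetric] = FillMetric.CONTIG_COUNT,
    rank: str = "family",
    stratify_factor: Optional[str] = None,
) -> AbundanceMatrix:
    """Build the abundance matrix over samples (or metadata groups).

    Each bundle must already carry assignments computed from its
    filtered annotations; contigs with no surviving annotation never
    appear.  With a stratification factor, columns are the factor's
    levels; counts and reads of member samples are summed, while
    relative reads are averaged unweighted so deeply sequenced samples
    do not dominate their group.
    """
    metric = FillMetric.parse(metric)
    if rank not in _RANK_INDEX:
        raise ValueError(f"unknown rank {rank!r}; valid ranks: {list(RANKS)}")
    per_sample = {
        b.sample_id: _per_sample_values(b, metric, rank) for b in bundles
    }
    frame = pd.DataFrame(per_sample).fillna(0.0)
    frame = frame.reindex(sorted(frame.index), axis=0)
    frame = frame.reindex(sorted(frame.columns), axis=1)

    if stratify_factor is not None:
        levels: dict[str, list[str]] = {}
        for b in bundles:
            if stratify_factor not in b.metadata_row:
                raise ValueError(
                    f"stratification factor {stratify_factor!r} missing from "
                    f"metadata of sample {b.sample_id!r}"
                )
            levels.setdefault(b.metadata_row[stratify_factor], []).append(b.sample_id)
        grouped = {}
        for level in sorted(levels):
            members = frame[levels[level]]
            grouped[level] = (members.mean(axis=1)
                              if metric is FillMetric.RELATIVE_READS
                              else members.sum(axis=1))
        frame = pd.DataFrame(grouped)

    if metric is FillMetric.CONTIG_COUNT:
        frame = frame.astype(int)
    return AbundanceMatrix(values=frame, metric=metric, rank=rank,
                           stratify_factor=stratify_factor)


def apply_selection(
    bundles: Sequence[SampleBundle],
    selection: Selection,
    rank: str = "family",
) -> dict[str, list[ContigAssignment]]:
    """Resolve a selection to the assignments it covers, per sample.

    An empty selection is the identity (everything selected).  Selected
    taxa that never occur are warned about and ignored, mirroring a
    click on an empty heatmap region.
    """
    seen_taxa: set[str] = set()
    result: dict[str, list[ContigAssignment]] = {}
    for bundle in bundles:
        if bundle.assignments is None:
            raise ValueError(f"sample {bundle.sample_id!r} has no LCA assignments")
        if selection.samples is not None and bundle.sample_id not in selection.samples:
            continue
        kept: list[ContigAssignment] = []
        for assignment in bundle.assignments:
            taxon = taxon_at_rank(assignment, rank)
            seen_taxa.add(taxon)
            if selection.taxa is None or taxon in selection.taxa:
                kept.append(assignment)
        result[bundle.sample_id] = kept
    if selection.taxa is not None:
        missing = selection.taxa - seen_taxa
        if missing:
            logger.warning("selected taxa not present in the view: %s",
                           sorted(missing))
    return result


# ---------------------------------------------------------------------------
# Export / plotting

def export_matrix(matrix: AbundanceMatrix, path: Union[str, Path],
                  format: str = "tsv") -> None:
    """Write the matrix as a TSV: taxon rows, sample/group columns,
    header row, '.' decimal separator."""
    if format != "tsv":
        raise ValueError(f"unsupported export format {format!r}")
    matrix.values.to_csv(Path(path), sep="\t", index_label="taxon",
                         float_format="%.10g", lineterminator="\n")


def read_matrix(path: Union[str, Path]) -> pd.DataFrame:
    """Re-read an exported matrix TSV (values only)."""
    return pd.read_csv(Path(path), sep="\t", index_col="taxon")


def plot_heatmap(matrix: AbundanceMatrix, path: Union[str, Path]) -> None:
    """Render the matrix as a static heatmap image (PNG/SVG by suffix)."""
    if matrix.values.shape[0] < 1 or matrix.values.shape[1] < 1:
        raise ValueError(
            "abundance matrix is empty — nothing survived filtering; "
            "consider relaxing the quality thresholds"
        )
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.values.to_numpy(dtype=float)
    n_rows, n_cols = data.shape
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.6 * n_cols + 2.5), max(3.0, 0.3 * n_rows + 1.5))
    )
    im = ax.imshow(data, aspect="auto", cmap="viridis")
    ax.set_xticks(np.arange(n_cols), labels=matrix.col_labels,
                  rotation=45, ha="right")
    ax.set_yticks(np.arange(n_rows), labels=matrix.row_labels)
    strat = (f", stratified by {matrix.stratify_factor}"
             if matrix.stratify_factor else "")
    ax.set_title(f"{matrix.metric.value} at {matrix.rank} level{strat}")
    fig.colorbar(im, ax=ax, label=matrix.metric.value)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
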