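"""Abundance matrices: metrics, rank naming, stratification,
selection semantics, export round trip and conservation laws."""

import numpy as np
import pandas as pd
import pytest

from virotriage import (
    ContigSet,
    ReadMappingSummary,
    SampleBundle,
    Selection,
    aggregate,
    apply_selection,
    assign_contigs,
    export_matrix,
    plot_heatmap,
    taxon_at_rank,
)
from virotriage.aggregation import FillMetric, read_matrix
from virotriage.taxonomy import ContigAssignment, ROOT
from conftest import make_record


class TestTaxonAtRank:
    def _assignment(self, lineage):
        return ContigAssignment("c1", lineage, 1, 100.0)

    def test_deeper_lineage_queried_at_family(self, mini_index):
        a = self._assignment(mini_index.by_taxid[11983])
        assert taxon_at_rank(a, "family") == "Caliciviridae"

    def test_shallow_lineage_falls_back_with_rank_suffix(self, mini_index):
        from virotriage import lca
        family_level = lca([mini_index.by_taxid[11983],
                            mini_index.by_taxid[95342]])
        a = self._assignment(family_level)
        assert taxon_at_rank(a, "species") == "Caliciviridae (at family)"

    def test_root_at_any_rank(self):
        a = self._assignment(ROOT)
        assert taxon_at_rank(a, "species") == "root"
        assert taxon_at_rank(a, "superkingdom") == "root"

    def test_unknown_rank_lists_valid_ones(self, mini_index):
        a = self._assignment(mini_index.by_taxid[11983])
        with pytest.raises(ValueError, match="superkingdom"):
            taxon_at_rank(a, "tribe")


class TestAggregate:
    def test_contig_count_at_genus(self, calici_bundle):
        mat = aggregate([calici_bundle], metric="contigs", rank="genus")
        assert mat.values.loc["Norovirus", "s1"] == 2
        assert mat.values.loc["Sapovirus", "s1"] == 1

    def test_relative_reads(self, calici_bundle):
        mat = aggregate([calici_bundle], metric="relative_reads", rank="genus")
        assert mat.values.loc["Norovirus", "s1"] == pytest.approx(0.2)
        assert mat.values["s1"].sum() <= 1.0

    def test_family_row_sums_genus_rows(self, calici_bundle):
        genus = aggregate([calici_bundle], metric="contigs", rank="genus")
        family = aggregate([calici_bundle], metric="contigs", rank="family")
        assert family.values.loc["Caliciviridae", "s1"] == \
            genus.values["s1"].sum() == 3

    def test_rank_coarsening_conserves_mass(self, calici_bundle):
        for metric in ("contigs", "reads"):
            sums = {
                rank: aggregate([calici_bundle], metric=metric,
                                rank=rank).values["s1"].sum()
                for rank in ("superkingdom", "family", "genus", "species")
            }
            assert len(set(sums.values())) == 1

    def test_relative_reads_requires_counts(self, calici_bundle):
        calici_bundle.reads = None
        with pytest.raises(ValueError, match="s1"):
            aggregate([calici_bundle], metric="relative_reads", rank="genus")

    def test_unknown_metric_and_rank(self, calici_bundle):
        with pytest.raises(ValueError, match="metric"):
            aggregate([calici_bundle], metric="coverage", rank="genus")
        with pytest.raises(ValueError, match="rank"):
            aggregate([calici_bundle], metric="contigs", rank="tribe")

    def test_missing_stratify_factor(self, calici_bundle):
        with pytest.raises(ValueError, match="phenotype"):
            aggregate([calici_bundle], metric="contigs", rank="genus",
                      stratify_factor="phenotype")

    def test_random_samples_match_tally_oracle(self, mini_index):
        """Every cell equals a brute-force per-contig tally."""
        rng = np.random.default_rng(21)
        taxids = [11983, 95342, 11320, 1211417]
        bundles = []
        truth = []  # (sample, contig, taxid, reads)
        for s in range(5):
            sid = f"s{s}"
            contigs, annotations, reads = {}, [], {}
            for c in range(int(rng.integers(3, 15))):
                cid = f"{sid}_c{c}"
                taxid = int(taxids[rng.integers(0, 4)])
                contigs[cid] = "A" * 800
                annotations.append(make_record(cid, taxid=taxid))
                reads[cid] = int(rng.integers(1, 500))
                truth.append((sid, cid, taxid, reads[cid]))
            bundle = SampleBundle(
                sample_id=sid, contigs=ContigSet(entries=contigs),
                annotations=annotations,
                reads=ReadMappingSummary(per_contig_reads=reads,
                                         total_reads=sum(reads.values()) + 100),
            )
            bundle.assignments = assign_contigs(annotations, mini_index)
            bundles.append(bundle)

        mat = aggregate(bundles, metric="contigs", rank="genus")
        for sid in {t[0] for t in truth}:
            for taxid, name in ((11983, "Norovirus"), (95342, "Sapovirus"),
                                (11320, "Alphainfluenzavirus"),
                                (1211417, "Viruses (at superkingdom)")):
                expected = sum(1 for t in truth
                               if t[0] == sid and t[2] == taxid)
                got = (mat.values.loc[name, sid]
                       if name in mat.values.index else 0)
                assert got == expected

        rmat = aggregate(bundles, metric="reads", rank="genus")
        for sid in {t[0] for t in truth}:
            expected = sum(t[3] for t in truth if t[0] == sid)
            assert rmat.values[sid].sum() == expected


class TestStratification:
    def _two_samples(self, mini_index):
        bundles = []
        for sid, taxid, n, group in (("s1", 11983, 2, "patient"),
                                     ("s2", 95342, 3, "control"),
                                     ("s3", 11983, 1, "patient")):
            contigs = {f"{sid}_c{i}": "A" * 800 for i in range(n)}
            annotations = [make_record(c, taxid=taxid) for c in contigs]
            reads = {c: 100 for c in contigs}
            b = SampleBundle(
                sample_id=sid, contigs=ContigSet(entries=contigs),
                annotations=annotations,
                reads=ReadMappingSummary(per_contig_reads=reads,
                                         total_reads=1000),
                metadata_row={"group": group},
            )
            b.assignments = assign_contigs(annotations, mini_index)
            bundles.append(b)
        return bundles

    def test_counts_sum_over_member_samples(self, mini_index):
        bundles = self._two_samples(mini_index)
        flat = aggregate(bundles, metric="contigs", rank="genus")
        strat = aggregate(bundles, metric="contigs", rank="genus",
                          stratify_factor="group")
        assert list(strat.values.columns) == ["control", "patient"]
        assert strat.values.loc["Norovirus", "patient"] == \
            flat.values.loc["Norovirus", ["s1", "s3"]].sum() == 3

    def test_relative_reads_are_group_means(self, mini_index):
        bundles = self._two_samples(mini_index)
        strat = aggregate(bundles, metric="relative_reads", rank="genus",
                          stratify_factor="group")
        # s1: 200/1000, s3: 100/1000 -> unweighted mean 0.15
        assert strat.values.loc["Norovirus", "patient"] == pytest.approx(0.15)


class TestSelection:
    def test_empty_selection_is_identity(self, calici_bundle):
        selected = apply_selection([calici_bundle], Selection(), rank="genus")
        assert [a.contig_id for a in selected["s1"]] == ["c1", "c2", "c3"]

    def test_taxa_selection(self, calici_bundle):
        selected = apply_selection(
            [calici_bundle], Selection(taxa={"Norovirus"}), rank="genus")
        assert [a.contig_id for a in selected["s1"]] == ["c1", "c2"]

    def test_disjoint_selection_is_empty_not_error(self, calici_bundle):
        selected = apply_selection(
            [calici_bundle],
            Selection(taxa={"Norovirus"}, samples={"s2"}), rank="genus")
        assert selected == {}

    def test_unknown_taxon_warns_and_is_ignored(self, calici_bundle, caplog):
        with caplog.at_level("WARNING"):
            selected = apply_selection(
                [calici_bundle], Selection(taxa={"Norovirus", "Ebolavirus"}),
                rank="genus")
        assert "Ebolavirus" in caplog.text
        assert [a.contig_id for a in selected["s1"]] == ["c1", "c2"]

    def test_idempotent(self, calici_bundle):
        sel = Selection(taxa={"Norovirus"})
        first = apply_selection([calici_bundle], sel, rank="genus")
        calici_bundle.assignments = first["s1"]
        second = apply_selection([calici_bundle], sel, rank="genus")
        assert second == first


class TestExportAndPlot:
    def test_tsv_shape(self, calici_bundle, tmp_path):
        mat = aggregate([calici_bundle], metric="contigs", rank="genus")
        p = tmp_path / "m.tsv"
        export_matrix(mat, p)
        lines = p.read_text().splitlines()
        assert lines[0] == "taxon\ts1"
        assert len(lines) == 3  # header + 2 taxa

    def test_round_trip_to_10_significant_digits(self, calici_bundle, tmp_path):
        mat = aggregate([calici_bundle], metric="relative_reads", rank="genus")
        p = tmp_path / "m.tsv"
        export_matrix(mat, p)
        back = read_matrix(p)
        assert np.allclose(back.to_numpy(), mat.values.to_numpy(),
                           rtol=1e-9, atol=0)
        assert list(back.index) == mat.row_labels

    def test_single_cell_plot(self, calici_bundle, tmp_path):
        mat = aggregate([calici_bundle], metric="contigs", rank="superkingdom")
        assert mat.values.shape == (1, 1)
        out = tmp_path / "h.png"
        plot_heatmap(mat, out)
        assert out.stat().st_size > 0

    def test_empty_matrix_plot_advises_relaxation(self):
        empty = aggregate([], metric="contigs", rank="genus")
        with pytest.raises(ValueError, match="threshold"):
            plot_heatmap(empty, "unused.png")

    def test_metric_parse_aliases(self):
        assert FillMetric.parse("reads") is FillMetric.READ_COUNT
        assert FillMetric.parse("READ_COUNT") is FillMetric.READ_COUNT
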