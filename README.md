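# virotriage

Headless triage of virome contig annotation results.

Viral metagenomics workflows typically end with assembled contigs in
FASTA format plus a BLAST-like tabular file linking each contig to
reference sequences and taxonomic identifiers, a read mapping giving
per-contig read counts, and a study metadata table. Turning that pile
of files into "which viruses are in which samples, with how much
evidence, and give me those sequences" usually means ad-hoc scripts.
`virotriage` packages those steps as a library and a CLI for
bioinformaticians and virologists who need them scriptable and
reproducible: no GUI, no server, deterministic outputs.

## What it computes

1. **Quality filtering.** An annotation record survives iff

   `contig_length > 500 nt` AND `percent_identity > 90 %` AND
   `alignment_length ≥ 500 nt`

   by default (all three bounds overridable per run or via a YAML
   profile; optional e-value and bitscore bounds are off by default).
   Every dropped record is attributed to the first criterion it fails,
   so the drop report is deterministic.

2. **LCA lineages.** Per contig, the lineages of its surviving hits —
   resolved through an NCBI `rankedlineage.dmp`-style table — are
   combined into a lowest common ancestor over the fixed rank ladder
   superkingdom → kingdom → phylum → class → order → family → genus →
   species: the longest leading run of ranks on which all hits agree.
   Hits spanning superkingdoms (or records without a usable taxid)
   yield the distinguished `root` assignment. The LCA is always
   computed *after* filtering, so spurious low-quality hits cannot drag
   assignments toward root.

3. **Abundance matrices.** Assigned contigs are tallied into a
   taxon × sample matrix at any rank, filled by contig count, absolute
   read count, or relative reads (reads on a taxon's contigs divided by
   the sample's total read count, mapped + unmapped). Samples can be
   stratified by any metadata factor.

4. **Six-frame ORFs.** Stop-to-stop open reading frames (canonical
   stops TAA/TAG/TGA, no start-codon requirement) on all six frames,
   with a minimal-size cutoff in amino acids, nucleotide and protein
   FASTA output, and open-ended edge fragments flagged rather than
   dropped.

5. **Sequence extraction.** A declarative selection (taxa × samples)
   plus thresholds resolves to contig FASTA and a provenance manifest,
   deterministically ordered.

A seeded synthetic-study generator (`virotriage simulate`) produces all
five input formats with known ground truth, so the full pipeline is
testable end to end without downloads.

## Worked example

```sh
$ virotriage simulate --seed 1 --out demo/data
wrote synthetic study with 4 samples to demo/data

$ virotriage run-all --data-dir demo/data --metric relative_reads \
      --rank genus --stratify-by group --out demo/out
run complete: matrix 5x2, 112 sequences extracted

$ head demo/out/matrix.tsv
taxon	control	patient
Alphainfluenzavirus	0.208780754	0.1713653748
Norovirus	0.2444087592	0.3061453232
Sapovirus	0.1898589886	0.1762867934
Viruses (at superkingdom)	0.08710313798	0.1613083199
root	0.08164850331	0.07232271135
```

Each cell is the group mean of per-sample relative read fractions at
genus level: e.g. on average 30.6 % of all reads in "patient" samples
map to contigs assigned to *Norovirus*. Contigs whose LCA is shallower
than genus appear under their deepest name ("Viruses (at
superkingdom)"); contigs whose hits span superkingdoms appear under
`root`. A `heatmap.png` and the extracted FASTA + manifest land in the
same directory.

Selections narrow every downstream artifact:

```sh
$ virotriage extract --data-dir demo/data --rank genus \
      --select-taxa Norovirus --out demo/noro
extracted 39 sequences

$ head -4 demo/noro/extracted.manifest.tsv
contig_id	sample	taxon	supporting_annotations	best_bitscore
s1_c000	s1	Norovirus	3	1557.4
s1_c003	s1	Norovirus	3	1331.3
s1_c009	s1	Norovirus	2	1040.0
```

The same operations are available as library calls
(`virotriage.apply_filter`, `assign_contigs`, `aggregate`,
`predict_orfs`, `extract`, …); the CLI is a thin wrapper.

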