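# Methods

## Input contract

Five formats are read: contig FASTA, BLAST-like tabular annotations,
read mappings (SAM/BAM or a counts TSV), a sample metadata TSV, and an
NCBI `rankedlineage.dmp`-dialect taxonomy. The binding contract is
identifier equality across files: the FASTA header token (up to the
first whitespace) must equal the query id of annotation rows and the
reference names of the read mapping. Both sides are compared after
whitespace truncation, since FASTA descriptions are common in practice.
Annotations referencing unknown contigs are dropped with a warning in
lenient mode and abort the run in strict mode.

The annotation dialect defaults to NCBI outfmt-6's 12 columns plus a
trailing `staxid`. The trailing taxid column is optional row-by-row
(a record without it is kept but contributes no lineage), and a
`column_map` argument rebinds field names to positions for workflows
that emit other column orders. A `staxid` cell holding several
`;`-separated taxids keeps the first — reference databases occasionally
merge identical sequences from several taxa, and the first entry is the
primary one.

Read counting from SAM/BAM uses mapped primary alignments only
(secondary and supplementary records excluded, no mapping-quality
floor), so each read contributes at most once. `total_reads` counts
every read in the file including unmapped ones; the counts-TSV dialect
carries the unmapped count in a `*` row so relative abundances are
reproducible without the alignment file.

FASTA normalization: sequences are uppercased, U→T, and IUPAC
ambiguity codes other than N are mapped to N with a warning. Mapping
rather than rejecting keeps assemblies with sporadic ambiguous bases
usable; anything outside the IUPAC alphabet is a hard error.

## Quality filtering

The default profile retains a record iff contig length > 500 nt,
percent identity > 90, and alignment length ≥ 500 nt. The boundary
semantics are intentionally asymmetric — the length and identity bounds
are strict, the alignment-length bound inclusive — following the
profile's documented wording literally. Optional e-value (inclusive
ceiling) and bitscore (inclusive floor) bounds are absent by default so
that the default profile is exactly the three documented criteria.
Profiles load from YAML; CLI flags override the file, which overrides
the defaults.

The drop report attributes each dropped record to the *first* failing
criterion in the fixed order missing-contig, contig length, identity,
alignment length, e-value, bitscore. First-failure attribution makes
reports deterministic and sums to the number of dropped records; it
does not claim a record fails only that criterion.

## LCA over ranked lineages

`rankedlineage.dmp` provides, per taxid, the taxon's own name plus its
named ancestors at eight fixed ranks — names only, no parent pointers.
The LCA of a lineage set is therefore defined as the longest prefix of
the ladder (superkingdom → species) on which every lineage has a
present and identical name. An absent rank stops the walk: merging
through a rank one lineage does not name would invent ancestry the
table does not assert, and taxdump lineages are genuinely sparse
(ranks like kingdom are unnamed for many prokaryotes, and many viral
entries name only a few levels). Consequences:

* a single lineage's LCA is its own ranked prefix (its name truncated
  to the deepest named leading rank);
* lineages sharing a family but differing at genus resolve to the
  family;
* lineages from different superkingdoms, and contigs whose records all
  lack usable taxids, resolve to the distinguished `root` lineage,
  which is reported as a "root" row rather than silently dropped;
* unknown taxids degrade to `root` with a warning instead of aborting,
  so one stale identifier cannot kill a batch run.

LCA is always computed on the quality-filtered annotation set
(`filter_and_assign` fixes the order), because a single spurious
low-identity hit to the wrong superkingdom would otherwise drag a
well-supported contig to root.

## Abundance matrices

Cells are tallied per assigned contig at the chosen rank. A lineage
shallower than the display rank contributes to a row named after its
deepest available rank ("Caliciviridae (at family)" in a species-level
view), so mass is never lost when coarse assignments meet a fine view;
column sums are invariant under the rank choice for the count metrics.

Metrics: contig count (integer), read count (sum of per-contig mapped
reads over assigned contigs), and relative reads (that sum divided by
the sample's total read count). Only contigs with at least one
surviving annotation are counted — the matrix describes the annotated,
quality-filtered view, not the whole assembly — so relative columns sum
to ≤ 1 and the remainder is unannotated or unmapped signal.

Stratification by a metadata factor sums member samples' cells for the
count metrics. For relative reads it takes the *unweighted mean* of
member samples' ratios rather than pooling reads, so a deeply
sequenced sample cannot dominate its group; the choice is recorded in
the matrix metadata. Rows and columns are sorted lexicographically for
deterministic output.

Interactive tile selection in a heatmap UI is re-expressed as a
declarative `Selection` — optional sets of taxa and samples — where the
empty selection selects everything. Selections naming absent taxa warn
and are ignored, mirroring a click on an empty region.

## ORF prediction

An ORF is a maximal run of non-stop codons in one of the six reading
frames: a stop-to-stop fragment with no start-codon requirement. For
genome fragments this is the right notion — genes routinely run off
contig edges — so edge fragments are kept and flagged
`open_ended_5p`/`open_ended_3p` instead of dropped. Stops are the
canonical table-1 set {TAA, TAG, TGA}. Codons containing N never split
an ORF (one low-quality base should not shred a long reading frame)
and translate to X; this is deliberately more conservative than
resolving ambiguity codes where possible, so protein output marks every
uncertain residue. The minimal size default is 50 aa, a common floor
below which random stop-free runs dominate; it is a CLI flag
(`--min-orf-aa`).

Coordinates are 1-based inclusive on the forward strand for all
frames; reverse-frame sequences are reverse-complemented, and the
strand-symmetry property (frames ±k mirror under reverse complement
with start' = L − end + 1) is enforced by test.

## Synthetic studies and what they show

The fixture generator emulates the complete input file set with known
intent: per-sample contigs (uniform random A/C/G/T, lengths 600–2500
nt), 1–3 annotation records per contig against a miniature taxonomy,
read counts (10–2000 per contig plus an unmapped remainder of
1000–5000), a two-factor metadata table, and the taxonomy itself. The
mini taxonomy embeds the branch structure the LCA must survive: two
superkingdoms, a shared-family/different-genus pair (Norovirus and
Sapovirus in Caliciviridae), a fully ranked lineage with a different
family (Influenza A virus), and a sparse superkingdom-only entry
(crAss-like phage).

Defaults: 4 samples × 30 contigs, 20 % annotation noise, 10 %
off-target contigs. Noise records violate exactly one criterion each —
identity (drawn in 60–89.9 %) or alignment length (100–499 nt) — so the
per-criterion drop report is checkable; clean records are drawn
strictly above the default bounds (identity 90.5–99.9 %, alignment
length ≥ 500 nt). Contig length noise is exercised by unit tests rather
than the generator, because contig length is a per-contig property that
would couple the fates of all of a contig's records. Off-target contigs
receive a clean virus + bacterium hit pair and must resolve to root.

Everything derives from one seeded generator, and the same seed yields
byte-identical files. Ground truth records each contig's intended
post-LCA lineage and each record's intended filter fate, and rebuilds
expected matrices by direct tally — independent of the parsing,
filtering and aggregation paths it checks.

What passing does *not* show: the generator draws i.i.d. uniform
sequences and noiseless identifier bookkeeping, so it exercises the
bookkeeping, boundary semantics and LCA/tally arithmetic, not
robustness to real-world pathology (chimeric contigs, conflicting
multi-database annotations, taxids missing from an out-of-date
taxonomy dump, paired-end double counting). Real BLAST output can also
interleave samples or use other column orders; those paths are covered
only insofar as the `column_map` and strict-mode tests reach them.

## Numerical and determinism notes

* All randomness flows through `numpy.random.default_rng` with
  explicit seeds; repeated runs are byte-identical, including FASTA
  and TSV output (fixed float formats: identity %.1f, e-value %.3e,
  bitscore %.1f).
* Matrix export writes 10 significant digits; the export→import round
  trip is validated to 1e-9 relative error.
* Relative-read agreement between pipeline and ground-truth tally is
  asserted at 1e-12 absolute — the only arithmetic involved is one
  division per cell, so anything looser would hide real defects.
* Extraction output is ordered (sample, contig id) lexicographically;
  cross-sample id collisions are disambiguated by a `sample|` prefix
  only when they occur, keeping headers clean in the common case.
* Degenerate inputs: empty annotation files, empty selections and
  empty extraction results are warnings, not errors; an empty matrix
  refuses only to *plot*, with a hint to relax thresholds.

## Problem sizes in the validation suite

The oracle suites run at 1000 random lineage sets (LCA), 5000 random
sequences ≤ 2 kb (ORFs, with strand-symmetry spot checks every 20th
sequence), and 200 records × 20 threshold profiles (filter); the
pipeline round trip uses the generator defaults (4 × 30 contigs).
These sizes give every branch (sparse ranks, forced root, boundary
ties, N-codons) hundreds of hits while the whole suite stays
interactive.

## Known limitations

* Lineage resolution requires a taxid column; accession-to-taxid
  mapping is out of scope, as are nodes.dmp/names.dmp graph walks and
  merged-taxid remapping.
* No FASTQ handling, no paired-end awareness, no remote access; the
  taxonomy file must be local.
* The ORF model is a stop-codon splitter by design — no codon-usage
  scoring, no alternative genetic codes.
* No normalization beyond total-read scaling, and no diversity or
  differential-abundance statistics; the matrix is meant for browsing
  and selection, not inference.
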