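# Methods

## Model

A sample is a set of assembled sequences — contigs, or contigs binned
into MAGs — each with a mean per-base sequencing depth per sample.
Depth is the abundance proxy: a gene present on a feature contributes
that feature's depth. For gene *q*, control gene *c*, and sample *s*:

    score(q, s) = Σ_{f ∈ F(q)} depth(f, s)  /  Σ_{f ∈ F(c)} depth(f, s)

where F(·) is the set of features carrying at least one retained hit.
The control is a universal single-copy marker, so its summed depth
estimates the total genome copies sequenced in *s*; the ratio is the
abundance-weighted average per-genome copy number of *q*. Two
assumptions matter: the control really is single-copy and universal in
the clades of interest (true of GrpE for bacteria to a good
approximation), and depth is proportional to abundance within a sample
(no strong GC/mappability bias differences between the features
compared).

### Counting rules

`per_feature` (default) counts each feature once, following the "sum
the depths of the features that contain the gene" definition.
`per_gene` lets a feature with *k* distinct hit genes contribute its
depth *k* times; this is the variant consistent with the copy-number
interpretation when a genome carries multiple copies on one feature.
The two agree whenever no feature carries more than one copy of the
same query — in particular on contig-level data where Prodigal rarely
calls duplicate orthologs per contig, and by construction in the
synthetic fixtures' default placement (at most one copy per contig).

### Stratification

Given MAG taxonomy at a chosen rank (default: phylum), numerators are
computed within each taxon's features. Features without a taxonomy
record fall into `Unclassified` rather than being dropped. With the
`global` denominator (default) the per-taxon scores sum exactly to the
unstratified score — the decomposition stacked "contribution" bar plots
need. `per_taxon` divides by the control depth within the same taxon,
giving a within-taxon copy number; these do not sum to the total.

### Undefined scores

A sample whose control depth is zero has no normalization basis; its
scores are marked undefined (NaN) with a warning — never coerced to 0
(which would claim absence) or infinity. Downstream consumers (tidy
export, plots, module annotation) exclude undefined cells and report
how many they dropped.

## Search and filtering

Searches reverse the usual annotation direction: the gene of interest
is the profile-HMM query, the sample's called genes are the target
database. The engine is pyhmmer's HMMER3 pipeline; results are a pure
function of (profile, targets, thresholds), so the two parallelism
levels — concurrent target files, worker threads per search — never
change the output. Hits are filtered on the full-sequence bit score
(default floor 25.0 bits, a conventional weak-homology cutoff; any
value may be set) and optionally on the full-sequence E-value; the
best-scoring record is kept per (gene, query, file). Raising the floor
can only shrink the hit set (monotonicity, property-tested).

Profiles can be built from a KEGG ortholog id: a pluggable fetcher
returns the family's protein sequences (the REST fetcher is the
production default; tests inject local fixtures), a pluggable aligner
produces the multiple alignment (default: MAFFT via subprocess), and
the profile is constructed from the alignment. The packaged control
profile is a *synthetic* GrpE-like family built by the fixtures module
so the whole pipeline runs offline; for biological use, point
`control_hmm(path=...)` at a real marker profile (e.g. GrpE derived
from GTDB marker alignments).

## Linking

Gene-to-feature association is a callable `(fasta_path, gene_id) →
feature_id`. Built-ins: MAG mode maps the FASTA filename (extension
stripped) to the MAG; contig mode strips the final Prodigal `_<ordinal>`
from the gene id, so contig names containing underscores survive.
Custom linkers slot in anywhere a built-in does. A hit whose feature is
absent from the depth table is an error naming the features — the
symptom of a mismatched linker or wrong depth file — not a silent drop.

## Depth import

MetaBAT/CoverM TSV dialects are recognized: `contigLen`,
`totalAvgDepth`, and `*-var` columns are dropped, and a trailing `.bam`
is stripped from sample names after the user's header rule runs.
Contig-mode imports concatenate one file per sample after the header
rule removes the file-specific column prefix; files whose post-rule
columns differ, or contig ids duplicated across files, are errors (a
merge policy for co-assembled overlapping ids is not well defined, so
we refuse rather than guess). An empty cell is an error, not zero:
silent zero-filling would bias the normalization denominator. Tables
are written with round-trip float formatting, so write → read is the
identity bit for bit.

## Module graphs

A module is a bipartite digraph of compounds and reactions; each
reaction carries the KO ids of its alternative enzymes. Annotation sets
reaction score = combine(per-KO mean over the selected samples), with
undefined cells excluded from the mean and KOs absent from the score
table contributing 0. The default combine is `sum`: alternative
enzymes add to the reaction's total gene dosage, which keeps the
reaction score consistent with summing the per-gene scores (`mean` and
`max` are options; the choice is a package default, not a universal
convention). The on-disk format is a three-record TSV (`C`/`R`/`E`
lines) rather than KGML or the KEGG MODULE boolean grammar — small
enough to write by hand and to keep module tests offline.

## Plots

Every plot writes the figure plus a TSV backing table with exactly the
plotted numbers; all numeric tests run against backing tables, never
pixels. Bar plots aggregate scores by sum (option: mean) over the
chosen x (and stacking fill) variable, conserving the total. Box plots
use per-sample scores grouped by a metadata column, with quartiles by
the median-exclusive (Tukey hinge) convention. Module plots color
reactions on a linear scale anchored at 0 — so absent functions look
alike across figures — with a grey sentinel for unset scores, and use a
deterministic layered (topological) layout.

## Synthetic communities

The fixtures generator is the test bed standing in for a real
assembly/binning workflow. It plants `n_genomes` genomes (default 50)
with log-normal abundances (log-mean 1.0, log-sd 0.7 — a right-skewed
community with a few dominant genomes, the shape typical of
environmental samples), split into `contigs_per_genome` contigs
(default 5). Copies of each query are placed on distinct contigs; the
control gene is placed exactly once per genome. Per-contig depth is
the genome abundance times (1 + noise_sd · N(0,1)), truncated at zero;
`noise_sd` is relative (0.05 = 5% depth noise). Both layouts are
emitted — one MAG-level table plus per-MAG FASTAs/search tables, and
per-sample MetaBAT-dialect contig tables with prefix-bearing column
names exercising the header rule. Search tables for the planted hits
are written directly (bit score 100, E-value 1e-30) so the
deterministic tier never depends on a live search; a separate helper
builds a real profile/target pair (diverged family vs shuffled decoys)
to exercise the search engine itself.

The planted truth is score(q,s) = Σ_g a_gs·k_gq / Σ_g a_gs with its
per-taxon decomposition. With zero noise the pipeline reproduces it
exactly (tolerance 1e-9); with 5% noise and 50 genomes, recovery within
0.05 absolute in ≥95% of replicates is the tested property. What the
generator does **not** emulate: read-level sampling noise, assembly
fragmentation and chimerism, binning error, incomplete or contaminated
MAGs, hit false positives/negatives from real homology search, and
compositional effects between samples. Passing these tests therefore
validates the arithmetic and plumbing of the method, not its robustness
to assembly or search artifacts.

## Numerical and design choices

- Scores and depths are float64 throughout; no rounding is applied on
  I/O (full-precision `repr` formatting).
- Deduplication of search hits keeps the maximum bit score per
  (gene, query, file); ties keep the first in stable sort order.
- Problem sizes in the test and acceptance runs (communities of 2–50
  genomes, 200 stochastic replicates, 1,000 parser lines) were chosen
  as the smallest sizes at which each property is informative.
- Seeds fix all randomness; community regeneration is byte-identical.

## Known limitations

- Copy-number interpretation degrades when the control marker is
  multi-copy or missing in a clade of interest; choose the control to
  match the domain(s) under study.
- No statistical testing across sample groups is provided; box plots
  are descriptive.
- The KEGG MODULE boolean definition grammar (enzyme complexes,
  AND/OR) is not parsed; module graphs must be supplied in the TSV
  format.
- DNA copy number is potential, not activity: high scores do not imply
  expression.
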