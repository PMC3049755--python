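# Methods

This note documents the models, rules and numerical choices behind
`lsgorigins`, and what the synthetic scenarios do and do not establish
about real data.

## Coordinate and sequence conventions

All internal coordinates are 0-based half-open on the forward strand; the
1-based inclusive conventions of GFF3 and 12-column tabular alignment
output are converted exactly once, at the I/O boundary (`lsgorigins.io`).
In hit tables, `sstart > send` encodes a minus-strand (inverted) hit;
internally subject coordinates are always stored plus-strand with an
orientation flag. A gene model keeps one representative isoform; when a
GFF3 carries several, the longest CDS wins with ties broken by
lexicographic model id. CDS sequences include the terminal stop codon; an
"intact ORF" means ATG start, terminal stop, no internal stop, length
divisible by 3. Printed percentages are rounded half-away-from-zero to two
decimals; spreads are semi-interquartile ranges, (Q3 − Q1)/2.

## LSG calling

A gene survives the cascade if **no** database tier holds a hit with
E-value below `lsg_evalue_cutoff` (default 1e-3) to a subject outside the
lineage taxon list, and no recognized cross-lineage protein domain is
annotated on it. Self-hits and hits to within-lineage subjects never
eliminate — lineage specificity is defined against sequences *outside* the
clade. The cascade is evaluated tier by tier so each non-LSG records its
eliminating tier; the survivor set is monotonically non-increasing in the
cutoff, which the sensitivity helper (`lsg_counts_by_cutoff`) exposes
directly. The domain filter consumes a precomputed flag table (gene →
carries-cross-lineage-domain) because running a domain scanner is outside
this package's scope.

Species-only status is a refinement: an LSG stays family-level only if the
outgroup peptide search has a hit with E < `within_genome_evalue`
(default 0.01) whose merged query coverage reaches
`min_query_coverage_pct` (default 10%). The two cutoffs differ
deliberately: the catalog cutoff (1e-3) controls the false-LSG rate against
large heterogeneous databases, while 0.01 is the standard within-genome /
outgroup search threshold. Both are configurable in `ThresholdConfig`
because the catalog cutoff is written ambiguously in the field's
shorthand ("10e-3"); we adopt the conventional reading 1e-3.

## HSP merging and coverage

All HSPs of one query–subject pair are concatenated by unioning their
query intervals; the pair is discarded when merged coverage falls strictly
below `min_query_coverage_pct`. Coverage counts alignment columns —
the query-interval union plus query-gap columns — over the query length,
so gapped alignments can exceed 100% (an insertion in the subject relative
to the query). Merged coverage equals a per-base brute-force union
whenever no gap columns are present; this is a test invariant.

## Origin classification

Evidence streams, in precedence order (configurable):

1. **Chimeric** — ≥ 2 evidence items (parent-gene hits, TE overlaps
   mapped into CDS space, CDS-overlap regions) occupying query regions
   that mutually overlap by at most 10% of the shorter region, with all
   contributing parent pairs mutually non-homologous (peptide E ≥ 0.01
   between parents). The 10% figure quantifies "non-overlapping" — the
   underlying rule gives no number, so the bound is explicit and
   configurable.
2. **Overprinting** — the LSG's CDS union intersects another model's CDS
   union by ≥ 1 bp on either strand. Only CDS counts (not introns/UTRs):
   lineage specificity is a peptide-level property.
3. **Duplication** — a merged peptide or CDS hit to a non-LSG. Hits to
   self, to other LSGs, and to overlapping gene models are removed first.
   Details: *in-frame* if a peptide-level pair exists; *out-of-frame* if
   CDS coverage strictly exceeds peptide coverage (absent peptide hit
   counts as zero); *inverted* if the dominant (most alignment columns)
   CDS HSP is minus-strand. Mechanism: *unequal crossing over* when an
   LSG splice boundary lies within `boundary_tolerance_bp` (5 bp,
   inclusive) of a subject boundary inside the aligned region (boundaries
   compared in alignment coordinates); *retrotransposition* when the
   alignment crosses ≥ 1 subject boundary while the corresponding LSG
   region is intron-free; otherwise indeterminate. Context: syntelog
   (from a supplied syntelog table, with a WGD flag from a supplied block
   table) beats tandem (same chromosome, ≤ `tandem_max_intervening_genes`
   = 10 genes apart — an explicit stand-in for a collinearity tool's
   local-duplicate call) beats distal.
4. **TE exaptation** — ≥ 1 bp overlap between a gene exon (default; CDS
   level selectable) and an annotated TE fragment. Tallies count distinct
   exapted fragments per superfamily split by LSG status; a gene exapting
   several superfamilies contributes one case per superfamily, and every
   percentage is printed with its denominator.
5. **Outgroup evidence** (species-only LSGs): out-of-frame CDS hits to
   outgroup gene models, else chained scaffold (intergenic) hits.
6. **Unknown.**

Exactly one primary mechanism is assigned per LSG and category counts
always sum to the LSG total (a hard invariant).

## Outgroup tracing

Scaffold hits below E = 0.01 are clustered on the top-scoring hit's
scaffold by transitive gaps ≤ `scaffold_chain_gap_bp` (4000 bp); the
selected region spans the extreme coordinates of the cluster containing
the top hit. The region (± a 60-bp margin so local-alignment end clipping
cannot push the start codon outside it) is aligned to the LSG CDS with an
affine-gap alignment, global in the CDS and local in the region (region
overhangs free). From the alignment:

- **frameshift indels** = internal gap runs with length ≢ 0 (mod 3);
- **internal stops** = stop codons in the region's aligned bases
  translated in the frame anchored at the LSG's codon boundaries — the
  frame therefore shifts through indels exactly as it would in the
  genome; the terminal stop codon never counts;
- **start**: `MSC` is only called when the alignment covers codon 1 and
  the aligned region codon is not ATG; when codon 1 is not covered the
  projection carries a `start_not_covered` flag and the category is
  computed from the covered portion. This is deliberate: an invisible
  start is not evidence of a missing one.

Categories follow the disruption inventory: `INTACT` (start ∧ no
disruption), `MSC` (no start ∧ no other disruption), `ISC_OR_INDEL`
(start ∧ disruption), `BOTH`. Projections under 10% coverage are
discarded; genes with an INTACT projection at ≥
`intact_orf_coverage_pct` (95%) are listed as candidate shared
un-annotated ORFs. The projection is deliberately unspliced: it replaces
a spliced gene-prediction model, is exact on intron-free regions (the
synthetic outgroup loci of species-only genes are intron-free by
construction), and is a declared limitation for real loci whose outgroup
orthologs retain introns.

Distant (non-family) genomes are scanned with reciprocal checks: a
qualifying transcript hit's top subject must top-hit the LSG back
(`distant_cds`), else a qualifying genomic hit's span ±
`distant_flank_bp` (100 bp, clamped to scaffold bounds) is extracted and
searched back (`distant_intergenic`).

**dN/dS** is Nei–Gojobori (1986): per-codon expected N/S sites (fractions
of single-base changes that are synonymous, changes to stops excluded and
renormalized) averaged over both sequences; observed differences in
multi-hit codons averaged over all orderings of single-step paths that
avoid stop codons (all orderings as fallback); Jukes–Cantor correction
−(3/4)·ln(1 − 4p/3), flagged saturated at p ≥ 3/4; ratio undefined at
dS = 0 except that a pair with zero nonsynonymous differences reports 0.
Ortholog pairs come from reciprocal best hits (ties: lower E, higher
score, lexicographic id). A codon-model maximum-likelihood estimator is
out of scope; the estimator hook is the single `compute_dnds` call site.

## Accession polymorphism

Only substitution SNPs are accepted (the call rule is defined for
substitutions; indel alleles raise). Per accession, the SNPs inside each
LSG CDS are applied strand-aware and the sequence translated; calls are
emitted only for disruptions absent from the reference: a new internal
stop (`ISC`; a stop arising in the terminal codon is not internal) or a
lost reference ATG (`MSC`). Undetermined alleles ('N') mark missing data
and never produce a call. Each call is cross-referenced against the
outgroup projection at the aligned site: `CONSERVED_SNP` (outgroup base
equals the disrupting allele), `DELETION` (gap), `NOT_COVERED`, else
`NOT_DISRUPTED`. Parsimony: a conserved disruption ⇒ *birth in the focal
lineage* (the intact allele is derived); an intact outgroup ORF with the
disruption confined to fewer than half of genotyped accessions ⇒ *loss in
the focal lineage*; anything else is ambiguous. The "< half" minority
threshold quantifies "present in only one or two accessions" without
hard-coding a panel size; it is configurable.

## Expression

Presence per (gene, tissue) is the OR over replicates (idempotent,
order-invariant; requires ≥ 2 replicates); breadth is the number of
present tissues. DE sets use adjusted p < `de_adj_p` (0.01) and |log2FC| >
`de_min_abs_log2fc` (log2 1.5 ≈ 0.585), read as a magnitude threshold
with the sign giving direction; up and down sets are disjoint by
construction. Raw-mode DE (two-sample t test + Benjamini–Hochberg) is an
explicit plain stand-in for a moderated model — real studies should
supply DE tables. Enrichment per contrast/tissue/time/direction is the
upper-tail hypergeometric probability computed in log space
(`scipy.stats.hypergeom.logsf`), flagged at `enrichment_p` (0.05), raw
p-values by default (no cross-contrast correction, matching the
single-contrast decision rule; a BH column can be added by the caller).

## The synthetic generator

`ScenarioConfig` defaults define the study conditions: 140 conserved
background genes (60–200 codons, 1–6 exons, ~40% single-exon so
duplication donors exist, 15% minus-strand) plus 60 planted events —
5 overprints, 8 in-frame / 6 frameshifted / 6 inverted duplicates,
5 retrocopies, 6 TE exaptations, 5 chimeras, 8 de novo genes (2 per
outgroup category), 4 differential losses, 4+3 accession ISC/MSC events —
on a ~250-kb nuclear chromosome with small mitochondrial and chloroplast
chromosomes, ~70 TE fragments across five superfamilies, a 5% diverged
outgroup, 19 accessions, and a 63-tissue × 3-replicate expression design
(breadth medians 4 vs 51, log2 shift 0.45, stress-contrast enrichment
odds 5). These sizes keep generation under ~2 s and a full pipeline run
near 10 s on one CPU while every planted class remains represented.

Construction notes:

- planted genes are inserted into intergenic gaps (all downstream
  coordinates shifted), anchored next to their donor for tandem copies or
  ≥ 15 genes away for distal ones;
- overprints are engineered by rewriting a donor CDS until a reverse-
  strand window holds an intact ORF while the donor frame stays intact,
  then annotating the window as a minus-strand gene;
- frameshifted/inverted duplicates are "repaired" into valid ORFs by
  minimal single-base edits of the stop codons that the new frame
  exposes, keeping nucleotide identity to the donor high;
- the outgroup is the focal genome mutated at the configured per-site
  divergence: CDS sites via ORF-preserving substitutions targeted at a
  planted dN/dS (ω = 0.15 for conserved genes, 0.6 for LSG-like genes,
  with expected N/S sites computed by the same NG86 site counting the
  estimator uses), dual-coding overprint loci site-wise with both frames
  checked, everything else freely; species-only loci then receive their
  planted disruption (start loss, internal stop, 1-bp deletion, both, or
  whole-locus deletion), and outgroup gene models (CDS sequences) are
  emitted only for genes meant to be annotated in the outgroup;
- background SNPs are synonymous or intergenic by construction, so only
  the planted accession events can disrupt an ORF — which is what makes
  "zero false calls" a meaningful recovery criterion;
- homology-tier tables are constructed directly (conserved genes carry an
  out-of-lineage hit in exactly one tier; a few genes are eliminated only
  at later tiers or only by the domain flag; planted LSGs get
  within-lineage decoy hits that must not eliminate them), because the
  cascade — not the search engine — is the computation under test there.

What passing synthetic tests does **not** show: realistic base
composition or TE sequence models, spliced outgroup orthologs (the
projection is unspliced), indel polymorphisms, probe-level expression
artifacts, or database-scale homology search behaviour. The generator
validates the rules and their composition, not database snapshots.

## The search stand-in

`toy_search` is an exact affine-gap Smith–Waterman (match +2 / mismatch
−3, gap open 5 / extend 2 for DNA; BLOSUM62 with 11/1 for peptides)
iterated with query masking to recover multiple HSPs, searching both
strands in nucleotide mode. E-values use the Karlin–Altschul form
K·m·n·e^(−λS) with λ = 0.625, K = 0.2 for the DNA scheme (λ solves
Σ pᵢpⱼ e^(λsᵢⱼ) = 1 at uniform composition; K is an order-of-magnitude
constant) and the standard gapped BLOSUM62 constants λ = 0.267,
K = 0.041 — adequate for thresholding at the decision cutoffs, not for
database-calibrated statistics. With `seed_word_size` set, pairs sharing
no exact word are skipped and long subjects are scanned in windows around
seed clusters; the pipeline uses words of 11 (DNA) and 4 (peptide), both
far below the divergence levels at which the planted homologies could be
missed. Unseeded mode is exact and is verified against an independent
quadratic Gotoh DP in the tests.

## Numerical and degenerate-input choices

- Hypergeometric tails in log space; k = 0 short-circuits to 1.
- Empty groups report missing values (never 0) in every summary.
- Duplicate-gap alignments can place a 1-bp gap anywhere within a run of
  identical bases; the outgroup DELETION status is therefore exact only
  up to that alignment ambiguity.
- Chain clustering is single-linkage and provably input-order
  independent (hits are sorted before clustering).
- All randomness flows from one `numpy` `SeedSequence` root; child
  generators are spawned in a fixed order, so scenario output is
  byte-identical across runs and platforms.

## Known limitations

- No spliced alignment in ORF projection (see above).
- NG86 with Jukes–Cantor only; no ML codon models, no transition /
  transversion weighting.
- The taxon label on every hit-table subject is required input; the
  package does not resolve taxonomy itself.
- Real-data LSG catalogs depend on database snapshots; the in-print
  arithmetic and statistics are reproducible (see
  `scripts/acceptance.py`), the genome-wide counts are not.
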