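# Methods

This note documents the models, conventions and numerical choices behind
`fgi-typer`, what the synthetic-data generator does and does not emulate,
and the known limitations of both.

## Island model and coordinates

The flagellin glycosylation island is defined as the intergenic span between
the flagellin gene *flaA2* and *flaG*, `[end(flaA2), start(flaG))` in
0-based half-open coordinates (GenBank/GFF3 I/O converts from their 1-based
inclusive conventions). The anchor CDSs themselves are **excluded** so that
the conserved flagellin and *flaG* genes never dilute the island's
compositional signal. A CDS belongs to the island only when fully contained
in the interval; partial overlaps are excluded so CDS counts are
reproducible. A zero-length intergap is a valid (empty) island with a null
G+C.

G+C content is (G+C)/(A+C+G+T), case-insensitive, with IUPAC ambiguity
codes excluded from numerator and denominator — draft-assembly N-runs
therefore cannot bias the deviation. The signed deviation is
ΔGC = GC_island − GC_genome in percentage points; the genome value is taken
over the concatenation of all contigs. Table rows carry values rounded to
two decimals (sizes to one), and the reader enforces the
deviation-consistency invariant to ±0.02 to absorb that rounding.

## Anchoring

Anchor hits use the annotation criterion (below) against bundled reference
proteins. When several flagellin paralogs qualify as *flaA2* (the *flaA1* /
*flaA3* copies are real homologs), the qualifying copy nearest to *flaG* on
its 5' side is chosen; when the inner anchors are ambiguous the search is
narrowed to the window spanned by the outer locus anchors *comFA* and
*raiA*. Strains without a qualifying pair on a single contig are excluded
from a cohort run (with the best near-miss scores reported) rather than
aborting the whole analysis — the draft-genome reality.

## Alignment, identity, coverage

Pairwise protein comparison is a global Needleman–Wunsch/Gotoh alignment
under BLOSUM62 with affine gaps costing `open + k·extend` for a gap of
length k (open 11, extend 1 — protein-BLAST's defaults), end gaps
penalized, and `X` scoring 0 against everything. Traceback ties resolve
diagonal > up > left, so the alignment is a deterministic function of its
inputs; the test suite checks score and identity against exhaustive
enumeration over all global alignments of short peptides.

- **identity** = matching columns / all alignment columns × 100 (BLAST-like;
  the denominator is *not* the shorter sequence).
- **coverage of a sequence** = residue-to-residue aligned columns / its
  length × 100. (Defining coverage as "non-gap columns of the sequence /
  its length" would be identically 100% in a global alignment; the aligned
  -span definition is the quantity the 70%-of-protein-length criterion
  actually needs, and reduces to the familiar fragment-span fraction when a
  fragment is aligned to a full-length protein.)

Two criteria use these statistics:

- **annotation** (island CDS vs. labeled reference set): identity > 50% and
  coverage of the **reference** ≥ 70%. Coverage over the reference length is
  one of three defensible readings of "70% of the protein length"; it is the
  choice here because it makes fragment behaviour predictable (a 75%
  fragment keeps its label, a 40% truncation does not). Best hit = highest
  identity, ties broken by more aligned columns, then lexicographic
  reference name.
- **orthology** (island CDSs across strains): identity > 70% and
  min(coverage_a, coverage_b) ≥ 70%. Identity thresholds are strict
  inequalities.

An optional k-mer prescreen (shared distinct 4-mers ≥ max(2, 1% of the
shorter length); pairs shorter than 40 residues always pass) skips full
alignment for pairs that cannot plausibly reach ~50% identity. For randomly
diverged sequences near either criterion the expected shared-4-mer count is
an order of magnitude above the bar, so the filter is effectively lossless
there; it can be disabled (`Thresholds(prescreen=False)`) for adversarial
inputs such as regularly spaced substitutions.

## Status call and typing

A strain is **FGI⁺** iff at least one island CDS is labeled
glycosyltransferase or maf. A transposon-disrupted glycosyltransferase
still counts toward status (the emitted 5' fragment retains ≥ 70% reference
coverage and so keeps its label), while it scores 0 in the typing matrix —
mirroring how a disrupted *rmlB* leaves a strain typeable and positive.

Ortholog families are single-linkage connected components over the
qualifying-pair graph (the simplest rule consistent with per-pair orthology
assumptions); family identifiers are ordered by first-seen strain and gene,
with strains pre-sorted by identifier, so output is independent of input
order. Presence/absence cells: 1 iff the strain has ≥ 1 member that is not
transposon-disrupted and whose length is ≥ 50% of the family's median
member length ("truncated" otherwise); provenance (present / truncated /
disrupted / absent) is kept per cell. Disruption in real-data mode is
inferred when an adjacent island CDS is transposase-labeled and the member
is < 90% of its family median; in synthetic data the generator's truth
flags provide an independent check.

One consequence of single-linkage at the 70/70 criterion: a gene truncated
below half length cannot reach 70% identity over the alignment columns of
its full-length relatives, so hard-truncated genes typically appear as
singleton families (scored present for their own strain) rather than as
in-family members scored 0. The in-family truncation rule still takes
effect for moderate shortenings such as disruption fragments. This adds a
few one-strain columns of typing noise per cohort and is measured, not
hidden, by the end-to-end recovery suite.

Profiles are compared with Pearson's *r* on the binary vectors,
similarity = 100·*r* and distance = 100 − similarity (the "absolute values
with Pearson correlation" convention of commercial typing software is not
publicly specified; this interpretation is deterministic and config-
visible). Zero-variance profiles get similarity 100 if identical, else 0.
UPGMA merges the minimal-average-distance pair (size-weighted update;
merge height = d/2; ties broken by lowest index pair with merged clusters
appended last; children ordered by smallest descendant leaf for a canonical
tree). Types are the maximal subtrees whose internal merges all occur at
similarity ≥ the cutoff (50% by default, i.e. height ≤ 25), labeled with
Roman numerals by decreasing size, ties by lexicographically first strain.
Cutting the dendrogram is the primary definition; it coincides with
thresholded-graph components only for ultrametric similarity structure.

## Flagellin profiling

Flagellin-like CDSs (hits to any flagellin class reference under the
annotation criterion, on the locus contig) are classified positionally:
the island's 5' anchor is *flaA2*; the nearest qualifying copy upstream is
*flaA1*; a copy downstream of *flaA2* is *flaA3*; leftovers fall back to
the highest-identity class reference. The multiple alignment is a
deterministic center-star construction (center = maximal summed pairwise
identity; "once a gap, always a gap") — adequate for column-conservation
statistics, not a substitute for a production MSA; externally produced
aligned FASTA is accepted wherever an alignment is consumed. Per-column
conservation is the modal non-gap residue count over the number of
sequences (gaps count as mismatches in the denominator; a gap-excluded
variant would be a one-line change and is deliberately not the default so
that indel-rich columns read as unconserved).

## Synthetic cohorts: what they emulate

`GeneratorConfig` defaults are the study conditions used throughout the
tests: host G+C 0.52 and typed-island G+C 0.38 (the compositional structure
of published thermophile cohorts), five island types × 3 strains plus five
island-negative strains, within-family substitution divergence 0.05,
truncation probability 0.03 and disruption probability 0.02 per island gene
(matching the observed rarity of truncated and transposon-split genes —
roughly 8 truncations and one disruption across ~290 island genes in the
cohort the fixture table describes). Island-negative strains receive 0–6
filler genes (homing endonucleases, macro-domain protein, hypotheticals) at
G+C 0.45, emulating the shallower deviation of negative intergenic spans.

The five default type profiles (10–12 families each from a 45-family pool)
mirror the pathway logic of real islands: neuraminic-acid genes for type I;
a pseudaminic-acid core shared by types II and III; a pen/pal variant of
that pathway plus *glf* for type IV; rhamnose genes for type V; each with
its own glycosyltransferases and maf/modification genes. Shared families
(5 *pse* genes between II and III, 4 + *glf* between III/IV and II/IV, one
*fdt* gene between II and V) keep profiles realistic while leaving
between-type Pearson similarity well below the 50% cutoff, as the published
type separation shows.

Island G+C is controlled by weighting synonymous codons by
exp(β·GC(codon)), with β solved once per target by bisection for a
composition-uniform protein (the generated proteins are composition-uniform
by construction); genes are expectation-matched, not exact. Realized mean
island G+C across a cohort lands within ~0.1 percentage point of the
target. Protein divergence is uniform random substitution without indels,
so pairwise identity ≈ (1−d)² is analytically predictable; an indel mode is
reserved but off by default. Flagellins are built from conserved 60-residue
termini around class-specific centers (heavily substituted and
length-jittered for *flaA1*/*flaA2*, near-constant for *flaA3*), which
produces the terminal-conservation pattern the profiling stage is meant to
detect. *flaA3*, when present, is placed 3' of *flaG* (the "within or 3' of
the island" position), keeping the inner-anchor rule unambiguous.

Genomes are locus-scale — a 200 kb host-composition backbone around the
flagellar locus — because every measured quantity is locus-relative and the
genome mean converges quickly; a full-size chromosome would only shrink the
island's share of the genome mean by a further fraction of a percentage
point. Everything is deterministic per seed, including the GenBank output
(fixed file date).

What the generator does **not** emulate: assembly fragmentation (each
genome is one contig; multi-contig islands in real drafts need the
user-declared contig order supported by the I/O layer), gene order
rearrangement within islands, codon-usage structure beyond the G+C target,
homologous recombination between family members, annotation errors, and
real flagellin phylogeny. Passing the end-to-end suites therefore shows the
pipeline's logic is sound under controlled divergence and composition — it
does not certify recovery rates on real draft genomes, where anchor decay,
mis-annotation and split contigs dominate the error budget.

## Numerical and degenerate-input choices

- Translation uses the bacterial code (table 11), stop stripped; a CDS
  whose translation has an internal stop is kept with an empty protein and
  a warning.
- Alignment scores are integers; identity/coverage are exact ratios, so
  threshold comparisons are not float-sensitive.
- The dendrogram cut height carries a +1e-9 tolerance so merges at exactly
  the cutoff similarity stay inside one type.
- An empty island ⇒ null G+C and null deviation, never 0.
- A cohort with no FGI⁺ strains skips typing (0 types); a single FGI⁺
  strain is labeled type I by convention without a dendrogram.
- Strain order never affects results: strains are sorted before clustering,
  and family/type labels have deterministic tie-breaks.

## Known limitations

- The published per-cohort values that depend on real assemblies or a
  live protein database (total distinct island CDSs, real flagellin
  identity percentages, glycosyltransferase counts) are out of reach
  without those inputs; the package reproduces the table-derived aggregates
  and validates everything else on synthetic truth.
- The fixture table's printed FGI⁺ mean island G+C (40.33) is inconsistent
  with the mean of its own island-G+C column (40.03); `summarize` reports
  the recomputed value.
- Center-star MSA quality degrades for deep divergence (< ~40% identity);
  conservation profiles remain usable because the conserved termini anchor
  the alignment, but indel placement in the variable center is approximate.
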