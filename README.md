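# fgi-typer

Detection and typing of **flagellin glycosylation islands (FGIs)** in
annotated bacterial genomes.

Many bacteria decorate flagellin — the structural subunit of the flagellar
filament — with O-linked glycans. The genes responsible (glycosyltransferases,
*maf* motility-associated factors, and sugar biosynthesis pathways such as
pseudaminic acid, neuraminic acid and rhamnose) typically sit in a compact
genomic island inside the flagellar biosynthetic locus, between the flagellin
gene *flaA2* and *flaG*. These islands are horizontally acquired: their G+C
content is markedly depressed relative to the genome mean, and their gene
content varies sharply even between close relatives.

`fgi-typer` is for comparative genomicists who want to reproduce this style
of analysis on a cohort of genomes:

1. **Locate** the flagellar locus via anchor proteins (*comFA*/*raiA* outer,
   *flaA2*/*flaG* inner) and excise the intergenic island
   `[end(flaA2), start(flaG))`.
2. **Measure** island size, CDS count, island G+C% and the signed deviation
   ΔGC = GC<sub>island</sub> − GC<sub>genome</sub>.
3. **Classify** each strain FGI⁺/FGI⁻: positive iff the island encodes a
   glycosyltransferase or a Maf protein (annotation by global protein
   alignment against a labeled reference set, identity > 50% over ≥ 70% of
   the reference length).
4. **Type** the FGI⁺ islands: ortholog families are single-linkage components
   over pairs with identity > 70% and mutual coverage ≥ 70%; strains become
   binary presence/absence profiles (truncated or transposon-disrupted genes
   scored 0); profiles are compared with Pearson's *r* (similarity = 100·*r*),
   clustered by UPGMA on distance 100 − similarity, and the dendrogram is cut
   at 50% similarity. Each resulting cluster is one island type (I, II, …).
5. **Profile flagellins**: classify *flaA1*/*flaA2*/*flaA3* paralogs around
   the locus, compute average pairwise identities, length ranges and
   per-column conservation of a center-star multiple alignment.

A synthetic-genome generator (`fgi_typer.synthetic`) builds full annotated
cohorts with known ground truth — implanted islands at a controlled G+C,
type-specific gene complements, tunable protein divergence, gene truncation
and transposon disruption — so the entire pipeline is testable without any
sequence downloads. A 36-strain table of published per-strain island metrics
ships with the package as a CSV fixture.

## Worked example

```python
from fgi_typer import GeneratorConfig, generate_cohort, run_pipeline

cohort = generate_cohort(GeneratorConfig(seed=42))      # 5 types x 3 + 5 FGI-
result = run_pipeline(cohort.genomes, cohort.anchors, cohort.reference_db)
print(result.summary.report())
```

prints

```
strains analysed: 20 (15 FGI+, 5 FGI-)
island types: 5 (I: 3, II: 3, III: 3, IV: 3, V: 3)
FGI+: mean island G+C 38.04%, mean |deviation| 13.21%, size 10.6-13.7 kb, CDS 10-13
FGI-: mean island G+C 43.15%, mean |deviation| 8.73%, size 0.1-5.2 kb, CDS 0-5
```

All 15 typed strains cluster back into the 5 generated types (adjusted Rand
index 1.0), every island's status is recovered, and the typed islands'
realized G+C sits at the configured 38% against a 52% host — the
compositional signature of horizontal acquisition.

The packaged fixture reproduces the published cohort's aggregates:

```bash
fgi-typer summarize
```

```
strains analysed: 36 (18 FGI+, 18 FGI-)
island types: 5 (I: 3, II: 3, III: 2, IV: 8, V: 2)
FGI+: mean island G+C 40.03%, mean |deviation| 10.32%, size 13.4-30.4 kb, CDS 11-23
FGI-: mean island G+C 44.73%, mean |deviation| 5.18%, size 0.9-6.9 kb, CDS 0-6
```

i.e. half the cohort is FGI⁺, FGI⁺ islands average 10.32 percentage points of
G+C below their genomes (FGI⁻ intergenic spans only 5.18), and the islands
fall into five types with Type IV the largest (8 strains).

The CLI also exposes `fgi-typer simulate` (write a synthetic cohort as
GenBank + truth JSON), `fgi-typer run` (full pipeline over a genome
directory) and `fgi-typer flagellins` (paralog classification and
conservation profiles).

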