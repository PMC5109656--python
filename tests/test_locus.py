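"""Anchor finding, island excision, annotation and FGI status calls."""

import numpy as np
import pytest

from fgi_typer import (
    AnchorsNotFoundError,
    MalformedLocusError,
    ValidationError,
    annotate_island,
    classify_island,
    extract_island,
    find_anchors,
)
from fgi_typer.genome_io import GeneFeature, Genome
from fgi_typer.locus import (
    FGI_MINUS,
    FGI_PLUS,
    AnchorSet,
    IslandRecord,
    ReferenceDB,
    ReferenceProtein,
    Thresholds,
)
from fgi_typer.synthetic import mutate_protein, random_protein, reverse_translate


class TestThresholds:
    def test_defaults_match_orthology_criteria(self):
        t = Thresholds()
        assert (t.annot_id_pct, t.annot_cov_pct) == (50.0, 70.0)
        assert (t.ortho_id_pct, t.ortho_cov_pct) == (70.0, 70.0)
        assert t.type_cutoff_pct == 50.0
        assert t.truncation_frac == 0.5

    @pytest.mark.parametrize("bad", [{"annot_id_pct": 0}, {"annot_cov_pct": 101},
                                     {"truncation_frac": 1.0}])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            Thresholds(**bad)


class TestFindAnchors:
    def test_recovers_implanted_anchor_pair(self, default_cohort):
        for genome in default_cohort.genomes[:6]:
            truth = default_cohort.truth.strains[genome.strain_id]
            flaA2, flaG = find_anchors(genome, default_cohort.anchors)
            assert flaA2.end == truth.island_start
            assert flaG.start == truth.island_end
            island = extract_island(genome, flaA2, flaG)
            assert (island.start, island.end) == (truth.island_start, truth.island_end)

    def test_anchors_found_despite_20pct_divergence(self, small_cohort):
        rng = np.random.default_rng(99)
        genome = small_cohort.genomes[0]
        truth = small_cohort.truth.strains[genome.strain_id]
        mutated_feats = []
        for f in genome.features:
            if f.gene_name in ("flaA2", "flaG"):
                f = GeneFeature(f.feature_id, f.contig_id, f.start, f.end, f.strand,
                                f.gene_name, f.product,
                                mutate_protein(f.protein_seq, 0.2, rng))
            mutated_feats.append(f)
        mutated = Genome(genome.strain_id, dict(genome.contigs), mutated_feats)
        flaA2, flaG = find_anchors(mutated, small_cohort.anchors)
        assert (flaA2.end, flaG.start) == (truth.island_start, truth.island_end)

    def test_missing_flaG_raises_with_near_misses(self, small_cohort):
        genome = small_cohort.genomes[0]
        kept = [f for f in genome.features if f.gene_name != "flaG"]
        broken = Genome(genome.strain_id, dict(genome.contigs), kept)
        with pytest.raises(AnchorsNotFoundError) as exc:
            find_anchors(broken, small_cohort.anchors)
        assert isinstance(exc.value.near_misses, list)

    def test_island_disjoint_from_anchor_intervals(self, default_cohort):
        genome = default_cohort.genomes[0]
        flaA2, flaG = find_anchors(genome, default_cohort.anchors)
        island = extract_island(genome, flaA2, flaG)
        assert island.start >= flaA2.end
        assert island.end <= flaG.start


class TestExtractIsland:
    def _mini_genome(self, gap_nt: int):
        rng = np.random.default_rng(1)
        protA = random_protein(rng, 60)
        protG = random_protein(rng, 50)
        ntA = reverse_translate(protA, 0.5, rng)
        ntG = reverse_translate(protG, 0.5, rng)
        gap = "AT" * (gap_nt // 2)
        contig = ntA + gap + ntG
        feats = [
            GeneFeature("a2", "c1", 0, len(ntA), "+", "flaA2", "", protA),
            GeneFeature("fg", "c1", len(ntA) + len(gap), len(contig), "+", "flaG", "", protG),
        ]
        return Genome("mini", {"c1": contig}, feats)

    def test_zero_length_intergap_permitted(self):
        g = self._mini_genome(0)
        a2, fg = g.features
        island = extract_island(g, a2, fg)
        assert island.n_cds == 0
        assert island.size_kb == 0.0
        assert island.island_gc_pct is None
        assert island.gc_deviation_pct is None

    def test_interval_and_gc(self):
        g = self._mini_genome(1000)
        a2, fg = g.features
        island = extract_island(g, a2, fg)
        assert (island.start, island.end) == (a2.end, fg.start)
        assert island.island_gc_pct == pytest.approx(0.0)  # AT-only gap
        assert island.gc_deviation_pct == pytest.approx(-g.genome_gc_pct, abs=1e-9)

    def test_misordered_anchors_rejected(self):
        g = self._mini_genome(300)
        a2, fg = g.features
        with pytest.raises(MalformedLocusError):
            extract_island(g, fg, a2)

    def test_synthetic_island_size_and_cds_count(self, default_cohort, default_pipeline):
        for strain, island in default_pipeline.islands.items():
            truth = default_cohort.truth.strains[strain]
            expected_cds = len(truth.families) + sum(
                1 for s in truth.gene_states.values() if s == "disrupted"
            )
            assert island.n_cds == expected_cds
            assert island.size_kb == pytest.approx(
                (truth.island_end - truth.island_start) / 1000.0
            )

    def test_deviation_consistent_before_rounding(self, default_pipeline):
        for island in default_pipeline.islands.values():
            if island.island_gc_pct is None:
                continue
            assert island.gc_deviation_pct == pytest.approx(
                island.island_gc_pct - island.genome_gc_pct, abs=1e-6
            )


class TestAnnotateIsland:
    def _island_with(self, proteins: dict[str, str]) -> IslandRecord:
        feats = []
        pos = 0
        for fid, prot in proteins.items():
            ln = 3 * (len(prot) + 1)
            feats.append(GeneFeature(fid, "c1", pos, pos + ln, "+", "", "", prot))
            pos += ln + 50
        return IslandRecord("s", "c1", 0, pos, 40.0, 50.0, feats)

    def test_best_hit_labels_and_thresholds(self):
        rng = np.random.default_rng(8)
        maf4 = random_protein(rng, 200)
        gt = random_protein(rng, 220)
        refdb = ReferenceDB([
            ReferenceProtein("maf4", "maf", maf4),
            ReferenceProtein("gtr1", "glycosyltransferase", gt),
        ])
        far = mutate_protein(maf4, 0.6, rng)        # ~40% identity: below 50
        half = mutate_protein(maf4, 0.05, rng)[:100]  # 60%+ identity, 50% coverage
        island = self._island_with({
            "exact": maf4, "decoy": far, "fragment": half,
        })
        ann = annotate_island(island, refdb)
        assert ann["exact"] == "maf"
        assert ann["decoy"] == "hypothetical"
        assert ann["fragment"] == "hypothetical"

    def test_empty_reference_db_rejected(self):
        from fgi_typer.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            ReferenceDB([])

    def test_unknown_label_rejected(self):
        from fgi_typer.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            ReferenceDB([ReferenceProtein("x", "mystery", "MKLV")])


class TestClassifyIsland:
    def _island(self, labels: dict[str, str]) -> IslandRecord:
        isl = IslandRecord("s", "c1", 0, 100, 40.0, 50.0, [])
        isl.annotations = labels
        return isl

    def test_glycosyltransferase_is_positive(self):
        assert classify_island(self._island({"g1": "glycosyltransferase"})) == FGI_PLUS

    def test_maf_alone_is_positive(self):
        assert classify_island(self._island({"g1": "maf", "g2": "hypothetical"})) == FGI_PLUS

    def test_endonuclease_and_hypothetical_are_negative(self):
        labels = {"g1": "endonuclease", "g2": "hypothetical", "g3": "biosynthesis:pse"}
        assert classify_island(self._island(labels)) == FGI_MINUS
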