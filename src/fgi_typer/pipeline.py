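"""Cohort orchestration: run every stage, aggregate per-strain metrics.

`run_pipeline` drives read → anchor → excise → annotate → classify →
ortholog clustering (island-positive strains only) → presence/absence →
Pearson similarity → UPGMA → type assignment, and `summarize` computes the
per-status aggregates (mean island G+C, mean absolute G+C deviation, size
and CDS ranges, per-type counts) from the per-strain table rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .errors import AnchorsNotFoundError, FgiTyperError, MalformedLocusError, ValidationError
from .genome_io import Genome, IslandTableRow, read_genome, write_table
from .island_typing import (
    TypingResult,
    assign_types,
    pearson_similarity,
    upgma,
    write_newick,
)
from .locus import (
    DEFAULT_THRESHOLDS,
    FGI_PLUS,
    AnchorSet,
    IslandRecord,
    ReferenceDB,
    Thresholds,
    annotate_island,
    classify_island,
    disrupted_features,
    extract_island,
    find_anchors,
)
from .orthology import OrthologFamily, PresenceAbsenceMatrix, cluster_orthologs, score_matrix

log = logging.getLogger(__name__)


def _round2(x: float | None) -> float | None:
    return None if x is None else round(x, 2)


@dataclass
class GroupAggregates:
    """Aggregates over one status group (island-positive or -negative)."""

    n: int
    mean_island_gc_pct: float | None
    mean_abs_deviation_pct: float | None
    size_range_kb: tuple[float, float] | None
    cds_range: tuple[int, int] | None


@dataclass
class CohortSummary:
    rows: list[IslandTableRow]
    fgi_plus: GroupAggregates
    fgi_minus: GroupAggregates
    type_counts: dict[str, int]

    @property
    def n_fgi_plus(self) -> int:
        return self.fgi_plus.n

    @property
    def n_fgi_minus(self) -> int:
        return self.fgi_minus.n

    @property
    def n_types(self) -> int:
        return len(self.type_counts)

    def report(self) -> str:
        lines = [
            f"strains analysed: {len(self.rows)} "
            f"({self.n_fgi_plus} FGI+, {self.n_fgi_minus} FGI-)",
            f"island types: {self.n_types} "
            + (
                "(" + ", ".join(f"{t}: {c}" for t, c in sorted(self.type_counts.items())) + ")"
                if self.type_counts
                else ""
            ),
        ]
        for name, grp in (("FGI+", self.fgi_plus), ("FGI-", self.fgi_minus)):
            if grp.n == 0:
                lines.append(f"{name}: no strains")
                continue
            size = grp.size_range_kb
            cds = grp.cds_range
            lines.append(
                f"{name}: mean island G+C {grp.mean_island_gc_pct}%, "
                f"mean |deviation| {grp.mean_abs_deviation_pct}%, "
                f"size {size[0]}-{size[1]} kb, CDS {cds[0]}-{cds[1]}"
            )
        return "\n".join(lines)


def _aggregate(rows: list[IslandTableRow]) -> GroupAggregates:
    if not rows:
        return GroupAggregates(0, None, None, None, None)
    gc = [r.island_gc_pct for r in rows if r.island_gc_pct is not None]
    dev = [abs(r.gc_deviation_pct) for r in rows if r.gc_deviation_pct is not None]
    return GroupAggregates(
        n=len(rows),
        mean_island_gc_pct=_round2(sum(gc) / len(gc)) if gc else None,
        mean_abs_deviation_pct=_round2(sum(dev) / len(dev)) if dev else None,
        size_range_kb=(
            round(min(r.size_kb for r in rows), 1),
            round(max(r.size_kb for r in rows), 1),
        ),
        cds_range=(min(r.n_cds for r in rows), max(r.n_cds for r in rows)),
    )


def summarize(rows: list[IslandTableRow]) -> CohortSummary:
    """Aggregate per-strain island metrics by FGI status.

    Strains with a typed island form the positive group; the mean absolute
    G+C deviation is the arithmetic mean of per-strain |island − genome|
    percentages. Results are rounded to two decimals (sizes to one).
    """
    if not rows:
        raise ValidationError("summarize requires at least one row")
    plus = [r for r in rows if r.is_fgi_plus]
    minus = [r for r in rows if not r.is_fgi_plus]
    type_counts: dict[str, int] = {}
    for r in plus:
        type_counts[r.fgi_type] = type_counts.get(r.fgi_type, 0) + 1
    return CohortSummary(
        rows=list(rows),
        fgi_plus=_aggregate(plus),
        fgi_minus=_aggregate(minus),
        type_counts=type_counts,
    )


@dataclass
class PipelineResult:
    summary: CohortSummary
    islands: dict[str, IslandRecord]
    families: list[OrthologFamily]
    matrix: PresenceAbsenceMatrix | None
    typing: TypingResult | None
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def type_of(self) -> dict[str, str]:
        return self.typing.type_of if self.typing else {}


def _compute_disrupted(islands, families):
    """(strain, feature_id) pairs flagged transposon-disrupted, using family
    median lengths and transposase adjacency inside each island."""
    med_by_feature: dict[str, dict[str, float]] = {}
    for fam in families:
        med = fam.median_length()
        for strain, members in fam.members.items():
            for m in members:
                med_by_feature.setdefault(strain, {})[m.feature_id] = med
    out = set()
    for strain, island in islands.items():
        if strain not in med_by_feature:
            continue
        for fid in disrupted_features(island, med_by_feature[strain]):
            out.add((strain, fid))
    return out


def run_pipeline(
    genomes: list[Genome] | list[str | Path],
    anchors: AnchorSet,
    reference_db: ReferenceDB,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    out_dir: str | Path | None = None,
    isolation_sources: dict[str, str] | None = None,
    genome_format: str = "genbank",
) -> PipelineResult:
    """Run the full island detection and typing pipeline on a cohort.

    ``genomes`` may be Genome objects or paths. Strains whose locus anchors
    cannot be found are excluded with a warning and listed in
    ``result.failures``. Typing runs only when at least two island-positive
    strains exist; with exactly one, that strain is labeled type I by
    convention. Artifacts (tables, matrix, similarity, tree, typing) are
    written under ``out_dir`` when given.
    """
    if len(genomes) < 2:
        raise ValidationError("run_pipeline requires at least two genomes")
    loaded: list[Genome] = []
    for g in genomes:
        if isinstance(g, Genome):
            loaded.append(g)
        else:
            loaded.append(read_genome(g, format=genome_format))
    isolation_sources = isolation_sources or {}

    islands: dict[str, IslandRecord] = {}
    failures: dict[str, str] = {}
    for genome in loaded:
        try:
            flaA2, flaG = find_anchors(genome, anchors, thresholds)
            island = extract_island(genome, flaA2, flaG)
            annotate_island(island, reference_db, thresholds)
            classify_island(island)
            islands[genome.strain_id] = island
        except (AnchorsNotFoundError, MalformedLocusError) as exc:
            log.warning("%s excluded: %s", genome.strain_id, exc)
            failures[genome.strain_id] = str(exc)
    log.info("islands extracted: %d of %d strains", len(islands), len(loaded))

    plus_strains = sorted(s for s, isl in islands.items() if isl.fgi_status == FGI_PLUS)
    families: list[OrthologFamily] = []
    matrix = None
    typing = None
    if plus_strains:
        proteins = {
            s: [(f.feature_id, f.protein_seq) for f in islands[s].cds if f.protein_seq]
            for s in plus_strains
        }
        families = cluster_orthologs(
            proteins,
            id_thresh=thresholds.ortho_id_pct,
            cov_thresh=thresholds.ortho_cov_pct,
            prescreen=thresholds.prescreen,
        )
        log.info("ortholog families: %d across %d FGI+ strains",
                 len(families), len(plus_strains))
        disrupted = _compute_disrupted(islands, families)
        matrix = score_matrix(families, plus_strains, thresholds.truncation_frac, disrupted)
    type_of: dict[str, str] = {}
    if len(plus_strains) >= 2:
        sim = pearson_similarity(matrix)
        tree = upgma(sim)
        typing = assign_types(tree, thresholds.type_cutoff_pct, matrix=sim)
        type_of = typing.type_of
        log.info("types at %.0f%% cutoff: %d", thresholds.type_cutoff_pct, typing.n_types)
    elif len(plus_strains) == 1:
        type_of = {plus_strains[0]: "I"}
        log.info("single FGI+ strain; labeled type I without a dendrogram")

    rows = [
        islands[s].to_table_row(
            fgi_type=type_of.get(s),
            isolation_source=isolation_sources.get(s, ""),
        )
        for s in sorted(islands)
    ]
    summary = summarize(rows) if rows else CohortSummary(
        [], _aggregate([]), _aggregate([]), {}
    )
    result = PipelineResult(summary, islands, families, matrix, typing, failures)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(rows, out / "island_metrics.csv")
        if matrix is not None:
            matrix.write_csv(out / "presence_absence.csv")
            matrix.write_long_tsv(out / "presence_absence_long.tsv")
        if typing is not None:
            typing.matrix.write_csv(out / "similarity.csv")
            write_newick(typing.tree, out / "upgma_tree.nwk")
            typing.write_tsv(out / "typing.tsv")
        _write_gene_order(islands, out / "gene_order.tsv")
        (out / "summary.txt").write_text(summary.report() + "\n", encoding="utf-8")
        if failures:
            (out / "excluded_strains.tsv").write_text(
                "strain_id\treason\n"
                + "".join(f"{s}\t{r}\n" for s, r in sorted(failures.items())),
                encoding="utf-8",
            )
    return result


def _write_gene_order(islands: dict[str, IslandRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("strain_id\tfeature_id\tstart\tend\tstrand\tlabel\n")
        for strain in sorted(islands):
            isl = islands[strain]
            for f in sorted(isl.cds, key=lambda f: f.start):
                label = isl.annotations.get(f.feature_id, "")
                fh.write(f"{strain}\t{f.feature_id}\t{f.start}\t{f.end}\t{f.strand}\t{label}\n")


def load_fixture_summary() -> CohortSummary:
    """Summary of the packaged 36-strain island-metrics table."""
    from .genome_io import load_island_table

    return summarize(load_island_table())
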