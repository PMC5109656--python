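"""Flagellar-locus anchoring, island excision and functional annotation.

The glycosylation island is the intergenic span between the flagellin gene
flaA2 and the downstream flaG. Anchors are found by aligning reference
proteins against every CDS under the annotation criterion (identity > 50%
over >= 70% of the reference length); when several flagellin paralogs
qualify as flaA2, the qualifying copy nearest to flaG on its 5' side wins,
with the outer comFA/raiA anchors narrowing the search window when they are
present. The island excludes both anchor genes so they never contribute to
island G+C.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment import DEFAULT_SCORING, align_global, may_share_identity
from .errors import (
    AnchorsNotFoundError,
    ConfigurationError,
    MalformedLocusError,
    ValidationError,
)
from .genome_io import GeneFeature, Genome, IslandTableRow, gc_content, read_fasta

log = logging.getLogger(__name__)

FGI_PLUS = "FGI+"
FGI_MINUS = "FGI-"

#: labels whose presence on an island CDS makes the strain FGI-positive
STATUS_LABELS = frozenset({"glycosyltransferase", "maf"})

KNOWN_LABEL_PREFIXES = (
    "glycosyltransferase",
    "maf",
    "flagellin",
    "biosynthesis:",
    "modification:",
    "endonuclease",
    "transposase",
    "hypothetical",
)


@dataclass(frozen=True)
class Thresholds:
    """Identity/coverage criteria and clustering cutoffs, in percent.

    annot_* is the reference-annotation criterion (vs. a labeled protein
    set), ortho_* the within-cohort orthology criterion, type_cutoff_pct the
    dendrogram similarity cutoff, truncation_frac the intact-length fraction.
    """

    annot_id_pct: float = 50.0
    annot_cov_pct: float = 70.0
    ortho_id_pct: float = 70.0
    ortho_cov_pct: float = 70.0
    type_cutoff_pct: float = 50.0
    truncation_frac: float = 0.5
    prescreen: bool = True

    def __post_init__(self):
        for name in ("annot_id_pct", "annot_cov_pct", "ortho_id_pct",
                     "ortho_cov_pct", "type_cutoff_pct"):
            v = getattr(self, name)
            if not (0.0 < v <= 100.0):
                raise ValidationError(f"{name}={v} outside (0, 100]")
        if not (0.0 < self.truncation_frac < 1.0):
            raise ValidationError("truncation_frac must lie in (0, 1)")


DEFAULT_THRESHOLDS = Thresholds()


@dataclass
class AnchorSet:
    """Reference proteins anchoring the flagellar locus.

    flaA2/flaG are the inner anchors delimiting the island; comFA/raiA the
    outer anchors of the whole flagellar biosynthetic locus, used as a
    fallback search window when flagellin paralogs make the inner anchors
    ambiguous.
    """

    flaA2: str
    flaG: str
    comFA: str
    raiA: str
    #: optional per-class flagellin references for paralog classification
    flagellin_refs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("flaA2", "flaG", "comFA", "raiA"):
            if not getattr(self, name):
                raise ValidationError(f"anchor {name} has an empty sequence")

    @classmethod
    def from_fasta(cls, path) -> "AnchorSet":
        seqs = {}
        extras = {}
        for header, seq in read_fasta(path):
            name = header.split("|")[0].split()[0]
            if name in ("flaA2", "flaG", "comFA", "raiA"):
                seqs[name] = seq
            else:
                extras[name] = seq
        missing = {"flaA2", "flaG", "comFA", "raiA"} - set(seqs)
        if missing:
            raise ValidationError(f"anchor FASTA missing {sorted(missing)}")
        return cls(**seqs, flagellin_refs=extras)

    def to_items(self) -> list[tuple[str, str]]:
        items = [
            ("flaA2", self.flaA2),
            ("flaG", self.flaG),
            ("comFA", self.comFA),
            ("raiA", self.raiA),
        ]
        items.extend(sorted(self.flagellin_refs.items()))
        return items


@dataclass
class ReferenceProtein:
    name: str
    label: str
    seq: str


class ReferenceDB:
    """Labeled reference proteins for island annotation (``>name|label``)."""

    def __init__(self, entries: list[ReferenceProtein]):
        if not entries:
            raise ConfigurationError("reference DB is empty")
        for e in entries:
            if not e.label.startswith(KNOWN_LABEL_PREFIXES):
                raise ConfigurationError(
                    f"reference {e.name}: unknown label {e.label!r}"
                )
        self.entries = sorted(entries, key=lambda e: e.name)

    @classmethod
    def from_fasta(cls, path) -> "ReferenceDB":
        entries = []
        for header, seq in read_fasta(path):
            token = header.split()[0]
            if "|" not in token:
                raise ConfigurationError(
                    f"reference header {header!r} lacks '|label' syntax"
                )
            name, label = token.split("|", 1)
            entries.append(ReferenceProtein(name, label, seq))
        return cls(entries)

    def write_fasta(self, path) -> None:
        from .genome_io import write_fasta

        write_fasta([(f"{e.name}|{e.label}", e.seq) for e in self.entries], path)


def _annotation_hit(query: str, ref: str, thresholds: Thresholds, scoring,
                    query_kmers=None, ref_kmers=None):
    """Alignment if the query hits the reference under the annotation
    criterion (identity > annot_id over >= annot_cov of the reference);
    None otherwise."""
    cov_frac = thresholds.annot_cov_pct / 100.0
    if len(query) < cov_frac * len(ref):
        return None  # exact: reference coverage can never be reached
    if thresholds.prescreen and not may_share_identity(query, ref, query_kmers, ref_kmers):
        return None
    res = align_global(query, ref, scoring)
    if res.identity_pct > thresholds.annot_id_pct and res.coverage_b_pct >= thresholds.annot_cov_pct:
        return res
    return None


def _anchor_candidates(genome: Genome, ref_seq: str, thresholds: Thresholds, scoring):
    """All CDSs hitting one anchor reference; list of (feature, result)."""
    from .alignment import kmer_set

    ref_kmers = kmer_set(ref_seq)
    hits = []
    near_misses = []
    for feat in genome.cds_features():
        res = _annotation_hit(feat.protein_seq, ref_seq, thresholds, scoring,
                              ref_kmers=ref_kmers)
        if res is not None:
            hits.append((feat, res))
        else:
            near_misses.append(feat)
    return hits, near_misses


def _best_near_miss(genome: Genome, ref_name: str, ref_seq: str, scoring, top: int = 3):
    """Best-scoring non-qualifying candidates, for error reporting."""
    scored = []
    for feat in genome.cds_features():
        if not feat.protein_seq or not may_share_identity(feat.protein_seq, ref_seq):
            continue
        res = align_global(feat.protein_seq, ref_seq, scoring)
        scored.append((feat.feature_id, ref_name, round(res.identity_pct, 2),
                       round(res.coverage_b_pct, 2)))
    scored.sort(key=lambda t: -t[2])
    return scored[:top]


def find_anchors(
    genome: Genome,
    anchors: AnchorSet,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    scoring=DEFAULT_SCORING,
) -> tuple[GeneFeature, GeneFeature]:
    """Locate the flaA2/flaG CDS pair delimiting the island.

    Raises :class:`AnchorsNotFoundError` (with best near-miss scores) when no
    qualifying pair exists on a single contig, :class:`MalformedLocusError`
    when the anchors overlap.
    """
    fla_hits, _ = _anchor_candidates(genome, anchors.flaA2, thresholds, scoring)
    flg_hits, _ = _anchor_candidates(genome, anchors.flaG, thresholds, scoring)

    if len(flg_hits) > 1 or len(fla_hits) > 2:
        # ambiguous locus: narrow to the comFA..raiA window when available
        com_hits, _ = _anchor_candidates(genome, anchors.comFA, thresholds, scoring)
        rai_hits, _ = _anchor_candidates(genome, anchors.raiA, thresholds, scoring)
        if com_hits and rai_hits:
            windows = {}
            for cf, _ in com_hits:
                for rf, _ in rai_hits:
                    if cf.contig_id == rf.contig_id:
                        lo = min(cf.start, rf.start)
                        hi = max(cf.end, rf.end)
                        prev = windows.get(cf.contig_id)
                        windows[cf.contig_id] = (
                            (min(prev[0], lo), max(prev[1], hi)) if prev else (lo, hi)
                        )
            if windows:
                def in_window(f):
                    w = windows.get(f.contig_id)
                    return w is not None and f.start >= w[0] and f.end <= w[1]

                fla_w = [(f, r) for f, r in fla_hits if in_window(f)]
                flg_w = [(f, r) for f, r in flg_hits if in_window(f)]
                if fla_w and flg_w:
                    fla_hits, flg_hits = fla_w, flg_w

    best_pair = None
    for flg_feat, flg_res in sorted(flg_hits, key=lambda t: (-t[1].identity_pct, t[0].start)):
        upstream = [
            (f, r) for f, r in fla_hits
            if f.contig_id == flg_feat.contig_id
            and f.end <= flg_feat.start
            and f is not flg_feat
        ]
        if upstream:
            # nearest qualifying flagellin on the 5' side of flaG
            fla_feat = max(upstream, key=lambda t: t[0].end)[0]
            best_pair = (fla_feat, flg_feat)
            break
        overlapping = [
            f for f, _ in fla_hits
            if f.contig_id == flg_feat.contig_id and f.end > flg_feat.start
            and f.start < flg_feat.end and f is not flg_feat
        ]
        if overlapping:
            raise MalformedLocusError(
                f"{genome.strain_id}: flaA2 candidate {overlapping[0].feature_id} "
                f"overlaps flaG {flg_feat.feature_id}"
            )
    if best_pair is None:
        misses = []
        if not fla_hits:
            misses += _best_near_miss(genome, "flaA2", anchors.flaA2, scoring)
        if not flg_hits:
            misses += _best_near_miss(genome, "flaG", anchors.flaG, scoring)
        raise AnchorsNotFoundError(
            f"{genome.strain_id}: no qualifying flaA2/flaG pair on a single contig "
            f"(flaA2 hits: {len(fla_hits)}, flaG hits: {len(flg_hits)})",
            near_misses=misses,
        )
    return best_pair


@dataclass
class IslandRecord:
    """Per-strain island: interval, composition, contents and status."""

    strain_id: str
    contig_id: str
    start: int
    end: int
    island_gc_pct: float | None
    genome_gc_pct: float
    cds: list[GeneFeature]
    fgi_status: str | None = None
    annotations: dict[str, str] = field(default_factory=dict)

    @property
    def size_kb(self) -> float:
        return (self.end - self.start) / 1000.0

    @property
    def n_cds(self) -> int:
        return len(self.cds)

    @property
    def gc_deviation_pct(self) -> float | None:
        if self.island_gc_pct is None:
            return None
        return self.island_gc_pct - self.genome_gc_pct

    def to_table_row(self, fgi_type: str | None, isolation_source: str = "") -> IslandTableRow:
        return IslandTableRow(
            strain_id=self.strain_id,
            isolation_source=isolation_source,
            fgi_type=fgi_type,
            genome_gc_pct=round(self.genome_gc_pct, 2),
            island_gc_pct=None if self.island_gc_pct is None else round(self.island_gc_pct, 2),
            gc_deviation_pct=None if self.gc_deviation_pct is None
            else round(self.island_gc_pct, 2) - round(self.genome_gc_pct, 2),
            size_kb=round(self.size_kb, 1),
            n_cds=self.n_cds,
        )


def extract_island(genome: Genome, flaA2: GeneFeature, flaG: GeneFeature) -> IslandRecord:
    """Excise the intergenic island [flaA2.end, flaG.start).

    A zero-length intergap is permitted: the record then has no CDSs and a
    null island G+C. Raises :class:`MalformedLocusError` when flaA2 ends
    after flaG starts.
    """
    if flaA2.contig_id != flaG.contig_id:
        raise MalformedLocusError(
            f"{genome.strain_id}: anchors on different contigs"
        )
    if flaA2.end > flaG.start:
        raise MalformedLocusError(
            f"{genome.strain_id}: flaA2 ends at {flaA2.end} after flaG start {flaG.start}"
        )
    start, end = flaA2.end, flaG.start
    seq = genome.contigs[flaA2.contig_id][start:end]
    island_gc = None
    if seq:
        try:
            island_gc = gc_content(seq) * 100.0
        except Exception:
            island_gc = None
    cds = [
        f for f in genome.cds_features()
        if f.contig_id == flaA2.contig_id and f.start >= start and f.end <= end
    ]
    return IslandRecord(
        strain_id=genome.strain_id,
        contig_id=flaA2.contig_id,
        start=start,
        end=end,
        island_gc_pct=island_gc,
        genome_gc_pct=genome.genome_gc_pct,
        cds=cds,
    )


def annotate_island(
    island: IslandRecord,
    reference_db: ReferenceDB,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    scoring=DEFAULT_SCORING,
) -> dict[str, str]:
    """Label each island CDS from its best qualifying reference hit.

    Qualification is identity > annot_id_pct over >= annot_cov_pct of the
    reference protein's length. Best hit = highest identity, ties broken by
    longer aligned length then lexicographic reference name. CDSs without a
    qualifying hit are labeled ``hypothetical``.
    """
    from .alignment import kmer_set

    ref_kmers = {ref.name: kmer_set(ref.seq) for ref in reference_db.entries}
    annotations: dict[str, str] = {}
    for feat in island.cds:
        best = None  # (neg identity, neg aligned cols, ref name, label)
        if feat.protein_seq:
            q_kmers = kmer_set(feat.protein_seq)
            for ref in reference_db.entries:
                res = _annotation_hit(feat.protein_seq, ref.seq, thresholds, scoring,
                                      query_kmers=q_kmers, ref_kmers=ref_kmers[ref.name])
                if res is None:
                    continue
                key = (-res.identity_pct, -res.n_columns, ref.name)
                if best is None or key < best[0]:
                    best = (key, ref.label)
        annotations[feat.feature_id] = best[1] if best else "hypothetical"
    island.annotations = annotations
    return annotations


def classify_island(island: IslandRecord) -> str:
    """FGI+ iff any island CDS carries a glycosyltransferase or maf label.

    A transposon-disrupted glycosyltransferase fragment keeps its label and
    still counts toward positive status.
    """
    labels = set(island.annotations.values())
    island.fgi_status = FGI_PLUS if labels & STATUS_LABELS else FGI_MINUS
    return island.fgi_status


def disrupted_features(island: IslandRecord, family_median: dict[str, float]) -> set[str]:
    """Feature ids considered transposon-disrupted.

    Rule: an island CDS is disrupted when an adjacent island CDS carries the
    transposase label and the CDS is shorter than 90% of its ortholog
    family's median length (``family_median`` maps feature_id → median).
    """
    ordered = sorted(island.cds, key=lambda f: f.start)
    out = set()
    for idx, feat in enumerate(ordered):
        med = family_median.get(feat.feature_id)
        if med is None or len(feat.protein_seq) >= 0.9 * med:
            continue
        neighbors = []
        if idx > 0:
            neighbors.append(ordered[idx - 1])
        if idx + 1 < len(ordered):
            neighbors.append(ordered[idx + 1])
        if any(island.annotations.get(nb.feature_id) == "transposase" for nb in neighbors):
            out.add(feat.feature_id)
    return out
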