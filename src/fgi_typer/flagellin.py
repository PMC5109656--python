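"""Flagellin paralog classification and conservation profiling.

Flagellins carry highly conserved N- and C-termini around a variable,
surface-exposed central region; the per-column conservation profile of an
alignment makes that pattern visible. Paralogs around the glycosylation
island are classified positionally: flaA2 sits at the island's 5' boundary,
flaA1 upstream of it, flaA3 within or 3' of the island.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .alignment import DEFAULT_SCORING, align_global
from .errors import ValidationError
from .genome_io import Genome
from .locus import AnchorSet, Thresholds, DEFAULT_THRESHOLDS, _annotation_hit, find_anchors

log = logging.getLogger(__name__)

GENE_CLASSES = ("flaA1", "flaA2", "flaA3")


@dataclass
class FlagellinSet:
    """Flagellins of one paralog class across a cohort."""

    gene_class: str
    members: dict[str, str] = field(default_factory=dict)  # strain_id -> protein

    @property
    def length_range(self) -> tuple[int, int]:
        lengths = [len(s) for s in self.members.values()]
        return (min(lengths), max(lengths)) if lengths else (0, 0)

    def average_pairwise_identity_pct(self, scoring=DEFAULT_SCORING) -> float:
        return average_pairwise_identity(list(self.members.values()), scoring)


def average_pairwise_identity(proteins: list[str], scoring=DEFAULT_SCORING) -> float:
    """Mean global-alignment identity over all unordered pairs, in percent."""
    if len(proteins) < 2:
        raise ValidationError("average_pairwise_identity requires >= 2 proteins")
    total = 0.0
    n_pairs = 0
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            total += align_global(proteins[i], proteins[j], scoring).identity_pct
            n_pairs += 1
    return total / n_pairs


def classify_flagellins(
    genomes: list[Genome],
    anchors: AnchorSet,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    scoring=DEFAULT_SCORING,
) -> dict[str, FlagellinSet]:
    """Assign flagellin CDSs around each strain's locus to paralog classes.

    Flagellin-like CDSs are those hitting the flaA2 reference under the
    annotation criterion. Per strain: the island's 5' anchor is flaA2, the
    nearest qualifying copy upstream of it is flaA1, any copy downstream of
    flaA2 (within or 3' of the island) is flaA3. Leftover copies fall back
    to the highest-identity class reference when per-class references are
    available. Strains without a detectable locus are skipped with a warning.
    """
    sets = {gc: FlagellinSet(gc) for gc in GENE_CLASSES}
    for genome in genomes:
        try:
            flaA2_feat, flaG_feat = find_anchors(genome, anchors, thresholds, scoring)
        except Exception as exc:
            log.warning("%s: flagellin classification skipped (%s)", genome.strain_id, exc)
            continue
        refs = {"flaA2": anchors.flaA2, **anchors.flagellin_refs}
        candidates = []
        for feat in genome.cds_features():
            if feat.contig_id != flaA2_feat.contig_id:
                continue
            if any(
                _annotation_hit(feat.protein_seq, ref, thresholds, scoring)
                for ref in refs.values()
            ):
                candidates.append(feat)
        if not candidates:
            log.warning("%s: no flagellin-like CDS found", genome.strain_id)
            continue
        sets["flaA2"].members[genome.strain_id] = flaA2_feat.protein_seq
        upstream = [f for f in candidates if f.end <= flaA2_feat.start]
        downstream = [f for f in candidates if f.start >= flaA2_feat.end]
        if upstream:
            fla1 = max(upstream, key=lambda f: f.end)
            sets["flaA1"].members[genome.strain_id] = fla1.protein_seq
            upstream = [f for f in upstream if f is not fla1]
        if downstream:
            fla3 = min(downstream, key=lambda f: f.start)
            sets["flaA3"].members[genome.strain_id] = fla3.protein_seq
            downstream = [f for f in downstream if f is not fla3]
        # any remaining copies: highest-identity class reference fallback
        for feat in upstream + downstream:
            best_class, best_id = None, -1.0
            for cls, ref in anchors.flagellin_refs.items():
                if cls not in GENE_CLASSES:
                    continue
                res = align_global(feat.protein_seq, ref, scoring)
                if res.identity_pct > best_id:
                    best_class, best_id = cls, res.identity_pct
            if best_class and genome.strain_id not in sets[best_class].members:
                sets[best_class].members[genome.strain_id] = feat.protein_seq
    return sets


def build_msa(proteins: list[tuple[str, str]], scoring=DEFAULT_SCORING) -> list[tuple[str, str]]:
    """Center-star progressive multiple alignment.

    The center is the sequence maximizing summed pairwise identity to all
    others (ties: first in input order); every other sequence is merged into
    the growing alignment through its pairwise global alignment with the
    center, with "once a gap, always a gap" semantics. Returns (name, gapped
    sequence) pairs in the input order.
    """
    if len(proteins) < 2:
        raise ValidationError("build_msa requires >= 2 sequences")
    names = [n for n, _ in proteins]
    seqs = [s for _, s in proteins]
    n = len(seqs)
    pairwise = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            ident = align_global(seqs[i], seqs[j], scoring).identity_pct
            pairwise[i][j] = pairwise[j][i] = ident
    center = max(range(n), key=lambda i: (sum(pairwise[i]), -i))

    center_seq = seqs[center]
    # master gap pattern of the center; rows stored aligned to that pattern
    master_center = center_seq
    rows: dict[int, str] = {center: center_seq}
    for idx in range(n):
        if idx == center:
            continue
        res = align_global(seqs[idx], center_seq, scoring)
        new_other, new_center = res.aligned_a, res.aligned_b
        # merge new_center's gap pattern with master_center's
        merged_other = []
        merged_master = []
        i = j = 0
        while i < len(master_center) or j < len(new_center):
            mc = master_center[i] if i < len(master_center) else None
            nc = new_center[j] if j < len(new_center) else None
            if mc is not None and nc is not None and mc != "-" and nc != "-":
                merged_master.append(mc)
                merged_other.append(new_other[j])
                i += 1
                j += 1
            elif mc == "-" and nc == "-":
                merged_master.append("-")
                merged_other.append(new_other[j])
                i += 1
                j += 1
            elif mc == "-":
                merged_master.append("-")
                merged_other.append("-")
                i += 1
            else:  # nc == '-' (insertion relative to the master)
                merged_master.append("-")
                merged_other.append(new_other[j])
                # open the same column in all previously merged rows
                for key in rows:
                    rows[key] = rows[key][: len(merged_master) - 1] + "-" + rows[key][len(merged_master) - 1:]
                j += 1
        master_center = "".join(merged_master)
        # pad pre-existing rows if the master grew at the end
        for key in rows:
            rows[key] = rows[key].ljust(len(master_center), "-")
        rows[idx] = "".join(merged_other).ljust(len(master_center), "-")
    width = len(master_center)
    return [(names[i], rows[i].ljust(width, "-")) for i in range(n)]


@dataclass
class ConservationProfile:
    """Per-column conservation of an alignment, in percent."""

    alignment: list[tuple[str, str]]
    conservation_pct: list[float]

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("column\tconservation_pct\n")
            for i, v in enumerate(self.conservation_pct, start=1):
                fh.write(f"{i}\t{v:.2f}\n")


def conservation_profile(alignment: list[tuple[str, str]]) -> ConservationProfile:
    """Fraction of sequences carrying the modal non-gap residue per column.

    Gaps count in the denominator (a gapped sequence is a mismatch at that
    column), matching how conservation bars under an alignment are usually
    drawn. Raises on ragged input.
    """
    if len(alignment) < 2:
        raise ValidationError("conservation_profile requires >= 2 sequences")
    seqs = [s for _, s in alignment]
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValidationError("ragged alignment: sequences differ in length")
    n = len(seqs)
    profile = []
    for col in range(width):
        counts = Counter(s[col] for s in seqs if s[col] != "-")
        modal = counts.most_common(1)[0][1] if counts else 0
        profile.append(100.0 * modal / n)
    return ConservationProfile(alignment, profile)
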