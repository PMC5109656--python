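"""Genome, feature and table I/O plus shared sequence utilities.

Internal coordinates are 0-based half-open throughout; GenBank and GFF3
readers convert from their native 1-based inclusive conventions on the way
in. CDS translations use the bacterial code (NCBI table 11) with the stop
codon stripped.
"""

from __future__ import annotations

import csv
import logging
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import FormatError, UndefinedContentError, ValidationError

log = logging.getLogger(__name__)

FGI_TYPES = ("I", "II", "III", "IV", "V")

_ROMAN_RE = re.compile(r"^M*(CM|CD|D?C{0,3})(XC|XL|L?X{0,3})(IX|IV|V?I{0,3})$")


def _is_roman(label: str) -> bool:
    return bool(label) and bool(_ROMAN_RE.match(label))

#: tolerance for Table-1-style rounding of the deviation column (percentage points)
DEVIATION_TOLERANCE = 0.02

TABLE_HEADER = [
    "strain_id",
    "isolation_source",
    "fgi_type",
    "genome_gc_pct",
    "island_gc_pct",
    "gc_deviation_pct",
    "size_kb",
    "n_cds",
]

_GC_BASES = frozenset("GCgc")
_UNAMBIGUOUS = frozenset("ACGTacgt")


def gc_content(seq: str) -> float:
    """Fraction (G+C)/(A+C+G+T) of ``seq``, case-insensitive.

    IUPAC ambiguity codes (N, R, Y, ...) and gap characters are excluded from
    both numerator and denominator, so draft-assembly padding cannot bias the
    value. Raises :class:`UndefinedContentError` when no unambiguous base is
    present.
    """
    if not seq:
        raise UndefinedContentError("G+C content of an empty sequence is undefined")
    gc = seq.count("G") + seq.count("C") + seq.count("g") + seq.count("c")
    total = gc + seq.count("A") + seq.count("T") + seq.count("a") + seq.count("t")
    if total == 0:
        raise UndefinedContentError(
            "G+C content undefined: no unambiguous A/C/G/T bases in sequence"
        )
    return gc / total


@dataclass
class GeneFeature:
    """A single annotated feature (usually a CDS) on a contig."""

    feature_id: str
    contig_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'
    gene_name: str = ""
    product: str = ""
    protein_seq: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"feature {self.feature_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise ValidationError(f"feature {self.feature_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_cds(self) -> bool:
        return bool(self.protein_seq)


@dataclass
class Genome:
    """A (possibly draft) genome: contigs plus ordered annotated features."""

    strain_id: str
    contigs: dict[str, str]
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        if not self.strain_id:
            raise ValidationError("strain_id must be non-empty")
        for f in self.features:
            if f.contig_id not in self.contigs:
                raise ValidationError(
                    f"feature {f.feature_id} references unknown contig {f.contig_id}"
                )
            if f.end > len(self.contigs[f.contig_id]):
                raise ValidationError(
                    f"feature {f.feature_id} extends past the end of {f.contig_id}"
                )
        self.features.sort(key=lambda f: (f.contig_id, f.start))
        self._gc_pct: float | None = None

    @property
    def genome_gc_pct(self) -> float:
        """Whole-genome G+C percentage over the concatenation of all contigs."""
        if self._gc_pct is None:
            self._gc_pct = gc_content("".join(self.contigs.values())) * 100.0
        return self._gc_pct

    def cds_features(self) -> list[GeneFeature]:
        return [f for f in self.features if f.is_cds]

    def feature_seq(self, feat: GeneFeature) -> str:
        """Nucleotide sequence of a feature, reverse-complemented for '-' strand."""
        s = self.contigs[feat.contig_id][feat.start:feat.end]
        if feat.strand == "-":
            s = str(Seq(s).reverse_complement())
        return s


def _translate_cds(nt_seq: str, feature_id: str) -> str:
    """Translate a CDS with the bacterial code; empty string on internal stops."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aa = str(Seq(nt_seq).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        log.warning("feature %s: internal stop on translation; protein left empty", feature_id)
        return ""
    return aa


def _genome_from_genbank(path: Path, strain_id: str | None) -> Genome:
    contigs: dict[str, str] = {}
    features: list[GeneFeature] = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises plain ValueError on bad records
        raise FormatError(f"{path}: cannot parse as GenBank: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no GenBank records found")
    organism = None
    for rec in records:
        contigs[rec.id] = str(rec.seq).upper()
        organism = organism or rec.annotations.get("organism")
        n_anon = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            start = int(feat.location.start)
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            quals = feat.qualifiers
            fid = (quals.get("locus_tag") or quals.get("protein_id") or [""])[0]
            if not fid:
                n_anon += 1
                fid = f"{rec.id}_cds{n_anon}"
            protein = (quals.get("translation") or [""])[0]
            if not protein:
                nt = str(rec.seq[start:end])
                if strand == "-":
                    nt = str(Seq(nt).reverse_complement())
                protein = _translate_cds(nt, fid)
            features.append(
                GeneFeature(
                    feature_id=fid,
                    contig_id=rec.id,
                    start=start,
                    end=end,
                    strand=strand,
                    gene_name=(quals.get("gene") or [""])[0],
                    product=(quals.get("product") or [""])[0],
                    protein_seq=protein,
                )
            )
    return Genome(strain_id or organism or records[0].id, contigs, features)


def _genome_from_fasta_gff3(fasta_path: Path, gff3_path: Path, strain_id: str | None) -> Genome:
    import gffutils

    try:
        contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    except Exception as exc:
        raise FormatError(f"{fasta_path}: cannot parse as FASTA: {exc}") from exc
    if not contigs:
        raise FormatError(f"{fasta_path}: no FASTA records found")
    try:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:
        raise FormatError(f"{gff3_path}: cannot parse as GFF3: {exc}") from exc
    features = []
    n_anon = 0
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        if feat.seqid not in contigs:
            raise FormatError(f"{gff3_path}: CDS on unknown contig {feat.seqid}")
        start, end = feat.start - 1, feat.end  # GFF3 is 1-based inclusive
        strand = "-" if feat.strand == "-" else "+"
        fid = feat.attributes.get("ID", [""])[0]
        if not fid:
            n_anon += 1
            fid = f"{feat.seqid}_cds{n_anon}"
        nt = contigs[feat.seqid][start:end]
        if strand == "-":
            nt = str(Seq(nt).reverse_complement())
        features.append(
            GeneFeature(
                feature_id=fid,
                contig_id=feat.seqid,
                start=start,
                end=end,
                strand=strand,
                gene_name=feat.attributes.get("gene", [""])[0],
                product=feat.attributes.get("product", [""])[0],
                protein_seq=_translate_cds(nt, fid),
            )
        )
    return Genome(strain_id or fasta_path.stem, contigs, features)


def read_genome(path, format: str = "genbank", gff3_path=None, strain_id: str | None = None) -> Genome:
    """Read an annotated genome from a GenBank flat file or a FASTA+GFF3 pair.

    Features are returned sorted by (contig_id, start) with ``protein_seq``
    populated for every CDS (from the annotation's translation when present,
    otherwise translated with NCBI table 11). A CDS whose translation hits an
    internal stop is kept with an empty protein and a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if format == "genbank":
        return _genome_from_genbank(path, strain_id)
    if format == "fasta+gff3":
        if gff3_path is None:
            raise FormatError("fasta+gff3 format requires gff3_path")
        return _genome_from_fasta_gff3(path, Path(gff3_path), strain_id)
    raise FormatError(f"unknown genome format {format!r}")


@dataclass
class IslandTableRow:
    """One per-strain row of island metrics (the published-table analogue)."""

    strain_id: str
    isolation_source: str
    fgi_type: str | None  # None = no typed island; otherwise 'I'..'V'
    genome_gc_pct: float
    island_gc_pct: float | None
    gc_deviation_pct: float | None
    size_kb: float
    n_cds: int

    def __post_init__(self):
        if self.fgi_type is not None and not _is_roman(self.fgi_type):
            raise ValidationError(f"{self.strain_id}: unknown FGI type {self.fgi_type!r}")
        if self.size_kb <= 0:
            raise ValidationError(f"{self.strain_id}: size_kb must be positive")
        if self.n_cds < 0:
            raise ValidationError(f"{self.strain_id}: n_cds must be non-negative")
        if self.island_gc_pct is not None and self.gc_deviation_pct is not None:
            expected = self.island_gc_pct - self.genome_gc_pct
            if abs(self.gc_deviation_pct - expected) > DEVIATION_TOLERANCE:
                raise ValidationError(
                    f"{self.strain_id}: gc_deviation_pct {self.gc_deviation_pct} does not "
                    f"match island-genome difference {expected:.2f}"
                )

    @property
    def is_fgi_plus(self) -> bool:
        return self.fgi_type is not None


def _parse_optional_float(text: str) -> float | None:
    text = text.strip()
    return None if text in ("", "NA", "nan") else float(text)


def load_island_table(path=None) -> list[IslandTableRow]:
    """Load per-strain island metrics from CSV.

    With no argument the packaged 36-strain fixture is loaded. The
    ``fgi_type`` column uses ``-`` (or empty) for strains without a typed
    island. Rows violating the deviation invariant raise
    :class:`ValidationError` naming the strain.
    """
    if path is None:
        source = resources.files("fgi_typer").joinpath("data/island_metrics.csv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    reader = csv.DictReader(text.splitlines())
    if reader.fieldnames != TABLE_HEADER:
        raise FormatError(
            f"island table header {reader.fieldnames} does not match {TABLE_HEADER}"
        )
    rows = []
    for rec in reader:
        ftype = rec["fgi_type"].strip()
        rows.append(
            IslandTableRow(
                strain_id=rec["strain_id"],
                isolation_source=rec["isolation_source"],
                fgi_type=None if ftype in ("-", "") else ftype,
                genome_gc_pct=float(rec["genome_gc_pct"]),
                island_gc_pct=_parse_optional_float(rec["island_gc_pct"]),
                gc_deviation_pct=_parse_optional_float(rec["gc_deviation_pct"]),
                size_kb=float(rec["size_kb"]),
                n_cds=int(rec["n_cds"]),
            )
        )
    return rows


def write_table(rows: list[IslandTableRow], path) -> None:
    """Write island metric rows as CSV (round-trips through load_island_table)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(TABLE_HEADER)
        for r in rows:
            writer.writerow(
                [
                    r.strain_id,
                    r.isolation_source,
                    r.fgi_type or "-",
                    f"{r.genome_gc_pct:.2f}",
                    "" if r.island_gc_pct is None else f"{r.island_gc_pct:.2f}",
                    "" if r.gc_deviation_pct is None else f"{r.gc_deviation_pct:.2f}",
                    f"{r.size_kb:.1f}",
                    r.n_cds,
                ]
            )


def write_fasta(proteins: dict[str, str] | list[tuple[str, str]], path, width: int = 70) -> None:
    """Write protein sequences to FASTA; empty sequences are skipped with a warning."""
    items = proteins.items() if isinstance(proteins, dict) else proteins
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in items:
            if not seq:
                log.warning("write_fasta: skipping empty sequence %s", name)
                continue
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file as (header, sequence) pairs (full header line kept)."""
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            out.append((rec.description, str(rec.seq)))
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as FASTA: {exc}") from exc
    return out
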