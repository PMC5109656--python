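"""Synthetic annotated genomes with implanted glycosylation islands.

The generator emulates the structure this pipeline is built to analyse: a
conserved flagellar biosynthetic locus (comFA ... flaA2 [island] flaG ...
raiA) embedded in a host-composition backbone, with an intergenic island
whose G+C is depressed relative to the host. Typed strains receive island
genes drawn from type-specific family profiles (distinct sugar-pathway
complements plus glycosyltransferase and maf genes); FGI-negative strains
receive only endonuclease/hypothetical filler. Island G+C is controlled by
biasing synonymous-codon choice so the expected composition hits the target;
protein divergence is uniform random substitution, so pairwise identity is
analytically predictable. Everything is deterministic per seed.

All reference sequences emitted here (anchors, labeled reference DB) are
synthetic constructs of this generator, not database proteins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .errors import ConfigurationError, ValidationError
from .genome_io import GeneFeature, Genome
from .locus import AnchorSet, ReferenceDB, ReferenceProtein

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# codon table 11 grouped by amino acid, with per-codon G+C counts
_table = CodonTable.unambiguous_dna_by_id[11]
AA_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _table.forward_table.items():
    AA_CODONS.setdefault(_aa, []).append(_codon)
for _aa in AA_CODONS:
    AA_CODONS[_aa].sort()
AA_CODONS["*"] = ["TAA"]
CODON_GC = {c: c.count("G") + c.count("C") for codons in AA_CODONS.values() for c in codons}


def random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, len(AA_ALPHABET), size=length)
    return "".join(AA_ALPHABET[i] for i in idx)


def mutate_protein(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each residue with probability ``divergence`` (no indels)."""
    if divergence <= 0:
        return seq
    out = list(seq)
    mask = rng.random(len(seq)) < divergence
    for i in np.flatnonzero(mask):
        choices = AA_ALPHABET.replace(out[i], "")
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _expected_gc(aa: str, beta: float) -> float:
    codons = AA_CODONS[aa]
    w = np.exp([beta * CODON_GC[c] for c in codons])
    gcs = np.array([CODON_GC[c] for c in codons], dtype=float)
    return float((w * gcs).sum() / w.sum())


from functools import lru_cache


@lru_cache(maxsize=None)
def _solve_beta(target_gc: float) -> float:
    """Codon-bias parameter giving expected G+C = target for a protein of
    uniform amino-acid composition (a small stop-codon weight included).

    The generated proteins are composition-uniform by construction, so one
    solve per target G+C makes every gene expectation-matched; per-gene
    composition noise averages out across an island. Raises
    :class:`ConfigurationError` for unreachable targets.
    """
    stop_weight = 1.0 / 300.0  # one stop per ~300 residues

    def mean_gc(beta: float) -> float:
        num = sum(_expected_gc(aa, beta) for aa in AA_ALPHABET)
        num += stop_weight * _expected_gc("*", beta)
        return num / (3.0 * (len(AA_ALPHABET) + stop_weight))

    lo, hi = -30.0, 30.0
    if not (mean_gc(lo) - 1e-9 <= target_gc <= mean_gc(hi) + 1e-9):
        raise ConfigurationError(
            f"target G+C {target_gc:.3f} unachievable with codon choice "
            f"(range {mean_gc(lo):.3f}-{mean_gc(hi):.3f})"
        )
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if mean_gc(mid) < target_gc:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


@lru_cache(maxsize=None)
def _codon_probs(aa: str, target_gc: float) -> tuple[list[str], tuple[float, ...]]:
    beta = _solve_beta(target_gc)
    codons = AA_CODONS[aa]
    w = np.exp([beta * CODON_GC[c] for c in codons])
    return codons, tuple(w / w.sum())


def reverse_translate(protein: str, target_gc: float, rng: np.random.Generator) -> str:
    """Encode a protein as DNA whose expected G+C equals ``target_gc``.

    Synonymous codons are weighted by exp(beta * codon G+C count), beta
    solved once per target (see :func:`_solve_beta`); the stop codon TAA is
    appended. The encoding is expectation-matched, not exact per gene.
    """
    residues = protein + "*"
    # sample codons, grouping positions by amino acid for speed;
    # iteration order is fixed so output is deterministic per rng state
    codons_out: list[str] = [""] * len(residues)
    positions: dict[str, list[int]] = {}
    for i, aa in enumerate(residues):
        positions.setdefault(aa, []).append(i)
    for aa in sorted(positions):
        codons, p = _codon_probs(aa, target_gc)
        if len(codons) == 1:
            for pos in positions[aa]:
                codons_out[pos] = codons[0]
            continue
        draws = rng.choice(len(codons), size=len(positions[aa]), p=np.array(p))
        for pos, d in zip(positions[aa], draws):
            codons_out[pos] = codons[d]
    return "".join(codons_out)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


@dataclass(frozen=True)
class FamilySpec:
    name: str
    label: str


# Default island gene pool: five type profiles emulating distinct glycan
# pathways — neuraminic acid (I), pseudaminic acid (II/III, shared pse core),
# pen/pal-variant pseudaminic acid (IV) and rhamnose (V) — each with its own
# glycosyltransferases and maf / modification genes. Profiles overlap enough
# to be realistic (shared pse genes, shared glf/fdtB) while remaining well
# separated at the 50% similarity cutoff.
_F = FamilySpec
DEFAULT_FAMILIES: list[FamilySpec] = [
    _F("neuA", "biosynthesis:neu"), _F("neuB", "biosynthesis:neu"),
    _F("neuC", "biosynthesis:neu"), _F("neuD", "biosynthesis:neu"),
    _F("arnA", "biosynthesis:neu"), _F("degT", "biosynthesis:neu"),
    _F("ntp", "biosynthesis:neu"),
    _F("gtr1", "glycosyltransferase"), _F("gtr2", "glycosyltransferase"),
    _F("maf1", "maf"), _F("fmt1", "modification:formyltransferase"),
    _F("sam1", "modification:methyltransferase"),
    _F("pseB", "biosynthesis:pse"), _F("pseC", "biosynthesis:pse"),
    _F("pseF", "biosynthesis:pse"), _F("pseG", "biosynthesis:pse"),
    _F("pseI", "biosynthesis:pse"),
    _F("gtr3", "glycosyltransferase"), _F("gtr4", "glycosyltransferase"),
    _F("maf2", "maf"), _F("maf3", "maf"),
    _F("fdtB", "biosynthesis:fdt"), _F("fdtC", "biosynthesis:fdt"),
    _F("gtr5", "glycosyltransferase"), _F("gtr6", "glycosyltransferase"),
    _F("gtr7", "glycosyltransferase"),
    _F("maf5", "maf"), _F("fmt2", "modification:formyltransferase"),
    _F("glf", "biosynthesis:glf"),
    _F("pen", "biosynthesis:pse"), _F("pal", "biosynthesis:pse"),
    _F("maf4", "maf"), _F("sam2", "modification:methyltransferase"),
    _F("gtr8", "glycosyltransferase"), _F("gtr9", "glycosyltransferase"),
    _F("fkbM1", "modification:methyltransferase"),
    _F("rmlA", "biosynthesis:rml"), _F("rmlB", "biosynthesis:rml"),
    _F("rmlC", "biosynthesis:rml"), _F("rmlD", "biosynthesis:rml"),
    _F("fdtA", "biosynthesis:fdt"), _F("fmt3", "modification:formyltransferase"),
    _F("sam3", "modification:methyltransferase"),
    _F("gtr10", "glycosyltransferase"), _F("gtr11", "glycosyltransferase"),
]

DEFAULT_TYPE_PROFILES: dict[str, list[str]] = {
    "I": ["neuA", "neuB", "neuC", "neuD", "arnA", "degT", "ntp",
          "gtr1", "gtr2", "maf1", "fmt1", "sam1"],
    "II": ["pseB", "pseC", "pseF", "pseG", "pseI",
           "gtr3", "gtr4", "maf2", "maf3", "fdtB", "fdtC"],
    "III": ["pseB", "pseC", "pseF", "pseG", "pseI",
            "gtr5", "gtr6", "gtr7", "maf5", "fmt2", "glf"],
    "IV": ["pen", "pal", "pseC", "pseF", "pseG", "pseI",
           "maf4", "sam2", "glf", "gtr8", "gtr9", "fkbM1"],
    "V": ["rmlA", "rmlB", "rmlC", "rmlD", "fdtA", "fdtB",
          "fmt3", "sam3", "gtr10", "gtr11"],
}

#: FGI-negative filler genes (endonucleases / macro-domain / hypotheticals)
FILLER_FAMILIES: list[FamilySpec] = [
    _F("edn1", "endonuclease"), _F("edn2", "endonuclease"),
    _F("appr1p", "hypothetical"), _F("hyp1", "hypothetical"),
    _F("hyp2", "hypothetical"), _F("hyp3", "hypothetical"),
]

HOST_GENES = [  # (name, product, length in aa)
    ("comFA", "late competence protein ComFA", 460),
    ("flgN", "flagella synthesis chaperone FlgN", 140),
    ("flgM", "anti-sigma-28 factor FlgM", 90),
    ("flgK", "flagellar hook-associated protein FlgK", 500),
    ("flgL", "flagellar hook-associated protein FlgL", 300),
    ("fliD", "flagellar filament cap protein FliD", 470),
    ("fliS", "flagellar export chaperone FliS", 130),
    ("fliT", "flagellar protein FliT", 100),
    ("flaG", "flagellar protein FlaG", 130),
    ("flhB", "flagellar biosynthesis protein FlhB", 360),
    ("raiA", "ribosome-associated translation inhibitor RaiA", 190),
]


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic cohort; defaults mirror the island
    structure seen in real thermophile cohorts (host ~52% G+C, typed islands
    depressed to ~38%, five island types of three strains plus five
    island-negative strains)."""

    seed: int = 0
    n_strains_per_type: dict[str, int] = field(
        default_factory=lambda: {"I": 3, "II": 3, "III": 3, "IV": 3, "V": 3}
    )
    n_fgi_minus: int = 5
    host_gc: float = 0.52
    island_gc: float = 0.38
    fgi_minus_island_gc: float = 0.45
    fgi_minus_max_genes: int = 6
    pan_pool: dict[str, list[str]] | None = None  # None -> DEFAULT_TYPE_PROFILES
    divergence: float = 0.05
    host_divergence: float = 0.02
    flagellin_center_divergence: float = 0.5
    p_truncate: float = 0.03
    p_disrupt: float = 0.02
    p_flaA1: float = 0.65
    p_flaA3: float = 0.33  # typed I/II/III strains only
    island_gene_len: tuple[int, int] = (180, 450)
    spacer_len: tuple[int, int] = (60, 150)
    backbone_len: int = 200_000
    indels: bool = False  # reserved: substitution-only divergence by default

    def __post_init__(self):
        for p in (self.divergence, self.p_truncate, self.p_disrupt,
                  self.p_flaA1, self.p_flaA3, self.host_divergence):
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"probability {p} outside [0, 1]")
        profiles = self.profiles
        flat = [tuple(sorted(v)) for v in profiles.values()]
        if len(set(flat)) != len(flat):
            raise ValidationError("type profiles must be pairwise distinct")

    @property
    def profiles(self) -> dict[str, list[str]]:
        return self.pan_pool if self.pan_pool is not None else DEFAULT_TYPE_PROFILES


@dataclass
class StrainTruth:
    strain_id: str
    fgi_status: str  # 'FGI+' / 'FGI-'
    fgi_type: str | None
    families: list[str]
    gene_states: dict[str, str]  # family -> intact/truncated/disrupted
    island_start: int
    island_end: int
    island_gc_target: float
    host_gc_target: float
    n_flagellins: int


@dataclass
class SyntheticTruth:
    strains: dict[str, StrainTruth] = field(default_factory=dict)

    def typed_strains(self) -> dict[str, str]:
        return {
            s: t.fgi_type for s, t in self.strains.items() if t.fgi_type is not None
        }

    def to_json(self, path) -> None:
        payload = {s: asdict(t) for s, t in sorted(self.strains.items())}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls({s: StrainTruth(**t) for s, t in payload.items()})


def generate_family_pool(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> dict[str, tuple[str, str]]:
    """Ancestral protein per island family: name -> (label, sequence).

    Lengths are drawn once per family from ``island_gene_len``; the pool is
    deterministic for a given seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.island_gene_len
    pool = {}
    for spec in DEFAULT_FAMILIES + FILLER_FAMILIES:
        length = int(rng.integers(lo, hi + 1))
        pool[spec.name] = (spec.label, random_protein(rng, length))
    pool["tnp1"] = ("transposase", random_protein(rng, 280))
    return pool


@dataclass
class _HostPool:
    """Ancestral host proteins shared by the cohort."""

    genes: dict[str, tuple[str, str]]  # name -> (product, protein)
    fla_termini: tuple[str, str]  # conserved N/C termini (60 aa each)
    fla_centers: dict[str, str]  # class -> ancestral center


def _host_pool(config: GeneratorConfig, rng: np.random.Generator) -> _HostPool:
    genes = {
        name: (product, random_protein(rng, length))
        for name, product, length in HOST_GENES
    }
    nterm = random_protein(rng, 60)
    cterm = random_protein(rng, 60)
    centers = {
        "flaA1": random_protein(rng, 200),
        "flaA2": random_protein(rng, 160),
        "flaA3": random_protein(rng, 145),
    }
    return _HostPool(genes, (nterm, cterm), centers)


def _flagellin(
    host: _HostPool, cls: str, config: GeneratorConfig, rng: np.random.Generator
) -> str:
    nterm, cterm = host.fla_termini
    center = host.fla_centers[cls]
    if cls == "flaA3":  # highly conserved paralog, near-constant length
        center = mutate_protein(center, 0.03, rng)
    else:
        center = mutate_protein(center, config.flagellin_center_divergence, rng)
        insert_len = int(rng.integers(0, 61))
        if insert_len:
            pos = len(center) // 2
            center = center[:pos] + random_protein(rng, insert_len) + center[pos:]
    return (
        mutate_protein(nterm, config.host_divergence, rng)
        + center
        + mutate_protein(cterm, config.host_divergence, rng)
    )


@dataclass
class _StrainSpec:
    strain_id: str
    fgi_type: str | None  # None = FGI-negative


class _GenomeBuilder:
    def __init__(self, strain_id: str, contig_id: str):
        self.strain_id = strain_id
        self.contig_id = contig_id
        self.parts: list[str] = []
        self.length = 0
        self.features: list[GeneFeature] = []

    def add_dna(self, seq: str) -> None:
        self.parts.append(seq)
        self.length += len(seq)

    def add_cds(self, fid: str, protein: str, nt: str, gene: str = "", product: str = "") -> int:
        start = self.length
        self.add_dna(nt)
        self.features.append(
            GeneFeature(
                feature_id=fid,
                contig_id=self.contig_id,
                start=start,
                end=self.length,
                strand="+",
                gene_name=gene,
                product=product,
                protein_seq=protein,
            )
        )
        return start

    def build(self) -> Genome:
        return Genome(self.strain_id, {self.contig_id: "".join(self.parts)}, self.features)


def generate_genome(
    config: GeneratorConfig,
    spec: _StrainSpec,
    pool: dict[str, tuple[str, str]],
    host: _HostPool,
    rng: np.random.Generator,
) -> tuple[Genome, StrainTruth]:
    """Build one annotated genome plus its ground-truth entry."""
    b = _GenomeBuilder(spec.strain_id, f"{spec.strain_id}_c1")
    gcH = config.host_gc
    n_gene = 0

    def next_id() -> str:
        nonlocal n_gene
        n_gene += 1
        return f"{spec.strain_id}_{n_gene:04d}"

    def host_cds(name: str) -> None:
        product, ancestral = host.genes[name]
        prot = mutate_protein(ancestral, config.host_divergence, rng)
        b.add_cds(next_id(), prot, reverse_translate(prot, gcH, rng), gene=name, product=product)

    has_flaA1 = rng.random() < config.p_flaA1
    has_flaA3 = spec.fgi_type in ("I", "II", "III") and rng.random() < config.p_flaA3

    b.add_dna(random_dna(rng, config.backbone_len // 2, gcH))
    host_cds("comFA")
    b.add_dna(random_dna(rng, 150, gcH))
    for name in ("flgN", "flgM", "flgK", "flgL"):
        host_cds(name)
        b.add_dna(random_dna(rng, 80, gcH))
    if has_flaA1:
        host_cds("fliS")  # second fliS copy flanking flaA1
        prot = _flagellin(host, "flaA1", config, rng)
        b.add_cds(next_id(), prot, reverse_translate(prot, gcH, rng),
                  gene="flaA1", product="flagellin")
        b.add_dna(random_dna(rng, 80, gcH))
    for name in ("fliD", "fliS", "fliT"):
        host_cds(name)
        b.add_dna(random_dna(rng, 80, gcH))
    prot = _flagellin(host, "flaA2", config, rng)
    b.add_cds(next_id(), prot, reverse_translate(prot, gcH, rng),
              gene="flaA2", product="flagellin")

    # --- island: intergenic span between flaA2 and flaG ---
    island_start = b.length
    if spec.fgi_type is not None:
        families = list(config.profiles[spec.fgi_type])
        gc_island = config.island_gc
    else:
        n_filler = int(rng.integers(0, config.fgi_minus_max_genes + 1))
        filler_names = [f.name for f in FILLER_FAMILIES]
        picks = rng.choice(len(filler_names), size=min(n_filler, len(filler_names)),
                           replace=False)
        families = [filler_names[i] for i in sorted(picks)]
        gc_island = config.fgi_minus_island_gc
    gene_states: dict[str, str] = {}
    lo_sp, hi_sp = config.spacer_len
    b.add_dna(random_dna(rng, int(rng.integers(lo_sp, hi_sp + 1)), gc_island))
    for fam in families:
        label, ancestral = pool[fam]
        prot = mutate_protein(ancestral, config.divergence, rng)
        u = rng.random()
        if spec.fgi_type is not None and u < config.p_truncate:
            frac = rng.uniform(0.2, 0.45)
            prot = prot[: max(10, int(frac * len(prot)))]
            state = "truncated"
        elif spec.fgi_type is not None and u < config.p_truncate + config.p_disrupt:
            frac = rng.uniform(0.72, 0.85)
            prot = prot[: int(frac * len(prot))]
            state = "disrupted"
        else:
            state = "intact"
        b.add_cds(next_id(), prot, reverse_translate(prot, gc_island, rng),
                  gene=fam, product="hypothetical protein")
        if state == "disrupted":
            b.add_dna(random_dna(rng, 20, gc_island))
            tnp = mutate_protein(pool["tnp1"][1], config.divergence, rng)
            b.add_cds(next_id(), tnp, reverse_translate(tnp, gc_island, rng),
                      gene="tnp", product="transposase")
        gene_states[fam] = state
        b.add_dna(random_dna(rng, int(rng.integers(lo_sp, hi_sp + 1)), gc_island))
    island_end = b.length

    host_cds("flaG")
    if has_flaA3:
        b.add_dna(random_dna(rng, 80, gcH))
        prot = _flagellin(host, "flaA3", config, rng)
        b.add_cds(next_id(), prot, reverse_translate(prot, gcH, rng),
                  gene="flaA3", product="flagellin")
    b.add_dna(random_dna(rng, 120, gcH))
    host_cds("flhB")
    b.add_dna(random_dna(rng, 150, gcH))
    host_cds("raiA")
    b.add_dna(random_dna(rng, config.backbone_len // 2, gcH))

    genome = b.build()
    truth = StrainTruth(
        strain_id=spec.strain_id,
        fgi_status="FGI+" if spec.fgi_type is not None else "FGI-",
        fgi_type=spec.fgi_type,
        families=families,
        gene_states=gene_states,
        island_start=island_start,
        island_end=island_end,
        island_gc_target=gc_island,
        host_gc_target=gcH,
        n_flagellins=1 + int(has_flaA1) + int(has_flaA3),
    )
    return genome, truth


@dataclass
class SyntheticCohort:
    genomes: list[Genome]
    truth: SyntheticTruth
    anchors: AnchorSet
    reference_db: ReferenceDB
    config: GeneratorConfig


def generate_cohort(config: GeneratorConfig, out_dir=None) -> SyntheticCohort:
    """Generate a full cohort: genomes, truth, anchors and reference DB.

    With ``out_dir`` set, one GenBank file per strain plus ``anchors.faa``,
    ``reference_db.faa`` and ``truth.json`` are written there; the outputs
    are byte-identical for identical configs.
    """
    rng = np.random.default_rng(config.seed)
    pool = generate_family_pool(config, rng)
    host = _host_pool(config, rng)

    specs: list[_StrainSpec] = []
    for t in sorted(config.n_strains_per_type):
        for _ in range(config.n_strains_per_type[t]):
            specs.append(_StrainSpec(strain_id="", fgi_type=t))
    for _ in range(config.n_fgi_minus):
        specs.append(_StrainSpec(strain_id="", fgi_type=None))
    for i, spec in enumerate(specs, start=1):
        spec.strain_id = f"strain{i:02d}" if len(specs) < 100 else f"strain{i:03d}"

    genomes = []
    truth = SyntheticTruth()
    for spec in specs:
        genome, st = generate_genome(config, spec, pool, host, rng)
        genomes.append(genome)
        truth.strains[spec.strain_id] = st

    nterm, cterm = host.fla_termini
    fla_refs = {
        cls: nterm + host.fla_centers[cls] + cterm for cls in ("flaA1", "flaA2", "flaA3")
    }
    anchors = AnchorSet(
        flaA2=fla_refs["flaA2"],
        flaG=host.genes["flaG"][1],
        comFA=host.genes["comFA"][1],
        raiA=host.genes["raiA"][1],
        flagellin_refs={"flaA1": fla_refs["flaA1"], "flaA3": fla_refs["flaA3"]},
    )
    ref_entries = [
        ReferenceProtein(name, label, seq) for name, (label, seq) in sorted(pool.items())
    ]
    ref_entries.extend(
        ReferenceProtein(cls, "flagellin", seq) for cls, seq in sorted(fla_refs.items())
    )
    reference_db = ReferenceDB(ref_entries)

    cohort = SyntheticCohort(genomes, truth, anchors, reference_db, config)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: SyntheticCohort, out_dir: Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    out_dir.mkdir(parents=True, exist_ok=True)
    genome_dir = out_dir / "genomes"
    genome_dir.mkdir(exist_ok=True)
    for genome in cohort.genomes:
        records = []
        for contig_id, seq in genome.contigs.items():
            rec = SeqRecord(Seq(seq), id=contig_id, name=contig_id[:16],
                            description=f"synthetic genome {genome.strain_id}")
            rec.annotations["molecule_type"] = "DNA"
            rec.annotations["date"] = "01-JAN-1980"  # fixed for reproducibility
            rec.annotations["organism"] = genome.strain_id
            for f in genome.features:
                if f.contig_id != contig_id:
                    continue
                qualifiers = {
                    "locus_tag": [f.feature_id],
                    "translation": [f.protein_seq],
                    "transl_table": ["11"],
                }
                if f.gene_name:
                    qualifiers["gene"] = [f.gene_name]
                if f.product:
                    qualifiers["product"] = [f.product]
                rec.features.append(
                    SeqFeature(
                        FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1),
                        type="CDS",
                        qualifiers=qualifiers,
                    )
                )
            records.append(rec)
        SeqIO.write(records, str(genome_dir / f"{genome.strain_id}.gbk"), "genbank")

    from .genome_io import write_fasta

    write_fasta(cohort.anchors.to_items(), out_dir / "anchors.faa")
    cohort.reference_db.write_fasta(out_dir / "reference_db.faa")
    cohort.truth.to_json(out_dir / "truth.json")
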