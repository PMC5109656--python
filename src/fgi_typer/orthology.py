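"""Ortholog-family construction across strains and binary presence/absence scoring.

Families are single-linkage connected components over the graph of protein
pairs clearing the orthology criterion (default: identity > 70% with both
coverages >= 70%). Presence is scored 1 only for families with at least one
intact member in the strain: members shorter than ``truncation_frac`` of the
family's median length count as truncated, and members flagged as
transposon-disrupted count as disrupted; both score 0, with the reason kept
as provenance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from statistics import median

import numpy as np

from .alignment import DEFAULT_SCORING, align_global, kmer_set, may_share_identity, qualifies
from .errors import ValidationError


@dataclass
class ProteinEntry:
    """One island CDS entering the ortholog clustering."""

    strain_id: str
    feature_id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class FamilyMember:
    feature_id: str
    length: int
    is_intact: bool = True
    reason: str = "present"


@dataclass
class OrthologFamily:
    family_id: str
    members: dict[str, list[FamilyMember]] = field(default_factory=dict)

    def member_lengths(self) -> list[int]:
        return [m.length for mem in self.members.values() for m in mem]

    def median_length(self) -> float:
        return median(self.member_lengths())


def cluster_orthologs(
    proteins_by_strain: dict[str, list[tuple[str, str]]],
    id_thresh: float = 70.0,
    cov_thresh: float = 70.0,
    scoring=DEFAULT_SCORING,
    prescreen: bool = True,
) -> list[OrthologFamily]:
    """Cluster island proteins of all strains into ortholog families.

    ``proteins_by_strain`` maps strain_id to an ordered list of
    (feature_id, protein_seq). Output order is stable: families are sorted
    by the first-seen (strain, gene) of their earliest member, with strains
    taken in sorted order, so membership is invariant to input dict order.
    """
    if not proteins_by_strain:
        raise ValidationError("cluster_orthologs requires at least one strain")
    entries: list[ProteinEntry] = []
    for strain in sorted(proteins_by_strain):
        for fid, seq in proteins_by_strain[strain]:
            if seq:
                entries.append(ProteinEntry(strain, fid, seq))
    n = len(entries)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    cov_frac = cov_thresh / 100.0
    kmers = [kmer_set(e.seq) for e in entries] if prescreen else None
    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            a, b = entries[i].seq, entries[j].seq
            la, lb = len(a), len(b)
            # exact filter: coverage of the longer sequence can never reach
            # cov_thresh when the lengths are too dissimilar
            if min(la, lb) < cov_frac * max(la, lb):
                continue
            if prescreen and not may_share_identity(a, b, kmers[i], kmers[j]):
                continue
            if qualifies(align_global(a, b, scoring), id_thresh, cov_thresh):
                union(i, j)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)
    families = []
    for k, root in enumerate(sorted(components, key=lambda r: min(components[r]))):
        fam = OrthologFamily(family_id=f"F{k + 1:03d}")
        for idx in components[root]:
            e = entries[idx]
            fam.members.setdefault(e.strain_id, []).append(
                FamilyMember(e.feature_id, e.length)
            )
        families.append(fam)
    return families


@dataclass
class PresenceAbsenceMatrix:
    """Binary strain × family matrix with per-cell provenance."""

    strains: list[str]
    families: list[str]
    cells: np.ndarray  # shape (n_strains, n_families), int8
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def profile(self, strain: str) -> np.ndarray:
        return self.cells[self.strains.index(strain)]

    def write_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["strain_id"] + self.families)
            for i, s in enumerate(self.strains):
                w.writerow([s] + [int(v) for v in self.cells[i]])

    def write_long_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("strain_id\tfamily_id\tcell\treason\n")
            for i, s in enumerate(self.strains):
                for j, f in enumerate(self.families):
                    reason = self.provenance.get((s, f), "absent")
                    fh.write(f"{s}\t{f}\t{int(self.cells[i, j])}\t{reason}\n")


def score_matrix(
    families: list[OrthologFamily],
    strains: list[str],
    truncation_frac: float = 0.5,
    disrupted: set[tuple[str, str]] | None = None,
) -> PresenceAbsenceMatrix:
    """Score presence (1) / absence (0) of each family in each strain.

    ``disrupted`` holds (strain_id, feature_id) pairs flagged as
    transposon-disrupted. A member is intact when its length is at least
    ``truncation_frac`` × the family median length and it is not disrupted.
    """
    disrupted = disrupted or set()
    strains = sorted(strains)
    fam_ids = [f.family_id for f in families]
    cells = np.zeros((len(strains), len(families)), dtype=np.int8)
    prov: dict[tuple[str, str], str] = {}
    for j, fam in enumerate(families):
        med = fam.median_length()
        for strain, members in fam.members.items():
            if strain not in strains:
                continue
            i = strains.index(strain)
            reasons = []
            for m in members:
                if (strain, m.feature_id) in disrupted:
                    m.is_intact = False
                    m.reason = "disrupted"
                elif m.length < truncation_frac * med:
                    m.is_intact = False
                    m.reason = "truncated"
                else:
                    m.is_intact = True
                    m.reason = "present"
                reasons.append(m.reason)
            if any(r == "present" for r in reasons):
                cells[i, j] = 1
                prov[(strain, fam.family_id)] = "present"
            elif "disrupted" in reasons:
                prov[(strain, fam.family_id)] = "disrupted"
            else:
                prov[(strain, fam.family_id)] = "truncated"
    return PresenceAbsenceMatrix(strains, fam_ids, cells, prov)
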