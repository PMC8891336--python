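"""Prey reference sequence database.

A metabarcoding diet pipeline assigns amplicon reads to prey species by
best match against a curated reference database. Some species cannot be
distinguished at a short marker — their reference sequences are identical —
and are reported jointly as a merged "OR" taxon (e.g.
``China_Rockfish_OR_Copper_Rockfish``). This module parses reference FASTA
files, computes pairwise distance matrices, detects indistinguishable
species groups (transitive closure over any identical sequence pair), and
builds the merged identifiers.

FASTA header grammar: ``>Species_name|Common_name|marker``. Headers that do
not follow the grammar fall back to the whole header as the species name,
empty common name, and the default marker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._align import _IUPAC, p_distance

VALID_MARKERS = ("16S", "COI")

#: The nine salmonid species known to occur regionally, resolved by the
#: salmonid-specific COI mini-barcode.
SALMONID_SPECIES = (
    "Oncorhynchus_gorbuscha",
    "Oncorhynchus_keta",
    "Oncorhynchus_kisutch",
    "Oncorhynchus_mykiss",
    "Oncorhynchus_nerka",
    "Oncorhynchus_tshawytscha",
    "Oncorhynchus_clarkii",
    "Salmo_salar",
    "Salvelinus_malma",
)


class FastaParseError(ValueError):
    """Raised for malformed or empty reference FASTA input."""


@dataclass(frozen=True)
class ReferenceEntry:
    species: str
    common_name: str
    sequence: str
    marker: str = "16S"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.species}")
        bad = set(self.sequence.upper()) - set(_IUPAC)
        if bad:
            raise ValueError(
                f"non-IUPAC characters {sorted(bad)} in sequence of {self.species}"
            )
        if self.marker not in VALID_MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}")
        # canonicalize to uppercase
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over reference sequences."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if (v < 0).any() or (v > 1).any():
            raise ValueError("distances must lie in [0, 1]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


class ReferenceDB:
    """Collection of reference sequences with species-level grouping."""

    def __init__(self, entries: list[ReferenceEntry]):
        if not entries:
            raise ValueError("reference database must contain at least one entry")
        self.entries = list(entries)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_fasta(cls, path, marker: str | None = None) -> "ReferenceDB":
        """Load a reference FASTA.

        Duplicate records (identical header and sequence) are removed with a
        warning. ``marker`` overrides the marker field for every record.
        """
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise FastaParseError(f"no FASTA records in {path}")
        entries: list[ReferenceEntry] = []
        seen: set[tuple[str, str]] = set()
        for rec in records:
            key = (rec.description, str(rec.seq).upper())
            if key in seen:
                warnings.warn(
                    f"duplicate record {rec.description!r} dropped", UserWarning
                )
                continue
            seen.add(key)
            entries.append(_parse_header(rec.description, str(rec.seq), marker))
        return cls(entries)

    def to_fasta(self, path) -> None:
        recs = [
            SeqRecord(
                Seq(e.sequence),
                id=f"{e.species}|{e.common_name}|{e.marker}",
                description="",
            )
            for e in self.entries
        ]
        SeqIO.write(recs, str(path), "fasta")

    def add_entries(self, entries: list[ReferenceEntry]) -> None:
        """Append entries (the iterative database-augmentation step);
        groupings must be recomputed afterwards."""
        self.entries.extend(entries)

    # -- queries -----------------------------------------------------------

    def subset(self, marker: str) -> "ReferenceDB":
        sub = [e for e in self.entries if e.marker == marker]
        if not sub:
            raise ValueError(f"no entries for marker {marker}")
        return ReferenceDB(sub)

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.species, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.entries)


def _parse_header(header: str, seq: str, marker: str | None) -> ReferenceEntry:
    parts = header.split("|")
    if len(parts) == 3 and parts[2].strip() in VALID_MARKERS:
        sp, common, mk = (p.strip() for p in parts)
    elif len(parts) == 2:
        sp, common = (p.strip() for p in parts)
        mk = "16S"
    else:
        sp, common, mk = header.strip(), "", "16S"
    return ReferenceEntry(sp, common, seq, marker or mk)


def distance_matrix(db: ReferenceDB, marker: str | None = None) -> DistanceMatrix:
    """All-pairs p-distance over the database (one marker at a time).

    Labels are ``species#index`` so multiple haplotypes per species stay
    distinguishable. Identical sequences get distance exactly 0.0.
    """
    entries = db.entries if marker is None else db.subset(marker).entries
    if len(entries) < 2:
        raise ValueError("distance matrix requires at least two sequences")
    labels = [f"{e.species}#{i}" for i, e in enumerate(entries)]
    n = len(entries)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = p_distance(entries[i].sequence, entries[j].sequence)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


def indistinguishable_groups(
    dm: DistanceMatrix, db: ReferenceDB
) -> list[frozenset[str]]:
    """Partition species into indistinguishability groups.

    Two species are grouped if ANY pair of their sequences has distance 0
    (one shared haplotype suffices even when other haplotypes differ);
    grouping is the transitive closure of that relation. Returns disjoint
    groups covering every species in the database.
    """
    species_of = {f"{e.species}#{i}": e.species for i, e in enumerate(db.entries)}
    parent: dict[str, str] = {sp: sp for sp in db.species}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    n = len(dm.labels)
    for i in range(n):
        for j in range(i + 1, n):
            if dm.values[i, j] == 0.0:
                si, sj = species_of[dm.labels[i]], species_of[dm.labels[j]]
                if si != sj:
                    union(si, sj)

    groups: dict[str, set[str]] = {}
    for sp in db.species:
        groups.setdefault(find(sp), set()).add(sp)
    return [frozenset(g) for g in groups.values()]


def merged_prey_id(group) -> str:
    """Merged identifier for an indistinguishability group.

    Species are ordered alphabetically and joined with ``_OR_``; a singleton
    group is reported as the species name itself.
    """
    members = sorted(group)
    if not members:
        raise ValueError("empty group has no prey ID")
    return "_OR_".join(members)


def group_lookup(groups: list[frozenset[str]]) -> dict[str, str]:
    """Map each species to its (possibly merged) prey identifier."""
    out: dict[str, str] = {}
    for g in groups:
        pid = merged_prey_id(g)
        for sp in g:
            out[sp] = pid
    return out


def read_distance_matrix_xlsx(path) -> DistanceMatrix:
    """Read a published distance matrix from xlsx (validation only)."""
    df = pd.read_excel(path, index_col=0)
    return DistanceMatrix([str(c) for c in df.columns], df.to_numpy(dtype=float))
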