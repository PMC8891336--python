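"""Amplicon read processing: tag-code design, demultiplexing, clustering,
taxonomic assignment, and the per-sample count table.

The processing rules mirror a standard metabarcoding workflow for 5'-tagged
single-end amplicons:

* samples are identified by a fixed-length primer tag designed so that any
  two tags differ by a minimum edit distance (10 bp, distance >= 5 by
  default, so two tags cannot be confused without 5 independent errors);
* a read is assigned to a sample only if its primer matches with at most 2
  mismatches AND exactly one tag matches with at most 2 mismatches;
* assigned inserts are clustered greedily (abundance-sorted, centroid
  identity >= 0.99, minimum cluster size 3);
* cluster representatives are assigned to the best-identity reference
  species (identity >= 0.9, minimum alignment length standing in for a
  BLAST e-value screen), mapped through indistinguishable-species groups;
* samples with fewer than 10 identified prey reads are excluded.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import hamming, identity, levenshtein
from .refdb import ReferenceDB, group_lookup

logger = logging.getLogger(__name__)

_BASES = "ACGT"

#: Chordate/cephalopod 16S and salmonid COI primer sequences.
PRIMERS = {
    "Chord_16S_F": "GATCGAGAAGACCCTRTGGAGCT",
    "Chord_16S_R": "GGATTGCGCTGTTATCCCT",
    "Ceph_16S_F": "GACGAGAAGACCCTAWTGAGCT",
    "Ceph_16S_R": "AAATTACGCTGTTATCCCT",
    "Sal_COI_F": "CTCTATTTAGTATTTGGTGCCTGAG",
    "Sal_COI_R": "GAGTCAGAAGCTTATGTTRTTTATTCG",
}


@dataclass(frozen=True)
class TagSet:
    """A set of equal-length DNA tags with guaranteed minimum pairwise
    Levenshtein distance."""

    tags: tuple[str, ...]
    min_distance: int

    def __post_init__(self):
        if not self.tags:
            raise ValueError("empty tag set")
        L = len(self.tags[0])
        if any(len(t) != L for t in self.tags):
            raise ValueError("tags must all have the same length")
        if len(set(self.tags)) != len(self.tags):
            raise ValueError("tags must be unique")

    @property
    def length(self) -> int:
        return len(self.tags[0])

    def verify(self) -> bool:
        """Exhaustive all-pairs Levenshtein check of the distance invariant."""
        return min_pairwise_distance(self.tags) >= self.min_distance


def min_pairwise_distance(tags) -> int:
    """Minimum pairwise Levenshtein distance over a tag collection."""
    tags = list(tags)
    if len(tags) < 2:
        return len(tags[0]) if tags else 0
    return min(
        levenshtein(tags[i], tags[j])
        for i in range(len(tags))
        for j in range(i + 1, len(tags))
    )


class TagDesignError(RuntimeError):
    """Raised when the randomized search cannot reach the target count."""

    def __init__(self, achieved: int, target: int):
        self.achieved = achieved
        self.target = target
        super().__init__(
            f"could not reach {target} tags; achieved {achieved} "
            f"within the search budget"
        )


def design_tags(
    length: int,
    min_distance: int,
    target_count: int,
    seed: int = 0,
    max_candidates: int | None = None,
) -> TagSet:
    """Greedy randomized construction of an edit-distance tag code.

    Random candidate tags are drawn uniformly from {A,C,G,T}^length and kept
    if their Levenshtein distance to every accepted tag is at least
    ``min_distance``. Homopolymer runs longer than 3 are rejected (they are
    error-prone on sequencers and conventionally excluded from tag designs).
    Raises :class:`TagDesignError` naming the achieved size if the bounded
    search cannot reach ``target_count``.
    """
    if length < 1 or min_distance < 1 or target_count < 1:
        raise ValueError("length, min_distance and target_count must be >= 1")
    rng = np.random.default_rng(seed)
    if max_candidates is None:
        max_candidates = max(200 * target_count, 20000)

    accepted: list[str] = []
    if length <= 8 and 4**length <= 65536:
        # small spaces: exhaustive greedy over a shuffled enumeration
        candidates = _enumerate_kmers(length)
        rng.shuffle(candidates)
        pool = candidates
    else:
        pool = None

    tried = 0
    while len(accepted) < target_count and tried < max_candidates:
        if pool is not None:
            if tried >= len(pool):
                break
            cand = pool[tried]
        else:
            cand = "".join(rng.choice(list(_BASES), size=length))
        tried += 1
        if _max_homopolymer(cand) > 3:
            continue
        if all(levenshtein(cand, t) >= min_distance for t in accepted):
            accepted.append(cand)

    if len(accepted) < target_count:
        raise TagDesignError(len(accepted), target_count)
    return TagSet(tuple(accepted[:target_count]), min_distance)


def _enumerate_kmers(length: int) -> list[str]:
    kmers = [""]
    for _ in range(length):
        kmers = [k + b for k in kmers for b in _BASES]
    return kmers


def _max_homopolymer(s: str) -> int:
    best = run = 1
    for a, b in zip(s, s[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


@dataclass
class AssignmentParams:
    """Thresholds of the read-processing rules."""

    max_primer_tag_mismatches: int = 2
    cluster_identity: float = 0.99
    min_cluster_size: int = 3
    min_assign_identity: float = 0.9
    min_alignment_length: int = 100
    min_prey_reads_per_sample: int = 10

    def __post_init__(self):
        if not 0 < self.cluster_identity <= 1:
            raise ValueError("cluster_identity must be in (0, 1]")
        if not 0 < self.min_assign_identity <= 1:
            raise ValueError("min_assign_identity must be in (0, 1]")
        for name in (
            "max_primer_tag_mismatches",
            "min_cluster_size",
            "min_alignment_length",
            "min_prey_reads_per_sample",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class DemuxResult:
    """Per-sample inserts plus tallies of rejected reads."""

    by_sample: dict[str, list[str]]
    n_assigned: int = 0
    n_bad_primer: int = 0
    n_bad_tag: int = 0
    n_ambiguous_tag: int = 0

    @property
    def n_rejected(self) -> int:
        return self.n_bad_primer + self.n_bad_tag + self.n_ambiguous_tag


def demultiplex(
    reads,
    tag_to_sample: dict[str, str],
    primer: str,
    params: AssignmentParams | None = None,
) -> DemuxResult:
    """Assign 5'-anchored reads (tag + primer + insert) to samples.

    A read is assigned iff the primer region matches the primer with at most
    ``max_primer_tag_mismatches`` mismatches and exactly one tag matches the
    tag region within the same tolerance. Reads matching zero tags or two or
    more tags (ambiguous) are discarded and tallied, never raised.
    """
    params = params or AssignmentParams()
    tags = list(tag_to_sample)
    if not tags:
        raise ValueError("no tags assigned to samples")
    L = len(tags[0])
    budget = params.max_primer_tag_mismatches
    result = DemuxResult(by_sample={s: [] for s in tag_to_sample.values()})

    for read in reads:
        read = str(read).upper()
        tag_region = read[:L]
        primer_region = read[L : L + len(primer)]
        if len(primer_region) < len(primer) or hamming(primer_region, primer) > budget:
            result.n_bad_primer += 1
            continue
        hits = [t for t in tags if hamming(tag_region, t) <= budget]
        if not hits:
            result.n_bad_tag += 1
            continue
        if len(hits) > 1:
            result.n_ambiguous_tag += 1
            continue
        sample = tag_to_sample[hits[0]]
        result.by_sample[sample].append(read[L + len(primer) :])
        result.n_assigned += 1
    return result


@dataclass
class Cluster:
    representative: str
    size: int
    members: Counter = field(default_factory=Counter)


def cluster_reads(reads, params: AssignmentParams | None = None) -> list[Cluster]:
    """Greedy abundance-sorted centroid clustering.

    Unique sequences are processed by descending count (ties broken
    lexicographically for determinism); a sequence joins the first existing
    cluster whose representative it matches at identity >=
    ``cluster_identity``, else founds a new cluster. Clusters with total
    count below ``min_cluster_size`` are discarded. Empty input yields an
    empty list.
    """
    params = params or AssignmentParams()
    counts = Counter(str(r).upper() for r in reads)
    clusters: list[Cluster] = []
    for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        for cl in clusters:
            if identity(seq, cl.representative) >= params.cluster_identity:
                cl.size += n
                cl.members[seq] += n
                break
        else:
            clusters.append(Cluster(seq, n, Counter({seq: n})))
    return [c for c in clusters if c.size >= params.min_cluster_size]


def assign_taxon(
    representative: str,
    refdb: ReferenceDB,
    params: AssignmentParams | None = None,
    groups: dict[str, str] | None = None,
) -> str | None:
    """Best-hit taxonomic assignment of a cluster representative.

    Returns the species (mapped through indistinguishable groups to a merged
    prey ID when ``groups`` is given) of the best global-alignment identity
    hit, provided identity >= ``min_assign_identity`` and the query is at
    least ``min_alignment_length`` long. A tie at the best identity between
    species of different groups is ambiguous and returns ``None``.
    """
    params = params or AssignmentParams()
    if len(refdb) == 0:
        raise ValueError("empty reference database")
    if len(representative) < params.min_alignment_length:
        return None

    best = -1.0
    best_species: set[str] = set()
    for entry in refdb.entries:
        ident = identity(representative, entry.sequence)
        if ident > best + 1e-12:
            best = ident
            best_species = {entry.species}
        elif abs(ident - best) <= 1e-12:
            best_species.add(entry.species)
    if best < params.min_assign_identity:
        return None
    if groups:
        ids = {groups.get(sp, sp) for sp in best_species}
    else:
        ids = best_species
    if len(ids) > 1:
        return None  # ambiguous across groups
    return ids.pop()


def build_count_table(
    assignments: dict[str, Counter],
    params: AssignmentParams | None = None,
    predator_taxon: str = "Phoca_vitulina",
    contaminant_taxa: set[str] | frozenset[str] = frozenset(),
) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample, per-taxon read-count table with the sample-level filter.

    Predator and contaminant taxa are removed before counting; samples whose
    total identified prey reads fall below ``min_prey_reads_per_sample`` are
    excluded and returned in the exclusion log.
    """
    params = params or AssignmentParams()
    drop = {predator_taxon} | set(contaminant_taxa)
    rows: dict[str, Counter] = {}
    excluded: list[str] = []
    for sample, counts in assignments.items():
        prey = Counter({t: n for t, n in counts.items() if t not in drop and t})
        if sum(prey.values()) < params.min_prey_reads_per_sample:
            excluded.append(sample)
            logger.info(
                "sample %s excluded: %d identified prey reads < %d",
                sample, sum(prey.values()), params.min_prey_reads_per_sample,
            )
            continue
        rows[sample] = prey
    table = (
        pd.DataFrame.from_dict(rows, orient="index")
        .fillna(0)
        .astype(int)
        .sort_index()
    )
    table = table[sorted(table.columns)] if len(table.columns) else table
    return table, sorted(excluded)


def process_reads(
    reads,
    tag_to_sample: dict[str, str],
    primer: str,
    refdb: ReferenceDB,
    groups: dict[str, str] | None = None,
    params: AssignmentParams | None = None,
    predator_taxon: str = "Phoca_vitulina",
) -> tuple[pd.DataFrame, DemuxResult, list[str]]:
    """Full pipeline: demultiplex -> pooled clustering -> assignment -> table.

    Clustering pools the unique inserts across samples (so low per-sample
    counts of a common sequence survive the minimum-cluster-size rule);
    each read is then mapped to its cluster's taxon.
    """
    params = params or AssignmentParams()
    demux = demultiplex(reads, tag_to_sample, primer, params)

    pooled = [seq for seqs in demux.by_sample.values() for seq in seqs]
    clusters = cluster_reads(pooled, params)
    if groups is None:
        from .refdb import distance_matrix, indistinguishable_groups

        if len(refdb) >= 2:
            groups = group_lookup(indistinguishable_groups(distance_matrix(refdb), refdb))
        else:
            groups = {}
    seq_to_taxon: dict[str, str | None] = {}
    for cl in clusters:
        taxon = assign_taxon(cl.representative, refdb, params, groups)
        for seq in cl.members:
            seq_to_taxon[seq] = taxon

    assignments = {
        sample: Counter(
            t for t in (seq_to_taxon.get(s.upper()) for s in seqs) if t is not None
        )
        for sample, seqs in demux.by_sample.items()
    }
    table, excluded = build_count_table(
        assignments, params, predator_taxon=predator_taxon
    )
    return table, demux, excluded
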