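"""Synthetic scat-sample generator.

Emulates the statistical structure the diet pipeline assumes so every
downstream stage is testable without field data:

* per-sample true prey biomass proportions drawn from a Dirichlet;
* 16S read counts multinomial over all prey with per-species amplification
  bias factors plus one predator-read category (blocking-oligo leakage);
* COI read counts from a separate PCR, multinomial over the salmonid taxa
  only (within-salmonid proportions, their own bias factors);
* tagged reads (tag + primer + reference insert, independent per-base
  substitution errors) for exercising demultiplexing and assignment;
* per-sample hard-part detections with juvenile/adult salmon bone labels
  driven by a month-dependent juvenile probability.

All randomness derives from ``config.seed``; identical configs give
byte-identical outputs. Distinct seeded streams per stage keep stages
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amplicon import PRIMERS, TagSet
from .lifestage import ADULT, JUVENILE, HardPartRecord
from .refdb import SALMONID_SPECIES, ReferenceDB

PREDATOR_TAXON = "Phoca_vitulina"

_DEFAULT_TAXA = (
    "Clupea_pallasii",          # Pacific herring
    "Merluccius_productus",     # Pacific hake
    "Ammodytes_hexapterus",     # sand lance
    "Gadus_chalcogrammus",      # walleye pollock
    "Oncorhynchus_tshawytscha", # Chinook
    "Oncorhynchus_keta",        # chum
    "Oncorhynchus_kisutch",     # coho
)
_DEFAULT_SALMONIDS = tuple(t for t in _DEFAULT_TAXA if t in SALMONID_SPECIES)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic scat study.

    Defaults give a moderately uneven 7-prey diet, mild amplification bias,
    a 10% predator-read fraction, fixed read depth, and hard-part detection
    in 80% of consumed-taxon occurrences.
    """

    n_samples: int = 50
    taxa: tuple[str, ...] = _DEFAULT_TAXA
    salmonid_taxa: tuple[str, ...] = _DEFAULT_SALMONIDS
    dirichlet_alpha: tuple[float, ...] | None = None  # default: 1.0 each
    bias_factors: dict[str, float] = field(default_factory=dict)  # default 1.0
    reads_per_sample: int = 2000
    coi_reads_per_sample: int = 1000
    predator_read_fraction: float = 0.1
    error_rate: float = 0.0
    hardpart_detection_prob: float = 0.8
    juvenile_prob_by_month: dict[int, float] = field(
        default_factory=lambda: {
            1: 0.1, 2: 0.1, 3: 0.8, 4: 0.9, 5: 0.9, 6: 0.8,
            7: 0.5, 8: 0.3, 9: 0.1, 10: 0.1, 11: 0.1, 12: 0.1,
        }
    )
    site_labels: tuple[str, ...] = ("Belle Chain", "Comox", "Fraser River")
    year_range: tuple[int, int] = (2012, 2019)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not self.taxa:
            raise ValueError("need at least one taxon")
        if not set(self.salmonid_taxa) <= set(self.taxa):
            raise ValueError("salmonid_taxa must be a subset of taxa")
        if self.dirichlet_alpha is None:
            self.dirichlet_alpha = tuple(1.0 for _ in self.taxa)
        if len(self.dirichlet_alpha) != len(self.taxa):
            raise ValueError("dirichlet_alpha length must match taxa")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha must be strictly positive")
        if any(b <= 0 for b in self.bias_factors.values()):
            raise ValueError("bias_factors must be strictly positive")
        if not 0 <= self.predator_read_fraction < 1:
            raise ValueError("predator_read_fraction must be in [0, 1)")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0 <= self.hardpart_detection_prob <= 1:
            raise ValueError("hardpart_detection_prob must be in [0, 1]")
        if any(not 0 <= p <= 1 for p in self.juvenile_prob_by_month.values()):
            raise ValueError("juvenile probabilities must be in [0, 1]")
        if any(m not in range(1, 13) for m in self.juvenile_prob_by_month):
            raise ValueError("juvenile_prob_by_month keys must be months 1-12")

    def bias_vector(self, taxa=None) -> np.ndarray:
        taxa = taxa if taxa is not None else self.taxa
        return np.array([self.bias_factors.get(t, 1.0) for t in taxa])

    def rng(self, stage: int) -> np.random.Generator:
        # independent stream per pipeline stage, all derived from seed
        return np.random.default_rng([int(self.seed) % (2**31), stage])


@dataclass(frozen=True)
class TrueDiet:
    """Ground-truth biomass proportions of one scat sample."""

    sample_id: str
    proportions: dict[str, float]

    def __post_init__(self):
        vals = np.array(list(self.proportions.values()))
        if (vals < 0).any():
            raise ValueError("proportions must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")

    def as_array(self, taxa) -> np.ndarray:
        return np.array([self.proportions.get(t, 0.0) for t in taxa])


def sample_ids(config: SimulationConfig) -> list[str]:
    return [f"Pv.S{i:04d}" for i in range(config.n_samples)]


def simulate_sample_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Site and collection date per sample (deterministic under seed)."""
    rng = config.rng(0)
    ids = sample_ids(config)
    sites = rng.choice(list(config.site_labels), size=config.n_samples)
    years = rng.integers(config.year_range[0], config.year_range[1] + 1,
                         size=config.n_samples)
    months = rng.integers(1, 13, size=config.n_samples)
    days = rng.integers(1, 29, size=config.n_samples)
    return pd.DataFrame(
        {"sample_ID": ids, "site": sites, "year": years,
         "month": months, "day": days}
    ).set_index("sample_ID")


def simulate_true_diets(config: SimulationConfig) -> list[TrueDiet]:
    """Draw each sample's true biomass proportions from
    Dirichlet(dirichlet_alpha)."""
    rng = config.rng(1)
    props = rng.dirichlet(config.dirichlet_alpha, size=config.n_samples)
    return [
        TrueDiet(sid, dict(zip(config.taxa, row)))
        for sid, row in zip(sample_ids(config), props)
    ]


def true_diet_table(diets: list[TrueDiet], taxa) -> pd.DataFrame:
    return pd.DataFrame(
        [d.as_array(taxa) for d in diets],
        index=[d.sample_id for d in diets],
        columns=list(taxa),
    )


@dataclass
class SimulatedCounts:
    """16S (prey + predator column) and COI (salmonid-only) count tables."""

    counts_16s: pd.DataFrame
    counts_coi: pd.DataFrame
    predator_taxon: str = PREDATOR_TAXON

    @property
    def prey_16s(self) -> pd.DataFrame:
        return self.counts_16s.drop(columns=[self.predator_taxon], errors="ignore")


def simulate_read_counts(
    diets: list[TrueDiet], config: SimulationConfig
) -> SimulatedCounts:
    """Multinomial read counts under per-species amplification bias.

    16S: ``p_i ∝ true_proportion_i × bias_factor_i`` scaled to
    ``1 - predator_read_fraction``, plus one predator category at
    ``predator_read_fraction``. COI: an independent multinomial over the
    salmonid taxa with probabilities ∝ within-salmonid true proportion ×
    bias factor (zero rows give zero COI reads).
    """
    if not diets:
        raise ValueError("no diets supplied")
    rng = config.rng(2)
    taxa = list(config.taxa)
    bias = config.bias_vector(taxa)

    rows_16s, rows_coi = [], []
    sal = list(config.salmonid_taxa)
    sal_bias = config.bias_vector(sal)
    for diet in diets:
        p = diet.as_array(taxa) * bias
        p = p / p.sum() * (1.0 - config.predator_read_fraction)
        p_full = np.append(p, config.predator_read_fraction)
        rows_16s.append(rng.multinomial(config.reads_per_sample, p_full))

        if sal:
            ps = diet.as_array(sal) * sal_bias
            tot = ps.sum()
            if tot > 0:
                rows_coi.append(rng.multinomial(config.coi_reads_per_sample,
                                                ps / tot))
            else:
                rows_coi.append(np.zeros(len(sal), dtype=int))

    ids = [d.sample_id for d in diets]
    counts_16s = pd.DataFrame(rows_16s, index=ids,
                              columns=taxa + [PREDATOR_TAXON])
    counts_coi = pd.DataFrame(
        rows_coi if sal else np.zeros((len(ids), 0), dtype=int),
        index=ids, columns=sal,
    )
    return SimulatedCounts(counts_16s, counts_coi)


_MUT = {b: tuple(o for o in "ACGT" if o != b) for b in "ACGT"}


def simulate_reads(
    counts: pd.DataFrame,
    refdb: ReferenceDB,
    tags: TagSet,
    config: SimulationConfig,
    primer: str = PRIMERS["Chord_16S_F"],
) -> list[tuple[str, str]]:
    """Emit tagged reads for a count table: per (sample, taxon) cell, that
    many reads of ``tag + primer + reference insert`` with independent
    per-base substitution errors at ``config.error_rate`` applied to the
    insert. Returns (read_id, sequence) pairs; read counts match the table
    exactly. Degenerate primer bases are resolved to their first option.
    """
    rng = config.rng(3)
    if len(counts.index) > len(tags.tags):
        raise ValueError("more samples than tags")
    ref_by_species: dict[str, list[str]] = {}
    for e in refdb.entries:
        ref_by_species.setdefault(e.species, []).append(e.sequence)
    for taxon in counts.columns:
        if taxon not in ref_by_species:
            raise ValueError(f"taxon {taxon!r} has no reference sequence")

    primer = _resolve_degenerate(primer)
    reads: list[tuple[str, str]] = []
    for si, sample in enumerate(counts.index):
        tag = tags.tags[si]
        for taxon in counts.columns:
            n = int(counts.loc[sample, taxon])
            refs = ref_by_species[taxon]
            for r in range(n):
                insert = refs[r % len(refs)]
                if config.error_rate > 0:
                    insert = _mutate(insert, config.error_rate, rng)
                reads.append((f"{sample}|{taxon}|{r}", tag + primer + insert))
    return reads


def _resolve_degenerate(primer: str) -> str:
    from ._align import _IUPAC

    return "".join(sorted(_IUPAC[b])[0] for b in primer.upper())


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    chars = list(seq)
    for i in np.flatnonzero(mask):
        chars[i] = _MUT[chars[i]][rng.integers(3)]
    return "".join(chars)


def write_fasta(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f">{rid}\n{seq}\n")


def simulate_hardparts(
    diets: list[TrueDiet],
    config: SimulationConfig,
    metadata: pd.DataFrame | None = None,
) -> list[HardPartRecord]:
    """Morphological detections: each consumed taxon (proportion > 0)
    leaves a diagnostic hard part with probability
    ``hardpart_detection_prob``; salmonid detections carry a
    Juvenile/Adult bone label drawn from ``juvenile_prob_by_month`` for
    the sample's collection month.
    """
    rng = config.rng(4)
    if metadata is None:
        metadata = simulate_sample_metadata(config)
    records: list[HardPartRecord] = []
    for diet in diets:
        month = int(metadata.loc[diet.sample_id, "month"])
        for taxon, prop in diet.proportions.items():
            if prop <= 0:
                continue
            if rng.random() >= config.hardpart_detection_prob:
                continue
            label = None
            if taxon in config.salmonid_taxa:
                p_juv = config.juvenile_prob_by_month.get(month, 0.5)
                label = JUVENILE if rng.random() < p_juv else ADULT
            records.append(
                HardPartRecord(diet.sample_id, taxon, label, analyst="synthetic")
            )
    return records


def synthetic_reference_db(
    config: SimulationConfig,
    seq_length: int = 260,
    marker: str = "16S",
    include_predator: bool = True,
    indistinguishable_pairs: tuple[tuple[str, str], ...] = (),
) -> ReferenceDB:
    """Random reference sequences for the configured taxa (plus predator).

    Sequences are i.i.d. uniform over ACGT, so any two species are ~75%
    divergent — far below assignment thresholds — unless listed in
    ``indistinguishable_pairs``, in which case the second species receives
    a copy of the first's sequence (modelling shared haplotypes).
    """
    from .refdb import ReferenceEntry

    rng = config.rng(5)
    taxa = list(config.taxa) + ([PREDATOR_TAXON] if include_predator else [])
    seqs = {
        t: "".join(rng.choice(list("ACGT"), size=seq_length)) for t in taxa
    }
    for a, b in indistinguishable_pairs:
        seqs[b] = seqs[a]
    entries = [
        ReferenceEntry(t, t.replace("_", " "), s, marker) for t, s in seqs.items()
    ]
    return ReferenceDB(entries)
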