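"""Dual-marker integration: 16S quantifies all prey, COI resolves salmonids.

The 16S marker amplifies chordate and cephalopod prey but cannot reliably
separate some salmonid congeners (notably coho, *O. kisutch*, from
steelhead, *O. mykiss*). A salmonid-specific COI mini-barcode run in a
separate PCR resolves the nine regional salmonid species. Integration per
sample: non-salmonid taxa keep their 16S read fractions; the total 16S
salmonid fraction F is distributed across salmon species as F x (that
species' COI fraction). When salmonid 16S signal exists but the sample has
too few COI reads, the fraction is reported at family level
("Salmonidae") rather than invented at species level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .refdb import SALMONID_SPECIES

logger = logging.getLogger(__name__)

SALMONIDAE_LABEL = "Salmonidae"


def is_salmonid_taxon(taxon: str, salmonid_species=SALMONID_SPECIES) -> bool:
    """True if a (possibly OR-merged) prey ID resolves wholly within
    Salmonidae."""
    if taxon == SALMONIDAE_LABEL:
        return True
    parts = taxon.split("_OR_")
    return all(p in salmonid_species for p in parts)


@dataclass
class MarkerPair:
    """16S (all-prey) and COI (salmonid-only) count tables, samples x taxa."""

    counts_16s: pd.DataFrame
    counts_coi: pd.DataFrame
    salmonid_species: tuple[str, ...] = SALMONID_SPECIES

    def __post_init__(self):
        bad = [
            t for t in self.counts_coi.columns
            if not is_salmonid_taxon(str(t), self.salmonid_species)
        ]
        if bad:
            raise ValueError(f"non-salmonid taxa in COI table: {bad}")


def integrate_sample(
    pair: MarkerPair,
    sample,
    min_coi_reads: int = 10,
) -> pd.Series:
    """Integrated per-sample prey fractions (sums to 1).

    The 16S salmonid fraction is the summed fraction of taxa resolving
    within Salmonidae (including OR-merged salmonid groups); it is split
    across salmon species by the sample's COI read fractions. With no
    salmonid 16S signal the 16S fractions pass through unchanged. With
    salmonid signal but < ``min_coi_reads`` COI reads, the fraction is
    reported unsplit as "Salmonidae" (a warning is logged).
    """
    if sample not in pair.counts_16s.index:
        raise KeyError(f"sample {sample!r} not in 16S table")
    row = pair.counts_16s.loc[sample].astype(float)
    total = row.sum()
    if total == 0:
        raise ValueError(f"sample {sample!r} has zero 16S reads")
    frac = row / total

    salmonid_cols = [
        c for c in frac.index if is_salmonid_taxon(str(c), pair.salmonid_species)
    ]
    F = float(frac[salmonid_cols].sum()) if salmonid_cols else 0.0
    out = frac.drop(labels=salmonid_cols)
    out = out[out > 0]
    if F <= 0:
        return out

    coi_row = (
        pair.counts_coi.loc[sample].astype(float)
        if sample in pair.counts_coi.index
        else pd.Series(dtype=float)
    )
    coi_total = float(coi_row.sum()) if len(coi_row) else 0.0
    if coi_total < min_coi_reads:
        logger.warning(
            "sample %s: salmonid 16S fraction %.3f but %d COI reads (<%d); "
            "reporting unsplit Salmonidae", sample, F, int(coi_total), min_coi_reads,
        )
        out[SALMONIDAE_LABEL] = F
        return out

    coi_frac = coi_row / coi_total
    for species, cf in coi_frac.items():
        if cf > 0:
            out[str(species)] = out.get(str(species), 0.0) + F * float(cf)
    return out


def integrate_all(pair: MarkerPair, min_coi_reads: int = 10) -> pd.DataFrame:
    """Apply :func:`integrate_sample` to every 16S sample; returns a
    samples x taxa fraction table (rows sum to 1, zeros filled)."""
    rows = {
        sample: integrate_sample(pair, sample, min_coi_reads)
        for sample in pair.counts_16s.index
    }
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    return table[sorted(table.columns)].sort_index()
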