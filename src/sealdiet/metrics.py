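"""Diet summary indices for metabarcoding count tables.

Given a samples x taxa read-count table ``n[i, k]`` (taxon *i*, sample *k*),
four standard indices summarise the population diet:

* ``%FOO_i = (1/S) * sum_k I[i,k] * 100`` — percent frequency of occurrence;
* ``POO_i`` — %FOO rescaled so the sum across taxa is 1 (occurrences of the
  taxon over total occurrences);
* ``wPOO_i = (1/S) * sum_k I[i,k] / sum_i I[i,k]`` — each sample contributes
  equal weight split among its detected taxa (a.k.a. split-sample FOO);
* ``RRA_i = (1/S) * sum_k n[i,k] / sum_i n[i,k] * 100`` — relative read
  abundance, the unweighted mean of per-sample read fractions, used as an
  index of proportional prey biomass.

Tables are pandas DataFrames with samples as rows and taxa as columns.
Merged "OR" prey identifiers are ordinary taxa here. Samples with no
detected items are undefined under wPOO and RRA and are dropped (with a
log message) before averaging.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValueError("count/occurrence table must have >= 1 sample and taxon")
    if (table.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    return table


def occurrence_table(counts: pd.DataFrame) -> pd.DataFrame:
    """0/1 indicator table: a taxon occurs in a sample iff its count > 0."""
    _check_table(counts)
    return (counts > 0).astype(int)


def _drop_empty_samples(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    totals = table.sum(axis=1)
    empty = totals[totals == 0].index
    if len(empty) == len(table):
        raise ValueError(f"all samples empty; {metric} undefined")
    if len(empty):
        logger.info("%s: dropping %d empty sample(s): %s",
                    metric, len(empty), list(empty))
        table = table.drop(index=empty)
    return table


def foo_percent(occ: pd.DataFrame) -> pd.Series:
    """Percent of samples in which each taxon occurs (0-100 per taxon;
    does not sum to 100)."""
    occ = _check_table(occ)
    out = occ.mean(axis=0) * 100.0
    out.name = "FOO%"
    return out


def poo(occ: pd.DataFrame) -> pd.Series:
    """Percent of occurrence: per-taxon occurrences over total occurrences
    (sums to 1)."""
    occ = _check_table(occ)
    total = occ.to_numpy().sum()
    if total == 0:
        raise ValueError("no occurrences; POO undefined")
    out = occ.sum(axis=0) / total
    out.name = "POO"
    return out


def wpoo(occ: pd.DataFrame) -> pd.Series:
    """Weighted percent of occurrence: each sample gets weight 1 split
    equally among its detected taxa (sums to 1). Samples with zero items
    are dropped and S reduced accordingly."""
    occ = _drop_empty_samples(_check_table(occ), "wPOO")
    weights = occ.div(occ.sum(axis=1), axis=0)
    out = weights.mean(axis=0)
    out.name = "wPOO"
    return out


def rra(counts: pd.DataFrame) -> pd.Series:
    """Relative read abundance: mean across samples of per-sample read
    fractions, x100 (sums to 100). Zero-total samples are dropped; the
    upstream minimum-prey-reads filter should normally have removed them."""
    counts = _drop_empty_samples(_check_table(counts), "RRA")
    fracs = counts.div(counts.sum(axis=1), axis=0)
    out = fracs.mean(axis=0) * 100.0
    out.name = "RRA"
    return out


def per_sample_fraction(counts: pd.DataFrame, sample) -> pd.Series:
    """Read fractions of one sample: n[i,k] / sum_i n[i,k] (the
    DNA_diet_fraction field; x100 gives DNA_diet_percent)."""
    _check_table(counts)
    if sample not in counts.index:
        raise KeyError(f"sample {sample!r} not in table")
    row = counts.loc[sample].astype(float)
    total = row.sum()
    if total == 0:
        raise ValueError(f"sample {sample!r} has zero total reads")
    return row / total


def sample_fractions(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample read fractions for every sample (rows sum to 1)."""
    counts = _drop_empty_samples(_check_table(counts), "fractions")
    return counts.div(counts.sum(axis=1), axis=0)


def summarise(counts: pd.DataFrame) -> pd.DataFrame:
    """Tidy long-format table of all four indices (metric, taxon, value)."""
    occ = occurrence_table(counts)
    frames = []
    for series in (foo_percent(occ), poo(occ), wpoo(occ), rra(counts)):
        frames.append(
            pd.DataFrame(
                {"metric": series.name, "taxon": series.index, "value": series.values}
            )
        )
    return pd.concat(frames, ignore_index=True)
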