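"""Juvenile/adult apportionment of salmonid DNA percentages.

Salmon DNA in a scat says which species were eaten but not their life
stage, while salmon bones recovered from the same scat can be visually
classified as juvenile or adult. The apportionment rule splits each
sample's salmonid DNA percentage by a cascade of evidence:

1. **sample_bones** — the sample's own juvenile:adult classified-bone
   ratio (a sample with 5% Chinook DNA and a 1:1 bone ratio yields 2.5%
   juvenile + 2.5% adult);
2. **month_pool** — no classified bones in the sample: the ratio of bones
   pooled over the sample's collection month (per site by default, falling
   back to the all-site month pool);
3. **season** — no bones for the month either: a seasonal rule driven by
   salmon life history (spring months are runs of out-migrating juveniles,
   fall months adult spawners).

The split ratio is sample-level and applied uniformly to every salmonid
species' DNA percent in the sample. Juvenile + adult always equals the
input DNA percent exactly.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

JUVENILE, ADULT = "Juvenile", "Adult"
RULES = ("sample_bones", "month_pool", "season")

#: Month -> season class used when no bones exist for the collection month.
#: Spring (3-6) follows the juvenile out-migration; late summer through
#: winter (7-12, 1-2) follows the adult return runs. Overridable per call.
DEFAULT_SEASON_JUVENILE_MONTHS = frozenset({3, 4, 5, 6})


@dataclass(frozen=True)
class HardPartRecord:
    """One morphological prey identification from a scat sample."""

    sample_id: str
    prey_species: str
    salmon_classification: str | None = None  # Juvenile / Adult / None
    comments: str = ""
    analyst: str = ""

    def __post_init__(self):
        if self.salmon_classification not in (None, JUVENILE, ADULT):
            raise ValueError(
                f"salmon_classification must be Juvenile/Adult/None, "
                f"got {self.salmon_classification!r}"
            )


@dataclass(frozen=True)
class ApportionmentResult:
    sample_id: str
    species: str
    juvenile_percent: float
    adult_percent: float
    rule_used: str

    def __post_init__(self):
        if self.juvenile_percent < 0 or self.adult_percent < 0:
            raise ValueError("apportioned percentages must be nonnegative")
        if self.rule_used not in RULES:
            raise ValueError(f"unknown rule {self.rule_used!r}")


def _split(dna_percent: float, juvenile_share: float):
    juv = dna_percent * juvenile_share
    return juv, dna_percent - juv


def apportion_sample(
    dna_percent: float,
    sample_bones: tuple[int, int] | None,
    month_pool_bones: tuple[int, int] | None,
    month: int,
    *,
    sample_id: str = "",
    species: str = "",
    season_juvenile_months=DEFAULT_SEASON_JUVENILE_MONTHS,
) -> ApportionmentResult:
    """Split one salmonid DNA percentage into juvenile and adult parts.

    ``sample_bones`` and ``month_pool_bones`` are (juvenile, adult) counts
    of classified salmon bones, or None when unavailable; unclassified
    bones never enter the ratio. ``month`` is the collection month (1-12).
    """
    if dna_percent < 0:
        raise ValueError("dna_percent must be >= 0")
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    for bones in (sample_bones, month_pool_bones):
        if bones is not None and (bones[0] < 0 or bones[1] < 0):
            raise ValueError("bone counts must be nonnegative")

    if sample_bones is not None and sum(sample_bones) > 0:
        share = sample_bones[0] / sum(sample_bones)
        rule = "sample_bones"
    elif month_pool_bones is not None and sum(month_pool_bones) > 0:
        share = month_pool_bones[0] / sum(month_pool_bones)
        rule = "month_pool"
    else:
        share = 1.0 if month in season_juvenile_months else 0.0
        rule = "season"

    juv, adult = _split(dna_percent, share)
    return ApportionmentResult(sample_id, species, juv, adult, rule)


@dataclass
class ApportionmentTally:
    """How often each rule resolved a sample."""

    counts: Counter = field(default_factory=Counter)

    @property
    def fractions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        return {r: self.counts.get(r, 0) / total for r in RULES} if total else {}


def classified_bone_counts(
    hardparts: list[HardPartRecord],
) -> dict[str, tuple[int, int]]:
    """(juvenile, adult) classified salmon bone counts per sample."""
    out: dict[str, list[int]] = {}
    for rec in hardparts:
        if rec.salmon_classification is None:
            continue
        pair = out.setdefault(rec.sample_id, [0, 0])
        pair[0 if rec.salmon_classification == JUVENILE else 1] += 1
    return {k: (v[0], v[1]) for k, v in out.items()}


def apportion_dataset(
    diet: pd.DataFrame,
    hardparts: list[HardPartRecord],
    *,
    pool_by_site: bool = True,
    season_juvenile_months=DEFAULT_SEASON_JUVENILE_MONTHS,
) -> tuple[pd.DataFrame, ApportionmentTally]:
    """Apportion every salmonid diet row of a dataset.

    ``diet`` needs columns sample_ID, prey_ID, DNA_diet_percent, month and
    (when ``pool_by_site``) site. Monthly pools are built per (site, month)
    of the samples carrying classified bones, falling back to the all-site
    month pool when a site-month has none. Returns the per-row results and
    a tally of which rule resolved each *sample*.
    """
    required = {"sample_ID", "prey_ID", "DNA_diet_percent", "month"}
    missing = required - set(diet.columns)
    if missing:
        raise ValueError(f"diet table missing columns: {sorted(missing)}")

    per_sample = classified_bone_counts(hardparts)

    sample_meta = diet.drop_duplicates("sample_ID").set_index("sample_ID")
    month_pools: dict[tuple, list[int]] = {}
    site_month_pools: dict[tuple, list[int]] = {}
    for sid, (j, a) in per_sample.items():
        if sid not in sample_meta.index:
            continue
        m = int(sample_meta.loc[sid, "month"])
        month_pools.setdefault((m,), [0, 0])
        month_pools[(m,)][0] += j
        month_pools[(m,)][1] += a
        if pool_by_site and "site" in sample_meta.columns:
            key = (sample_meta.loc[sid, "site"], m)
            site_month_pools.setdefault(key, [0, 0])
            site_month_pools[key][0] += j
            site_month_pools[key][1] += a

    results: list[ApportionmentResult] = []
    tally = ApportionmentTally()
    seen_samples: set[str] = set()
    for _, row in diet.iterrows():
        sid = row["sample_ID"]
        month = int(row["month"])
        bones = per_sample.get(sid)
        pool = None
        if pool_by_site and "site" in diet.columns:
            p = site_month_pools.get((row["site"], month))
            if p and sum(p) > 0:
                pool = (p[0], p[1])
        if pool is None:
            p = month_pools.get((month,))
            if p and sum(p) > 0:
                pool = (p[0], p[1])
        res = apportion_sample(
            float(row["DNA_diet_percent"]),
            bones,
            pool,
            month,
            sample_id=sid,
            species=row["prey_ID"],
            season_juvenile_months=season_juvenile_months,
        )
        results.append(res)
        if sid not in seen_samples:
            seen_samples.add(sid)
            tally.counts[res.rule_used] += 1

    frame = pd.DataFrame(
        [
            {
                "sample_ID": r.sample_id,
                "prey_ID": r.species,
                "juvenile_percent": r.juvenile_percent,
                "adult_percent": r.adult_percent,
                "rule_used": r.rule_used,
            }
            for r in results
        ]
    )
    return frame, tally
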