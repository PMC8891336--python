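"""Correction factors for amplification and digestion bias.

Read proportions are a biased index of diet biomass proportions: mDNA
density varies between prey species, primers bind preferentially, and
bioinformatic filters can favour one species' sequences. Three per-species
multiplicative correction factors address this:

* **TCF** (tissue correction factor) — from sequencing a tissue mixture of
  known composition: ``TCF_i = observed_fraction_i / known_fraction_i``;
* **RCF** (relative correction factor) — from 50/50 biomass mixtures of
  each test species with a fixed control species:
  ``RCF_test = reads_test / reads_control`` (1 under no bias; replicate
  mixtures aggregated by geometric mean; RCF of the control is 1 by
  definition);
* **DCF** (digestion correction factor) — supplied externally per species.

Correction divides read counts by the factor and renormalises per sample;
multiplying all factors by a constant therefore changes nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gmean

logger = logging.getLogger(__name__)

KINDS = ("TCF", "RCF", "DCF")


@dataclass
class CorrectionFactorSet:
    kind: str
    factors: dict[str, float]
    control_species: str | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if any(f <= 0 for f in self.factors.values()):
            raise ValueError("correction factors must be strictly positive")
        if self.kind == "RCF":
            if self.control_species is None:
                raise ValueError("RCF requires a control species")
            self.factors.setdefault(self.control_species, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": list(self.factors),
                "kind": self.kind,
                "factor": list(self.factors.values()),
                "is_control": [s == self.control_species for s in self.factors],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CorrectionFactorSet":
        df = pd.read_csv(path)
        kind = df["kind"].iloc[0]
        control = None
        if "is_control" in df.columns and df["is_control"].any():
            control = df.loc[df["is_control"], "species"].iloc[0]
        return cls(kind, dict(zip(df["species"], df["factor"])), control)


def compute_rcf(
    mixtures: pd.DataFrame,
    control_species: str,
) -> CorrectionFactorSet:
    """RCFs from 50/50 test+control mixture read counts.

    ``mixtures`` has one row per sequenced mixture with columns
    ``test_species``, ``test_reads``, ``control_reads``. Because the two
    species were present at equal biomass, the read ratio *is* the relative
    bias. Replicates of the same test species are aggregated by geometric
    mean (ratios are multiplicative).
    """
    required = {"test_species", "test_reads", "control_reads"}
    missing = required - set(mixtures.columns)
    if missing:
        raise ValueError(f"mixture table missing columns: {sorted(missing)}")
    if len(mixtures) == 0:
        raise ValueError("no mixtures supplied")
    if (mixtures["control_reads"] <= 0).any():
        raise ValueError("zero control reads in a mixture; RCF undefined")
    if (mixtures["test_reads"] <= 0).any():
        raise ValueError("zero test reads in a mixture; RCF undefined")
    if (mixtures["test_species"] == control_species).any():
        raise ValueError("control species cannot be its own test species")

    ratios = mixtures["test_reads"] / mixtures["control_reads"]
    factors = (
        ratios.groupby(mixtures["test_species"]).apply(lambda s: float(gmean(s)))
    ).to_dict()
    factors[control_species] = 1.0
    return CorrectionFactorSet("RCF", factors, control_species)


def compute_tcf(
    observed_fractions: pd.Series | dict,
    known_fractions: pd.Series | dict,
) -> CorrectionFactorSet:
    """TCFs from a sequenced mixture of known composition:
    TCF_i = observed_i / known_i over species present in the mixture."""
    obs = pd.Series(observed_fractions, dtype=float)
    known = pd.Series(known_fractions, dtype=float)
    factors: dict[str, float] = {}
    for sp in known.index:
        k = known[sp]
        o = float(obs.get(sp, 0.0))
        if k == 0:
            if o > 0:
                raise ValueError(
                    f"{sp}: observed reads but zero known fraction; TCF undefined"
                )
            continue
        if o <= 0:
            raise ValueError(f"{sp}: no observed reads; TCF undefined")
        factors[sp] = o / k
    return CorrectionFactorSet("TCF", factors)


def apply_correction(
    counts: pd.DataFrame,
    cf: CorrectionFactorSet,
) -> pd.DataFrame:
    """Correct a samples x taxa count table and renormalise per sample.

    corrected_count = n / factor; species without a factor keep factor 1
    (with a warning). Returns per-sample fractions (rows sum to 1).
    """
    factors = pd.Series(1.0, index=counts.columns, dtype=float)
    missing = [t for t in counts.columns if t not in cf.factors]
    if missing:
        logger.warning("no %s factor for %s; using 1.0", cf.kind, missing)
    for sp, f in cf.factors.items():
        if f <= 0:
            raise ValueError(f"nonpositive factor for {sp}")
        if sp in factors.index:
            factors[sp] = f
    corrected = counts.div(factors, axis=1)
    totals = corrected.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("sample with zero total corrected reads")
    return corrected.div(totals, axis=0)
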