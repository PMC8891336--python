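"""Readers and writers for the published diet-data file schemas.

The primary dataset is a long-format CSV with one row per (sample, prey)
identification carrying collection metadata, per-marker read counts and
the per-sample DNA diet fraction/percent; hard-part identifications live
in a five-field companion CSV. Prey species indistinguishable at the
marker appear as a single merged ID joined with "OR". Validation of the
published files (record, site and species counts) is supported when the
files are locally present, and skipped with a notice otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .lifestage import HardPartRecord

logger = logging.getLogger(__name__)

DIET_COLUMNS = [
    "sample_ID", "site", "Lat", "Lon", "day", "month", "year", "predator",
    "prey_code", "prey_ID", "common_name", "count.16S", "count.COI",
    "DNA_diet_fraction", "DNA_diet_percent", "Lab", "Bioinformatician", "File",
]
REQUIRED_DIET_COLUMNS = [
    "sample_ID", "prey_ID", "count.16S", "DNA_diet_fraction", "DNA_diet_percent",
]
HARDPARTS_COLUMNS = [
    "Sample ID", "Prey Species", "Salmon classification", "Sample comments",
    "Analyst",
]


def prey_code(species: str) -> str:
    """Six-letter prey code: first three letters of genus + first three of
    species epithet, uppercased (e.g. Oncorhynchus_tshawytscha -> ONCTSH).
    OR-merged IDs code their alphabetically first member."""
    first = species.split("_OR_")[0]
    parts = [p for p in first.split("_") if p]
    if len(parts) >= 2:
        return (parts[0][:3] + parts[1][:3]).upper()
    return parts[0][:6].upper().ljust(6, "X")


def split_prey_id(prey_id: str) -> list[str]:
    """Member species of a possibly OR-merged prey identifier."""
    return [p for p in str(prey_id).split("_OR_") if p]


@dataclass
class ValidationReport:
    issues: list[str]

    @property
    def ok(self) -> bool:
        return not self.issues


def read_diet_csv(path) -> tuple[pd.DataFrame, ValidationReport]:
    """Read a diet CSV and check its row-level invariants.

    Violations (percent != 100 x fraction, month out of range, per-sample
    fractions not summing to 1) are collected in the report, not raised;
    missing required columns are fatal.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_DIET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"diet CSV missing required columns: {missing}")

    issues: list[str] = []
    if "DNA_diet_percent" in df.columns:
        bad = ~np.isclose(
            df["DNA_diet_percent"], 100.0 * df["DNA_diet_fraction"], atol=1e-6
        )
        for i in df.index[bad]:
            issues.append(
                f"row {i}: DNA_diet_percent != 100 x DNA_diet_fraction"
            )
    if "month" in df.columns:
        bad = ~df["month"].between(1, 12)
        for i in df.index[bad]:
            issues.append(f"row {i}: month {df.loc[i, 'month']} outside 1-12")
    sums = df.groupby("sample_ID")["DNA_diet_fraction"].sum()
    for sid, s in sums.items():
        if not np.isclose(s, 1.0, atol=1e-6):
            issues.append(f"sample {sid}: fractions sum to {s:.6f}, not 1")
    return df, ValidationReport(issues)


def write_diet_csv(df: pd.DataFrame, path) -> None:
    """Write a diet table in the published schema (canonical column order,
    comma-separated, UTF-8). Refuses to write rows violating the
    percent/fraction invariant."""
    missing = [c for c in REQUIRED_DIET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cannot write diet CSV; missing columns: {missing}")
    if len(df) and not np.allclose(
        df["DNA_diet_percent"], 100.0 * df["DNA_diet_fraction"], atol=1e-6
    ):
        raise ValueError("refusing to write: percent != 100 x fraction")
    cols = [c for c in DIET_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in DIET_COLUMNS
    ]
    df[cols].to_csv(path, index=False, encoding="utf-8")


def read_hardparts_csv(path) -> list[HardPartRecord]:
    """Read the five-field hard-parts CSV into records."""
    df = pd.read_csv(path)
    missing = [c for c in HARDPARTS_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"hardparts CSV missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        cls = row.get("Salmon classification")
        if pd.isna(cls) or cls == "":
            cls = None
        comments = row.get("Sample comments", "")
        records.append(
            HardPartRecord(
                sample_id=str(row["Sample ID"]),
                prey_species=str(row["Prey Species"]),
                salmon_classification=cls,
                comments="" if pd.isna(comments) else str(comments),
                analyst=str(row.get("Analyst", "")),
            )
        )
    return records


def write_hardparts_csv(records: list[HardPartRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "Sample ID": r.sample_id,
                "Prey Species": r.prey_species,
                "Salmon classification": r.salmon_classification or "",
                "Sample comments": r.comments,
                "Analyst": r.analyst,
            }
            for r in records
        ],
        columns=HARDPARTS_COLUMNS,
    ).to_csv(path, index=False, encoding="utf-8")


def diet_records_from_fractions(
    fractions: pd.DataFrame,
    counts_16s: pd.DataFrame | None = None,
    counts_coi: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
    predator: str = "Harbour seal",
    lab: str = "synthetic",
    bioinformatician: str = "synthetic",
    source_file: str = "synthetic.csv",
) -> pd.DataFrame:
    """Assemble a published-schema diet table from a samples x taxa
    fraction table (plus optional per-marker counts and sample metadata).
    Zero-fraction cells are omitted, matching the long format of the
    published file."""
    rows = []
    for sample in fractions.index:
        for taxon in fractions.columns:
            f = float(fractions.loc[sample, taxon])
            if f <= 0:
                continue
            row = {
                "sample_ID": sample,
                "predator": predator,
                "prey_code": prey_code(str(taxon)),
                "prey_ID": taxon,
                "common_name": str(taxon).replace("_", " "),
                "count.16S": (
                    int(counts_16s.loc[sample, taxon])
                    if counts_16s is not None and taxon in counts_16s.columns
                    and sample in counts_16s.index else 0
                ),
                "count.COI": (
                    int(counts_coi.loc[sample, taxon])
                    if counts_coi is not None and taxon in counts_coi.columns
                    and sample in counts_coi.index else 0
                ),
                "DNA_diet_fraction": f,
                "DNA_diet_percent": 100.0 * f,
                "Lab": lab,
                "Bioinformatician": bioinformatician,
                "File": source_file,
            }
            if metadata is not None and sample in metadata.index:
                for col in ("site", "year", "month", "day", "Lat", "Lon"):
                    if col in metadata.columns:
                        row[col] = metadata.loc[sample, col]
            rows.append(row)
    return pd.DataFrame(rows)


def validate_published_dataset(
    diet_csv=None, hardparts_csv=None, prey_fasta=None
) -> dict:
    """Summary counts over the published (or pipeline-produced) files.

    Reports unique samples, sites, years, months, prey-identification rows,
    species counts in the reference FASTA, and the fraction of DNA samples
    with corresponding hard-part records. Absent files are skipped with a
    notice; an empty dict means nothing was available.
    """
    summary: dict = {}
    diet = None
    if diet_csv is not None and Path(diet_csv).exists():
        diet, _ = read_diet_csv(diet_csv)
        summary["n_prey_identifications"] = int(len(diet))
        summary["n_samples"] = int(diet["sample_ID"].nunique())
        if "site" in diet.columns:
            summary["n_sites"] = int(diet["site"].nunique())
        if "year" in diet.columns:
            summary["n_years"] = int(diet["year"].nunique())
        if "month" in diet.columns:
            summary["n_months"] = int(diet["month"].nunique())
    elif diet_csv is not None:
        logger.info("diet CSV %s not found; skipping", diet_csv)

    if hardparts_csv is not None and Path(hardparts_csv).exists():
        records = read_hardparts_csv(hardparts_csv)
        summary["n_hardpart_rows"] = len(records)
        hp_samples = {r.sample_id for r in records}
        summary["n_hardpart_samples"] = len(hp_samples)
        if diet is not None:
            dna = set(diet["sample_ID"])
            summary["hardparts_coverage"] = (
                len(dna & hp_samples) / len(dna) if dna else 0.0
            )
    elif hardparts_csv is not None:
        logger.info("hardparts CSV %s not found; skipping", hardparts_csv)

    if prey_fasta is not None and Path(prey_fasta).exists():
        from .refdb import ReferenceDB

        db = ReferenceDB.from_fasta(prey_fasta)
        summary["n_reference_sequences"] = len(db)
        summary["n_reference_species"] = len(db.species)
    elif prey_fasta is not None:
        logger.info("prey FASTA %s not found; skipping", prey_fasta)
    return summary
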