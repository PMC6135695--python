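"""Pyrosequencing allele-quantification to hotspot mutation calls.

Loci are the BRAF c.1799 and KRAS c.34/35/37/38 hotspots.  A locus is called
mutant when its mutant-allele percentage is at or above the cutoff (default
20%), wildtype below it, and not evaluable when the sample's tumor cell
content is known and below the minimum (default 40%) — an allele fraction
from a dilute tumor cannot be interpreted against a fixed cutoff.  A gene is
mutant when any of its evaluable loci is mutant, wildtype when all evaluable
loci are wildtype.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import InputError

__all__ = [
    "LOCI",
    "LOCUS_GENE",
    "AlleleQuantification",
    "call_mutation",
    "aggregate_sample_status",
    "call_sample_genes",
    "read_allele_quantifications",
    "mutation_status_table",
]

LOCI = ("BRAF_1799", "KRAS_34", "KRAS_35", "KRAS_37", "KRAS_38")
LOCUS_GENE = {locus: locus.split("_")[0] for locus in LOCI}


@dataclasses.dataclass(frozen=True)
class AlleleQuantification:
    """One pyrosequencing readout: percent mutant allele at one hotspot."""

    sample_id: str
    locus: str
    fraction_percent: float
    tumor_content_percent: float | None = None

    def __post_init__(self):
        if self.locus not in LOCI:
            raise InputError(f"unknown locus {self.locus!r}; expected one of {LOCI}")
        if not 0.0 <= self.fraction_percent <= 100.0:
            raise InputError(
                f"allele fraction {self.fraction_percent} outside [0, 100] "
                f"for sample {self.sample_id!r}")
        if self.tumor_content_percent is not None and not 0.0 < self.tumor_content_percent <= 100.0:
            raise InputError(
                f"tumor content {self.tumor_content_percent} outside (0, 100] "
                f"for sample {self.sample_id!r}")


def call_mutation(aq: AlleleQuantification,
                  cutoff_percent: float = 20.0,
                  min_tumor_content: float = 40.0) -> str:
    """Per-locus call: 'mutant' (fraction >= cutoff, inclusive), 'wildtype', or 'not_evaluable'."""
    if aq.tumor_content_percent is not None and aq.tumor_content_percent < min_tumor_content:
        return "not_evaluable"
    return "mutant" if aq.fraction_percent >= cutoff_percent else "wildtype"


def aggregate_sample_status(calls: Iterable[str]) -> str:
    """Gene-level status: mutant if any locus mutant; wildtype if all evaluable wildtype."""
    calls = list(calls)
    if not calls:
        raise InputError("no locus calls to aggregate")
    bad = [c for c in calls if c not in ("mutant", "wildtype", "not_evaluable")]
    if bad:
        raise InputError(f"unknown call status {bad[0]!r}")
    if "mutant" in calls:
        return "mutant"
    if any(c == "wildtype" for c in calls):
        return "wildtype"
    return "not_evaluable"


def call_sample_genes(quantifications: Sequence[AlleleQuantification],
                      cutoff_percent: float = 20.0,
                      min_tumor_content: float = 40.0) -> dict[str, str]:
    """Per-gene status for one sample's quantifications."""
    by_gene: dict[str, list[str]] = {}
    for aq in quantifications:
        by_gene.setdefault(LOCUS_GENE[aq.locus], []).append(
            call_mutation(aq, cutoff_percent, min_tumor_content))
    return {gene: aggregate_sample_status(calls) for gene, calls in sorted(by_gene.items())}


def read_allele_quantifications(path: str | Path, sep: str = "\t") -> list[AlleleQuantification]:
    """Read a TSV with columns sample_id, locus, fraction_percent[, tumor_content_percent]."""
    table = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "locus": str})
    required = {"sample_id", "locus", "fraction_percent"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"allele quantification file missing columns: {sorted(missing)}")
    out = []
    for _, row in table.iterrows():
        content = row.get("tumor_content_percent")
        content = None if pd.isna(content) else float(content)
        out.append(AlleleQuantification(sample_id=str(row["sample_id"]), locus=str(row["locus"]),
                                        fraction_percent=float(row["fraction_percent"]),
                                        tumor_content_percent=content))
    return out


def mutation_status_table(quantifications: Sequence[AlleleQuantification],
                          cutoff_percent: float = 20.0,
                          min_tumor_content: float = 40.0) -> pd.DataFrame:
    """Per-sample KRAS/BRAF status table (columns kras_status, braf_status)."""
    by_sample: dict[str, list[AlleleQuantification]] = {}
    for aq in quantifications:
        by_sample.setdefault(aq.sample_id, []).append(aq)
    rows = {}
    for sample, aqs in sorted(by_sample.items()):
        genes = call_sample_genes(aqs, cutoff_percent, min_tumor_content)
        rows[sample] = {"kras_status": genes.get("KRAS", "unknown"),
                        "braf_status": genes.get("BRAF", "unknown")}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out
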