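"""Domain containers and tabular/sequence readers shared by every pipeline stage.

The universal currency is the :class:`BetaMatrix`: a probe x sample matrix of
Infinium methylation beta-values (methylated-signal fraction in [0, 1]), with
``NaN`` marking missing measurements (e.g. detection failures).  Probe context
(gene, TSS distance, 500-bp window / CpG score) travels as a plain pandas
DataFrame validated by :func:`read_annotation`; sample phenotype as a DataFrame
validated by :func:`read_metadata`.

All on-disk formats are delimiter-separated text (tab by default, comma via
``sep=','``); coordinates are 1-based fully closed, following the Infinium
manifest convention.  Readers reject malformed input with a diagnostic naming
the offending row/column; they never silently coerce.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BetaMatrix",
    "PipelineConfig",
    "InputError",
    "ANNOTATION_COLUMNS",
    "METADATA_COLUMNS",
    "COHORTS",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_annotation",
    "write_annotation",
    "read_metadata",
    "write_metadata",
    "read_fasta_windows",
    "write_fasta_windows",
]


class InputError(ValueError):
    """Malformed or inconsistent input data."""


ANNOTATION_COLUMNS = ("probe_id", "chromosome", "position", "gene", "tss_position", "strand")
METADATA_COLUMNS = ("sample_id", "cohort", "preparation", "location", "histology",
                    "kras_status", "braf_status")

COHORTS = frozenset({"FAP", "sporadic_CRC", "sporadic_adenoma", "normal"})
PREPARATIONS = frozenset({"frozen", "FFPE"})
LOCATIONS = frozenset({"proximal", "distal", "unknown"})
HISTOLOGIES = frozenset({"adenoma", "cancer", "SSA", "normal"})
MUTATION_STATUSES = frozenset({"mutant", "wildtype", "unknown"})

WINDOW_LENGTH = 500
_WINDOW_ALPHABET = frozenset("ACGTN")


class BetaMatrix:
    """Probe x sample matrix of methylation beta-values.

    Parameters
    ----------
    values
        DataFrame with probe ids as index, sample ids as columns, float
        beta-values in [0, 1]; ``NaN`` encodes a missing measurement.

    Raises
    ------
    InputError
        On duplicate probe/sample ids, non-numeric content, or values
        outside [0, 1].
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate probe ids: {dups[:5]}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise InputError(f"duplicate sample ids: {dups[:5]}")
        try:
            numeric = values.astype(float)
        except (TypeError, ValueError) as exc:
            raise InputError(f"non-numeric beta value: {exc}") from None
        bad = (numeric < 0.0) | (numeric > 1.0)
        if bad.any().any():
            probe = numeric.index[bad.any(axis=1)][0]
            sample = numeric.columns[bad.loc[probe]][0]
            raise InputError(
                f"beta value out of [0, 1] at probe {probe!r}, sample {sample!r}: "
                f"{numeric.loc[probe, sample]}"
            )
        numeric.index = numeric.index.astype(str)
        numeric.columns = numeric.columns.astype(str)
        numeric.index.name = "probe_id"
        self.values = numeric

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select_probes(self, probes: Iterable[str]) -> "BetaMatrix":
        probes = list(probes)
        missing = [p for p in probes if p not in self.values.index]
        if missing:
            raise InputError(f"unknown probe ids: {missing[:5]}")
        return BetaMatrix(self.values.loc[probes])

    def select_samples(self, samples: Iterable[str]) -> "BetaMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise InputError(f"unknown sample ids: {missing[:5]}")
        return BetaMatrix(self.values[samples])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BetaMatrix):
            return NotImplemented
        return self.values.equals(other.values)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"BetaMatrix({self.shape[0]} probes x {self.shape[1]} samples)"


def read_beta_matrix(path: str | Path | _stdio.StringIO, sep: str = "\t") -> BetaMatrix:
    """Read a probe x sample beta-value TSV (first column probe ids, header sample ids).

    Empty cells and ``NA`` become missing values; any other non-numeric cell,
    out-of-range value, ragged row or duplicate id is an :class:`InputError`.
    """
    # pandas silently renames duplicate header fields; check the raw header
    if hasattr(path, "read"):
        pos = path.tell()
        header_line = path.readline()
        path.seek(pos)
    else:
        with open(path) as handle:
            header_line = handle.readline()
    header = header_line.rstrip("\r\n").split(sep)[1:]
    dup_samples = {name for name in header if header.count(name) > 1}
    if dup_samples:
        raise InputError(f"duplicate sample ids: {sorted(dup_samples)[:5]}")
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                          na_values=["NA", ""], keep_default_na=False,
                          skip_blank_lines=False)
    except pd.errors.ParserError as exc:
        raise InputError(f"malformed beta matrix: {exc}") from None
    converted = {}
    for col in raw.columns:
        try:
            converted[col] = pd.to_numeric(raw[col])
        except (TypeError, ValueError):
            bad = raw[col][pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna()]
            raise InputError(
                f"non-numeric beta value in sample column {col!r}, "
                f"probe {bad.index[0]!r}: {bad.iloc[0]!r}"
            ) from None
    return BetaMatrix(pd.DataFrame(converted, index=raw.index))


def write_beta_matrix(matrix: BetaMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a :class:`BetaMatrix` as delimiter-separated text (missing as NA)."""
    matrix.values.to_csv(path, sep=sep, na_rep="NA", float_format="%.6g")


def _validate_windows(annotation: pd.DataFrame) -> None:
    if "window_sequence" not in annotation.columns:
        return
    for probe, seq in annotation["window_sequence"].dropna().items():
        if len(seq) != WINDOW_LENGTH:
            raise InputError(
                f"window for probe {probe!r} has length {len(seq)}, expected {WINDOW_LENGTH}"
            )
        extra = set(seq.upper()) - _WINDOW_ALPHABET
        if extra:
            raise InputError(f"window for probe {probe!r} has illegal characters {sorted(extra)}")


def read_annotation(path: str | Path, fasta_path: str | Path | None = None,
                    sep: str = "\t") -> pd.DataFrame:
    """Read probe annotation, optionally attaching 500-bp window sequences from FASTA.

    Returns a DataFrame indexed by ``probe_id`` with columns ``chromosome``,
    ``position``, ``gene``, ``tss_position``, ``strand`` and, when available,
    ``cpg_score`` and/or ``window_sequence``.  FASTA records are keyed by probe
    id; a record without a matching annotation row is an error, as is a window
    whose length is not exactly 500.
    """
    table = pd.read_csv(path, sep=sep, dtype={"probe_id": str, "gene": str})
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing_cols:
        raise InputError(f"annotation is missing mandatory columns: {missing_cols}")
    if table["probe_id"].duplicated().any():
        dups = table.loc[table["probe_id"].duplicated(), "probe_id"].tolist()
        raise InputError(f"duplicate probe ids in annotation: {dups[:5]}")
    bad_strand = ~table["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise InputError(f"invalid strand for probe {table.loc[bad_strand, 'probe_id'].iloc[0]!r}")
    table = table.set_index("probe_id")
    table["position"] = table["position"].astype(int)
    table["tss_position"] = table["tss_position"].astype(int)
    if "cpg_score" in table.columns:
        table["cpg_score"] = pd.to_numeric(table["cpg_score"])
    if fasta_path is not None:
        windows = read_fasta_windows(fasta_path)
        unknown = [pid for pid in windows if pid not in table.index]
        if unknown:
            raise InputError(f"FASTA records without annotation rows: {unknown[:5]}")
        table["window_sequence"] = pd.Series(windows, dtype=object).reindex(table.index)
    _validate_windows(table)
    return table


def write_annotation(annotation: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    out = annotation.drop(columns=["window_sequence"], errors="ignore")
    out.to_csv(path, sep=sep, na_rep="NA", float_format="%.6g")


def read_fasta_windows(path: str | Path) -> dict[str, str]:
    """Read a FASTA of probe window sequences keyed by probe id."""
    from Bio import SeqIO

    windows: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in windows:
            raise InputError(f"duplicate FASTA record {record.id!r}")
        windows[record.id] = str(record.seq).upper()
    return windows


def write_fasta_windows(windows: Mapping[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in windows.items()]
    seqio_write(records, str(path), "fasta")


def read_metadata(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read sample metadata; validates category levels and the normal-cohort rule."""
    table = pd.read_csv(path, sep=sep, dtype=str, na_values=[""], keep_default_na=False)
    missing_cols = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing_cols:
        raise InputError(f"metadata is missing mandatory columns: {missing_cols}")
    if table["sample_id"].duplicated().any():
        dups = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise InputError(f"duplicate sample ids in metadata: {dups[:5]}")
    table = table.set_index("sample_id")
    for col, levels in [("cohort", COHORTS), ("preparation", PREPARATIONS),
                        ("location", LOCATIONS), ("histology", HISTOLOGIES),
                        ("kras_status", MUTATION_STATUSES), ("braf_status", MUTATION_STATUSES)]:
        bad = ~table[col].isin(levels)
        if bad.any():
            sample = table.index[bad][0]
            raise InputError(
                f"invalid {col} {table.loc[sample, col]!r} for sample {sample!r}; "
                f"allowed: {sorted(levels)}"
            )
    inconsistent = (table["cohort"] == "normal") & (table["histology"] != "normal")
    if inconsistent.any():
        raise InputError(
            f"sample {table.index[inconsistent][0]!r}: cohort 'normal' requires histology 'normal'"
        )
    return table


def write_metadata(metadata: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    metadata.to_csv(path, sep=sep)


@dataclasses.dataclass
class PipelineConfig:
    """Analysis constants for the whole cascade.

    Attributes
    ----------
    delta_beta_threshold
        Frozen-vs-FFPE |delta beta| bound; a probe is pair-concordant when its
        difference is strictly below this (default 0.1).
    sd_threshold
        Across-sample beta SD (n-1 denominator) a probe must strictly exceed
        to enter clustering (default 0.10).
    cpg_score_threshold
        Observed/expected CpG ratio a selected promoter probe must strictly
        exceed for its gene to count as high-CpG (default 0.48).
    marker_beta_threshold
        Per-epigenotype mean beta at or above which a gene counts as
        methylated in that epigenotype (default 0.2).
    n_epigenotypes
        Number of flat sample clusters cut from the dendrogram (default 4).
    mutation_cutoff_percent
        Pyrosequencing mutant-allele percentage at or above which a locus is
        called mutant (default 20).
    min_tumor_content_percent
        Tumor cell content below which a sample's allele quantification is not
        evaluable (default 40).
    seed
        Single seed feeding every random draw in the package.
    """

    delta_beta_threshold: float = 0.1
    sd_threshold: float = 0.10
    cpg_score_threshold: float = 0.48
    marker_beta_threshold: float = 0.2
    n_epigenotypes: int = 4
    mutation_cutoff_percent: float = 20.0
    min_tumor_content_percent: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("delta_beta_threshold", "sd_threshold", "cpg_score_threshold",
                     "marker_beta_threshold", "mutation_cutoff_percent",
                     "min_tumor_content_percent"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be strictly positive")
        if self.n_epigenotypes < 2:
            raise InputError("n_epigenotypes must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle, sort_keys=True)
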