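"""On-disk artifacts: SEG segment files, matrix TSVs, variant and clinical tables.

All coordinates are normalized to 0-based half-open on read, so segment
length is always ``end - start``. Chromosome names are normalized by
stripping a leading ``chr``; sex chromosomes stay strings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SegDialect = Literal["zero_half_open", "one_closed"]
ValueKind = Literal["beta", "count", "rpm", "uq_normalized", "log_scaled"]

ER_LEVELS = ("positive", "negative", "unknown")
AGE_DECADES = ("<40", "40-49", "50-59", "60-69", "70+")
STAGES = ("I", "II", "III/IV")
T_SIZES = ("T1", "T2", "T3", "T4")
NODE_LEVELS = ("positive", "negative")
TUMOR_SUBTYPES = ("LumA", "LumB", "HER2", "Basal", "unknown")

VARIANT_COLUMNS = [
    "patient", "chrom", "pos", "ref", "alt",
    "t_ref", "t_alt", "b_ref", "b_alt", "n_ref", "n_alt",
    "rna_ref", "rna_alt",
]


class FieldscapeParseError(ValueError):
    """Malformed on-disk input (carries the offending line/field)."""


class FieldscapeValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


def normalize_chrom(chrom: str) -> str:
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


@dataclass(frozen=True, order=True)
class SegRecord:
    """One copy-number segment: 0-based half-open, seg_mean is a log2 ratio."""

    sample_id: str
    chrom: str
    start: int
    end: int
    seg_mean: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FieldscapeValidationError(
                f"segment start must precede end: {self.sample_id} "
                f"{self.chrom}:{self.start}-{self.end}"
            )
        if not math.isfinite(self.seg_mean):
            raise FieldscapeValidationError(
                f"non-finite seg_mean for {self.sample_id} {self.chrom}:{self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MatrixTable:
    """Features x samples abundance matrix with a declared value kind."""

    values: pd.DataFrame  # index = feature ids, columns = sample ids
    value_kind: ValueKind

    def __post_init__(self) -> None:
        idx, cols = self.values.index, self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FieldscapeValidationError(f"duplicated feature id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FieldscapeValidationError(f"duplicated sample id: {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if self.value_kind == "beta":
            bad = (arr < 0) | (arr > 1)
            if np.any(bad & np.isfinite(arr)):
                raise FieldscapeValidationError("beta values must lie in [0, 1]")
        elif self.value_kind in ("count", "rpm", "uq_normalized"):
            if np.any((arr < 0) & np.isfinite(arr)):
                raise FieldscapeValidationError(
                    f"{self.value_kind} values must be non-negative"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    er_status: str = "unknown"
    age_decade: str = "50-59"
    stage: str = "I"
    t_size: str = "T1"
    node_status: str = "negative"
    tumor_subtype: str = "unknown"
    time_years: float = 0.0
    event: bool = False

    def __post_init__(self) -> None:
        checks = [
            ("er_status", self.er_status, ER_LEVELS),
            ("age_decade", self.age_decade, AGE_DECADES),
            ("stage", self.stage, STAGES),
            ("t_size", self.t_size, T_SIZES),
            ("node_status", self.node_status, NODE_LEVELS),
            ("tumor_subtype", self.tumor_subtype, TUMOR_SUBTYPES),
        ]
        for name, value, levels in checks:
            if value not in levels:
                raise FieldscapeValidationError(
                    f"{name}={value!r} not in {levels} for patient {self.patient_id}"
                )
        if not math.isfinite(self.time_years) or self.time_years < 0:
            raise FieldscapeValidationError(
                f"time_years must be finite and >= 0 for patient {self.patient_id}"
            )


# ---------------------------------------------------------------------------
# SEG files


def read_seg(path: str | Path, dialect: SegDialect = "one_closed") -> list[SegRecord]:
    """Read a SEG file and normalize coordinates to 0-based half-open.

    Expected columns (tab-separated, header required): Sample, Chromosome,
    Start, End, optional Num_Probes, Segment_Mean. ``one_closed`` inputs
    (the common SEG export convention) have 1 subtracted from Start.
    """
    path = Path(path)
    records: list[SegRecord] = []
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise FieldscapeParseError(f"{path}: missing header row")
        ncol = len(header.rstrip("\n").split("\t"))
        if ncol < 5:
            raise FieldscapeParseError(f"{path}: expected >=5 tab-separated columns")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != ncol:
                raise FieldscapeParseError(
                    f"{path}:{lineno}: expected {ncol} fields, found {len(fields)}"
                )
            try:
                sample = fields[0]
                chrom = normalize_chrom(fields[1])
                start = int(fields[2])
                end = int(fields[3])
                seg_mean = float(fields[-1])
            except ValueError as exc:
                raise FieldscapeParseError(f"{path}:{lineno}: {exc}") from None
            if dialect == "one_closed":
                start -= 1
            try:
                records.append(SegRecord(sample, chrom, start, end, seg_mean))
            except FieldscapeValidationError as exc:
                raise FieldscapeValidationError(f"{path}:{lineno}: {exc}") from None
    records.sort(key=lambda r: (r.sample_id, r.chrom, r.start, r.end))
    _warn_overlaps(records, path)
    return records


def _warn_overlaps(records: Sequence[SegRecord], path: Path) -> None:
    prev: SegRecord | None = None
    for rec in records:
        if (
            prev is not None
            and rec.sample_id == prev.sample_id
            and rec.chrom == prev.chrom
            and rec.start < prev.end
        ):
            logger.warning(
                "%s: overlapping segments within one profile: %s %s:%d-%d and %d-%d",
                path, rec.sample_id, rec.chrom, prev.start, prev.end, rec.start, rec.end,
            )
        prev = rec


def write_seg(
    records: Iterable[SegRecord], path: str | Path, dialect: SegDialect = "one_closed"
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("Sample\tChromosome\tStart\tEnd\tSegment_Mean\n")
        for rec in sorted(records):
            start = rec.start + 1 if dialect == "one_closed" else rec.start
            fh.write(
                f"{rec.sample_id}\t{rec.chrom}\t{start}\t{rec.end}\t"
                f"{rec.seg_mean:.6f}\n"
            )


def group_by_sample(records: Iterable[SegRecord]) -> dict[str, list[SegRecord]]:
    grouped: dict[str, list[SegRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.sample_id, []).append(rec)
    return grouped


# ---------------------------------------------------------------------------
# Matrix TSVs


def read_matrix(
    path: str | Path,
    value_kind: ValueKind,
    na_policy: Literal["drop_feature", "error"] = "drop_feature",
) -> MatrixTable:
    """Read a features-x-samples TSV (first column feature ids, first row samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        n_bad = int(df.isna().any(axis=1).sum())
        if na_policy == "error":
            raise FieldscapeValidationError(f"{path}: {n_bad} features contain NA")
        logger.info("%s: dropping %d features with NA values", path, n_bad)
        df = df.dropna(axis=0)
    return MatrixTable(values=df.astype(float), value_kind=value_kind)


def write_matrix(table: MatrixTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", float_format="%.10g", index_label="feature")


# ---------------------------------------------------------------------------
# Variant tables


def read_variants(path: str | Path) -> pd.DataFrame:
    """Read a triplet pileup table; see VARIANT_COLUMNS for the schema.

    Counts are ref/alt reads per compartment: t (tumor), b (blood),
    n (adjacent normal), rna (adjacent RNA).
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient": str, "chrom": str, "ref": str, "alt": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FieldscapeParseError(f"{path}: missing variant columns {missing}")
    df = df[VARIANT_COLUMNS].copy()
    df["chrom"] = df["chrom"].map(normalize_chrom)
    count_cols = VARIANT_COLUMNS[5:]
    if (df[count_cols] < 0).any().any():
        raise FieldscapeValidationError(f"{path}: negative read counts")
    return df


def write_variants(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clinical tables

_CLINICAL_COLUMNS = [
    "patient_id", "er_status", "age_decade", "stage", "t_size",
    "node_status", "tumor_subtype", "time_years", "event",
]


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FieldscapeParseError(f"{path}: missing clinical columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ClinicalRecord(
                patient_id=row.patient_id,
                er_status=row.er_status,
                age_decade=row.age_decade,
                stage=row.stage,
                t_size=row.t_size,
                node_status=row.node_status,
                tumor_subtype=row.tumor_subtype,
                time_years=float(row.time_years),
                event=str(row.event).strip().lower() in ("1", "true", "yes"),
            )
        )
    return records


def write_clinical(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "er_status": r.er_status,
            "age_decade": r.age_decade,
            "stage": r.stage,
            "t_size": r.t_size,
            "node_status": r.node_status,
            "tumor_subtype": r.tumor_subtype,
            "time_years": f"{r.time_years:.6f}",
            "event": int(r.event),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)


def clinical_to_frame(records: Iterable[ClinicalRecord]) -> pd.DataFrame:
    """Clinical records as a DataFrame indexed by patient id."""
    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "er_status": r.er_status,
                "age_decade": r.age_decade,
                "stage": r.stage,
                "t_size": r.t_size,
                "node_status": r.node_status,
                "tumor_subtype": r.tumor_subtype,
                "time_years": r.time_years,
                "event": bool(r.event),
            }
            for r in records
        ]
    )
    return df.set_index("patient_id")
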