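"""Reading and writing clonotype tables and subject metadata.

Two on-disk dialects are supported:

* **AIRR** — the AIRR Rearrangement TSV schema (``sequence_id``,
  ``duplicate_count``, ``junction``, ``junction_aa``, ``v_call``, ``d_call``,
  ``j_call``, ``productive`` plus optional junction-relative coordinate
  columns).
* **legacy** — an 11-column tab-delimited clonotype dialect
  (count, freq, cdr3nt, cdr3aa, v, d, j, VEnd, DStart, DEnd, JStart) as
  emitted by classic repertoire post-processing tools.

Gene calls are normalised to segment level: allele suffixes (``*01``) are
stripped and multi-call fields keep the first call.  Frequencies are always
recomputed from counts at ingestion; stored frequency columns are advisory.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .types import (
    ClonotypeRecord,
    Cohort,
    EmptyRepertoireError,
    IntegrityError,
    RepertoireSample,
    SchemaError,
    SubjectRecord,
)

log = logging.getLogger(__name__)

__all__ = [
    "normalize_gene_call",
    "parse_airr",
    "parse_legacy_table",
    "write_clonotype_table",
    "read_subjects",
    "write_subjects",
    "attach_metadata",
]

AIRR_REQUIRED = ["duplicate_count", "junction", "junction_aa", "v_call", "d_call", "j_call"]
AIRR_COLUMNS = [
    "sequence_id",
    "duplicate_count",
    "junction",
    "junction_aa",
    "v_call",
    "d_call",
    "j_call",
    "productive",
    "v_sequence_end",
    "d_sequence_start",
    "d_sequence_end",
    "j_sequence_start",
]
LEGACY_COLUMNS = [
    "count",
    "freq",
    "cdr3nt",
    "cdr3aa",
    "v",
    "d",
    "j",
    "VEnd",
    "DStart",
    "DEnd",
    "JStart",
]
SUBJECT_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "pasi",
    "duration_years",
    "cmv_igg",
    "cmv_status",
]


def normalize_gene_call(call: object) -> Optional[str]:
    """Truncate a V/D/J call at the allele separator '*' and keep the first
    call of a comma-separated list.  Empty-ish values ('', '.', NaN) map to
    ``None``."""
    if call is None or (isinstance(call, float) and pd.isna(call)):
        return None
    text = str(call).strip()
    if text in ("", ".", "nan", "None"):
        return None
    first = text.split(",")[0].strip()
    return first.split("*")[0]


def _finalize(
    records: list[ClonotypeRecord], sample_meta: dict, path: object
) -> RepertoireSample:
    sample = RepertoireSample(
        sample_id=sample_meta["sample_id"],
        subject_id=sample_meta.get("subject_id", sample_meta["sample_id"]),
        tissue=sample_meta.get("tissue", "blood"),
        chain=sample_meta.get("chain", "TRG"),
        clonotypes=records,
        off_target_reads=int(sample_meta.get("off_target_reads", 0)),
    )
    if not records:
        raise EmptyRepertoireError(f"{path}: no clonotype rows")
    sample.recompute_frequencies()
    return sample


def parse_airr(path: str | Path, sample_meta: dict) -> RepertoireSample:
    """Read one AIRR Rearrangement TSV into a :class:`RepertoireSample`.

    ``sample_meta`` supplies the library descriptor: ``sample_id`` (required),
    ``subject_id``, ``tissue``, ``chain``, ``off_target_reads``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in AIRR_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing AIRR columns {missing}")

    def coord(row: pd.Series, col: str) -> int:
        val = row.get(col, "")
        if val in ("", ".", None):
            return -1
        return int(float(val))

    records: list[ClonotypeRecord] = []
    for _, row in df.iterrows():
        v = normalize_gene_call(row["v_call"])
        j = normalize_gene_call(row["j_call"])
        if v is None or j is None:
            raise SchemaError(f"{path}: row with missing v_call/j_call")
        rec = ClonotypeRecord(
            count=int(float(row["duplicate_count"])),
            frequency=0.0,
            cdr3_nt=str(row["junction"]),
            cdr3_aa=str(row["junction_aa"]),
            v_gene=v,
            d_gene=normalize_gene_call(row["d_call"]),
            j_gene=j,
            v_end=coord(row, "v_sequence_end"),
            d_start=coord(row, "d_sequence_start"),
            d_end=coord(row, "d_sequence_end"),
            j_start=coord(row, "j_sequence_start"),
        )
        prod = str(row.get("productive", "")).strip().upper()
        rec.functional = rec.is_functional() if prod in ("", ".") else prod in ("T", "TRUE")
        records.append(rec)
    return _finalize(records, sample_meta, path)


def parse_legacy_table(path: str | Path, sample_meta: dict) -> RepertoireSample:
    """Read the 11-column legacy clonotype dialect."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in LEGACY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing legacy columns {missing}")
    records: list[ClonotypeRecord] = []
    freq_mismatch = False
    raw: list[tuple[int, float]] = []
    for i, row in df.iterrows():
        try:
            count = int(row["count"])
        except ValueError as exc:
            raise SchemaError(f"{path}: non-integer count at row {i + 2}") from exc
        v = normalize_gene_call(row["v"])
        j = normalize_gene_call(row["j"])
        if v is None or j is None:
            raise SchemaError(f"{path}: missing V/J call at row {i + 2}")
        rec = ClonotypeRecord(
            count=count,
            frequency=0.0,
            cdr3_nt=str(row["cdr3nt"]),
            cdr3_aa=str(row["cdr3aa"]),
            v_gene=v,
            d_gene=normalize_gene_call(row["d"]),
            j_gene=j,
            v_end=int(row["VEnd"]),
            d_start=int(row["DStart"]),
            d_end=int(row["DEnd"]),
            j_start=int(row["JStart"]),
        )
        rec.functional = rec.is_functional()
        records.append(rec)
        raw.append((count, float(row["freq"]) if row["freq"] not in ("", ".") else -1.0))
    sample = _finalize(records, sample_meta, path)
    total = sample.total_reads
    for (count, stored), rec in zip(raw, sample.clonotypes):
        if stored >= 0 and abs(stored - count / total) > 1e-6:
            freq_mismatch = True
    if freq_mismatch:
        log.warning(
            "%s: stored frequency column disagrees with counts; frequencies recomputed",
            path,
        )
    return sample


def write_clonotype_table(
    sample: RepertoireSample, path: str | Path, dialect: str = "airr"
) -> None:
    """Write a sample so that the matching parser round-trips it field-identically.

    An empty clonotype list produces a header-only file.
    """
    if dialect == "airr":
        rows = []
        for i, c in enumerate(sample.clonotypes):
            rows.append(
                {
                    "sequence_id": f"{sample.sample_id}-{i + 1}",
                    "duplicate_count": c.count,
                    "junction": c.cdr3_nt,
                    "junction_aa": c.cdr3_aa,
                    "v_call": c.v_gene,
                    "d_call": c.d_gene if c.d_gene is not None else "",
                    "j_call": c.j_gene,
                    "productive": "T" if c.functional else "F",
                    "v_sequence_end": c.v_end,
                    "d_sequence_start": c.d_start,
                    "d_sequence_end": c.d_end,
                    "j_sequence_start": c.j_start,
                }
            )
        df = pd.DataFrame(rows, columns=AIRR_COLUMNS)
    elif dialect == "legacy":
        rows = []
        for c in sample.clonotypes:
            rows.append(
                {
                    "count": c.count,
                    "freq": repr(c.frequency),
                    "cdr3nt": c.cdr3_nt,
                    "cdr3aa": c.cdr3_aa,
                    "v": c.v_gene,
                    "d": c.d_gene if c.d_gene is not None else ".",
                    "j": c.j_gene,
                    "VEnd": c.v_end,
                    "DStart": c.d_start,
                    "DEnd": c.d_end,
                    "JStart": c.j_start,
                }
            )
        df = pd.DataFrame(rows, columns=LEGACY_COLUMNS)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df.to_csv(path, sep="\t", index=False)


def read_subjects(path: str | Path) -> dict[str, SubjectRecord]:
    """Read the subject-metadata TSV (subject_id, group, age, sex, pasi,
    duration_years, cmv_igg, cmv_status)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("subject_id", "group", "age", "sex") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing subject columns {missing}")
    subjects: dict[str, SubjectRecord] = {}

    def opt_float(val: str) -> Optional[float]:
        return None if val in ("", ".", "NA") else float(val)

    for _, row in df.iterrows():
        sid = row["subject_id"]
        if sid in subjects:
            raise IntegrityError(f"{path}: duplicate subject_id {sid}")
        subjects[sid] = SubjectRecord(
            subject_id=sid,
            group=row["group"],
            age=float(row["age"]),
            sex=row["sex"],
            pasi=opt_float(row.get("pasi", "")),
            duration=opt_float(row.get("duration_years", "")),
            cmv_igg=opt_float(row.get("cmv_igg", "")),
            cmv_status=row.get("cmv_status", "unknown") or "unknown",
        )
    return subjects


def write_subjects(subjects: dict[str, SubjectRecord], path: str | Path) -> None:
    rows = []
    for s in subjects.values():
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
                "pasi": "" if s.pasi is None else s.pasi,
                "duration_years": "" if s.duration is None else s.duration,
                "cmv_igg": "" if s.cmv_igg is None else s.cmv_igg,
                "cmv_status": s.cmv_status,
            }
        )
    pd.DataFrame(rows, columns=SUBJECT_COLUMNS).to_csv(path, sep="\t", index=False)


def attach_metadata(
    samples: Sequence[RepertoireSample], subjects: dict[str, SubjectRecord]
) -> Cohort:
    """Join samples to subjects.  Every sample's subject must exist; a PV
    subject without a PASI score is kept with a warning (scores can be missing
    at sampling time)."""
    unmatched = sorted({s.subject_id for s in samples} - set(subjects))
    if unmatched:
        raise IntegrityError(f"samples reference unknown subjects: {unmatched}")
    for sub in subjects.values():
        if sub.group == "PV" and sub.pasi is None:
            log.warning("subject %s is PV without a PASI score", sub.subject_id)
    return Cohort(samples=list(samples), subjects=dict(subjects))
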