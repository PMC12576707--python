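"""Core domain types for gamma/delta TCR repertoire analysis.

A *clonotype* is a unique rearranged receptor sequence, keyed here by its V
segment, J segment and CDR3 (nucleotide or amino acid).  A *repertoire sample*
is one sequencing library (one subject, one tissue, one chain) holding the
clonotype table for that library.  Subjects carry the clinical covariates used
by the association stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

__all__ = [
    "ClonotypeRecord",
    "RepertoireSample",
    "SubjectRecord",
    "Cohort",
    "SchemaError",
    "EmptyRepertoireError",
    "IntegrityError",
    "UndefinedValueError",
    "TISSUES",
    "CHAINS",
]

TISSUES = ("blood", "skin")
CHAINS = ("TRG", "TRD")

STOP_MARKERS = ("*", "_")


class SchemaError(ValueError):
    """A clonotype table is missing required columns or is malformed."""


class EmptyRepertoireError(ValueError):
    """A clonotype table contains no rows."""


class IntegrityError(ValueError):
    """Sample/subject metadata violates a uniqueness or matching constraint."""


class UndefinedValueError(ValueError):
    """A statistic is undefined for the given input (e.g. empty repertoire)."""


@dataclass(slots=True)
class ClonotypeRecord:
    """One rearrangement: read count, CDR3 in both units, segment calls and
    junction coordinates.

    Coordinates are 0-based, half-open, relative to ``cdr3_nt``; ``-1`` encodes
    "undefined".  ``d_gene`` is ``None`` when no D segment was called (always
    the case for TRG).
    """

    count: int
    frequency: float
    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    d_gene: Optional[str]
    j_gene: str
    v_end: int = -1
    d_start: int = -1
    d_end: int = -1
    j_start: int = -1
    functional: bool = True

    def is_functional(self) -> bool:
        """In-frame and free of stop codons.

        Used when the source table carries no productive flag: the CDR3 must be
        a whole number of codons and the amino-acid junction must contain no
        stop ('*') or frameshift ('_') marker.
        """
        if len(self.cdr3_nt) % 3 != 0:
            return False
        return not any(m in self.cdr3_aa for m in STOP_MARKERS)

    def copy(self) -> "ClonotypeRecord":
        return replace(self)


@dataclass(slots=True)
class RepertoireSample:
    """One sequencing library: a clonotype table plus its provenance.

    ``off_target_reads`` counts TRA/TRB reads observed in the library; it is
    used only for library-level QC and contributes nothing to ``total_reads``.
    """

    sample_id: str
    subject_id: str
    tissue: str
    chain: str
    clonotypes: list[ClonotypeRecord] = field(default_factory=list)
    off_target_reads: int = 0

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.chain not in CHAINS:
            raise ValueError(f"unknown chain {self.chain!r}")

    @property
    def total_reads(self) -> int:
        return sum(c.count for c in self.clonotypes)

    @property
    def n_clonotypes(self) -> int:
        return len(self.clonotypes)

    def recompute_frequencies(self) -> None:
        """Force ``frequency = count / total_reads``; stored frequency columns
        are advisory only."""
        total = self.total_reads
        if total == 0:
            for c in self.clonotypes:
                c.frequency = 0.0
            return
        for c in self.clonotypes:
            c.frequency = c.count / total

    def frequencies(self) -> list[float]:
        return [c.frequency for c in self.clonotypes]

    def counts(self) -> list[int]:
        return [c.count for c in self.clonotypes]

    def copy(self) -> "RepertoireSample":
        return RepertoireSample(
            sample_id=self.sample_id,
            subject_id=self.subject_id,
            tissue=self.tissue,
            chain=self.chain,
            clonotypes=[c.copy() for c in self.clonotypes],
            off_target_reads=self.off_target_reads,
        )

    def validate(self) -> None:
        """Check the structural invariants of an ingested sample."""
        total = self.total_reads
        seen: set[tuple[str, str, str]] = set()
        for c in self.clonotypes:
            if c.count < 1:
                raise IntegrityError(
                    f"{self.sample_id}: clonotype with count {c.count} < 1"
                )
            if total and abs(c.frequency - c.count / total) > 1e-9:
                raise IntegrityError(
                    f"{self.sample_id}: frequency of {c.cdr3_nt} inconsistent with counts"
                )
            key = (c.v_gene, c.cdr3_nt, c.j_gene)
            if key in seen:
                raise IntegrityError(f"{self.sample_id}: duplicate clonotype {key}")
            seen.add(key)
            coords = [x for x in (c.v_end, c.d_start, c.d_end, c.j_start) if x >= 0]
            if coords != sorted(coords) or (coords and coords[-1] > len(c.cdr3_nt)):
                raise IntegrityError(
                    f"{self.sample_id}: junction coordinates out of order for {c.cdr3_nt}"
                )


@dataclass(slots=True)
class SubjectRecord:
    """Clinical covariates for one study participant.

    PV (psoriasis vulgaris) subjects may carry a PASI score and disease
    duration; healthy controls (HC) must not carry a PASI.
    """

    subject_id: str
    group: str  # "PV" | "HC"
    age: float
    sex: str  # "M" | "F"
    pasi: Optional[float] = None
    duration: Optional[float] = None
    cmv_igg: Optional[float] = None
    cmv_status: str = "unknown"  # "pos" | "neg" | "unknown"

    def __post_init__(self) -> None:
        if self.group not in ("PV", "HC"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == "HC" and self.pasi is not None:
            raise IntegrityError(f"{self.subject_id}: HC subject carries a PASI score")
        if self.pasi is not None and self.pasi < 0:
            raise ValueError(f"{self.subject_id}: negative PASI")


@dataclass(slots=True)
class Cohort:
    """Samples joined to their subjects."""

    samples: list[RepertoireSample]
    subjects: dict[str, SubjectRecord]

    def subject_of(self, sample: RepertoireSample) -> SubjectRecord:
        return self.subjects[sample.subject_id]

    def select(
        self,
        tissue: Optional[str] = None,
        chain: Optional[str] = None,
        group: Optional[str] = None,
    ) -> list[RepertoireSample]:
        out = []
        for s in self.samples:
            if tissue is not None and s.tissue != tissue:
                continue
            if chain is not None and s.chain != chain:
                continue
            if group is not None and self.subjects[s.subject_id].group != group:
                continue
            out.append(s)
        return out


def unique_subjects(samples: Iterable[RepertoireSample]) -> list[str]:
    seen: dict[str, None] = {}
    for s in samples:
        seen.setdefault(s.subject_id)
    return list(seen)
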