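"""Library-level QC and clonotype-level filtering / error-correction.

The processing order is fixed and documented: library assessment (depth,
repertoire size, off-target fraction) -> functional filter -> V-segment
restriction -> error-correction merging.  Merging absorbs low-abundance
"child" clonotypes into similar high-abundance "parents" (identical V, J and
CDR3 length, small Hamming distance, small count ratio), the standard remedy
for sequencing and PCR errors in clonotype tables; total reads are conserved
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import RepertoireSample

__all__ = [
    "QCThresholds",
    "QCReport",
    "assess_library",
    "filter_nonfunctional",
    "restrict_segments",
    "merge_error_clonotypes",
    "preprocess_sample",
    "DEFAULT_TRGV",
    "DEFAULT_TRDV",
]

# Functional V segments retained by the analysis: coding TRGV segments and
# TRDV1-TRDV8.  Pseudogenes (e.g. TRGV10) and TRAV-incorporating hybrids
# (e.g. TRAV14/DV4) are excluded.
DEFAULT_TRGV = frozenset({"TRGV2", "TRGV3", "TRGV4", "TRGV5", "TRGV8", "TRGV9"})
DEFAULT_TRDV = frozenset({f"TRDV{i}" for i in range(1, 9)})


@dataclass(slots=True)
class QCThresholds:
    """Configurable QC cut-offs.

    The library-level defaults separate clearly acceptable libraries (median
    depth ~1e6 reads, hundreds to thousands of clonotypes, ~12% off-target)
    from clearly failing ones (tens of reads, <=10 clonotypes, >60% off-target)
    and are meant to be tuned per study.  Merge parameters follow common
    repertoire error-correction practice: one mismatch, 10:1 abundance ratio.
    """

    min_reads: int = 1000
    min_clonotypes: int = 10
    max_offtarget_fraction: float = 0.5
    merge_max_mismatch: int = 1
    merge_max_ratio: float = 0.1
    allowed_trgv: frozenset[str] = DEFAULT_TRGV
    allowed_trdv: frozenset[str] = DEFAULT_TRDV
    excluded_segments: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0.0 < self.merge_max_ratio < 1.0):
            raise ValueError("merge_max_ratio must lie in (0, 1)")
        if not self.allowed_trgv or not self.allowed_trdv:
            raise ValueError("allowed segment sets must be non-empty")


@dataclass(slots=True)
class QCReport:
    sample_id: str
    verdict: str = "pass"  # "pass" | "fail"
    reasons: list[str] = field(default_factory=list)
    reads_before: int = 0
    reads_after: int = 0
    clonotypes_before: int = 0
    clonotypes_after: int = 0
    reads_retained_fraction: float = 1.0


def assess_library(sample: RepertoireSample, thresholds: QCThresholds) -> QCReport:
    """Accept or reject a whole library.

    Fails iff any rule trips: total reads below ``min_reads``, clonotype count
    at or below ``min_clonotypes``, or off-target (TRA/TRB) read fraction above
    ``max_offtarget_fraction``.  All tripped reasons are listed.
    """
    reasons = []
    total = sample.total_reads
    if total < thresholds.min_reads:
        reasons.append("low_depth")
    if sample.n_clonotypes <= thresholds.min_clonotypes:
        reasons.append("few_clonotypes")
    denom = total + sample.off_target_reads
    offtarget = sample.off_target_reads / denom if denom else 0.0
    if offtarget > thresholds.max_offtarget_fraction:
        reasons.append("offtarget_excess")
    return QCReport(
        sample_id=sample.sample_id,
        verdict="fail" if reasons else "pass",
        reasons=reasons,
        reads_before=total,
        reads_after=total,
        clonotypes_before=sample.n_clonotypes,
        clonotypes_after=sample.n_clonotypes,
        reads_retained_fraction=1.0,
    )


def filter_nonfunctional(sample: RepertoireSample) -> RepertoireSample:
    """Drop out-of-frame clonotypes and those whose junction carries a stop
    codon; frequencies are recomputed over the survivors."""
    out = sample.copy()
    out.clonotypes = [
        c for c in out.clonotypes if (c.functional and c.is_functional())
    ]
    out.recompute_frequencies()
    return out


def restrict_segments(
    sample: RepertoireSample, thresholds: QCThresholds
) -> RepertoireSample:
    """Keep only the allowed V segments for the sample's chain.

    Anything matching ``TRAV`` (hybrid TRAV/DV rearrangements) or listed in
    ``excluded_segments`` is dropped regardless of chain.
    """
    allowed = thresholds.allowed_trgv if sample.chain == "TRG" else thresholds.allowed_trdv

    def keep(v: str) -> bool:
        if "TRAV" in v or v in thresholds.excluded_segments:
            return False
        return v in allowed

    out = sample.copy()
    out.clonotypes = [c for c in out.clonotypes if keep(c.v_gene)]
    out.recompute_frequencies()
    return out


def _hamming_rows(block: np.ndarray, row: np.ndarray) -> np.ndarray:
    return (block != row).sum(axis=1)


def merge_error_clonotypes(
    sample: RepertoireSample, thresholds: QCThresholds
) -> RepertoireSample:
    """Absorb low-abundance error clonotypes into similar abundant parents.

    Children are scanned once in ascending count order (ties broken
    lexicographically by CDR3 nt for determinism).  A child is absorbed into
    the highest-count eligible parent sharing its V gene, J gene and CDR3
    nucleotide length, with Hamming distance <= ``merge_max_mismatch`` and
    child/parent count ratio <= ``merge_max_ratio``; the child's count is added
    to the parent's.  Total reads are conserved exactly.
    """
    out = sample.copy()
    mm = thresholds.merge_max_mismatch
    ratio = thresholds.merge_max_ratio

    groups: dict[tuple[str, str, int], list[int]] = {}
    for i, c in enumerate(out.clonotypes):
        groups.setdefault((c.v_gene, c.j_gene, len(c.cdr3_nt)), []).append(i)

    absorbed: set[int] = set()
    counts = np.array([c.count for c in out.clonotypes], dtype=np.int64)

    for (_, _, length), idx in groups.items():
        if len(idx) < 2 or length == 0:
            continue
        idx_arr = np.array(idx, dtype=np.int64)
        seqs = np.frombuffer(
            "".join(out.clonotypes[i].cdr3_nt for i in idx).encode("ascii"),
            dtype=np.uint8,
        ).reshape(len(idx), length)
        nts = [out.clonotypes[i].cdr3_nt for i in idx]
        # ascending count, ties lexicographic by cdr3_nt
        order = sorted(range(len(idx)), key=lambda k: (counts[idx_arr[k]], nts[k]))
        alive = np.ones(len(idx), dtype=bool)
        for k in order:
            child = idx_arr[k]
            child_count = counts[child]
            # parent must satisfy child/parent <= ratio, i.e. count >= child/ratio
            eligible = alive.copy()
            eligible[k] = False
            eligible &= counts[idx_arr] * ratio >= child_count
            if not eligible.any():
                continue
            cand = np.flatnonzero(eligible)
            dist = _hamming_rows(seqs[cand], seqs[k])
            cand = cand[dist <= mm]
            if cand.size == 0:
                continue
            cand_counts = counts[idx_arr[cand]]
            best = cand_counts.max()
            top = cand[cand_counts == best]
            parent_local = min(top, key=lambda t: nts[t])
            parent = idx_arr[parent_local]
            counts[parent] += child_count
            counts[child] = 0
            alive[k] = False
            absorbed.add(int(child))

    survivors = []
    for i, c in enumerate(out.clonotypes):
        if i in absorbed:
            continue
        c.count = int(counts[i])
        survivors.append(c)
    out.clonotypes = survivors
    out.recompute_frequencies()
    return out


def preprocess_sample(
    sample: RepertoireSample, thresholds: QCThresholds | None = None
) -> tuple[RepertoireSample, QCReport]:
    """Full clonotype-level pipeline: functional filter -> segment restriction
    -> error merging.  Returns the processed sample and a report carrying the
    library verdict and before/after accounting."""
    thresholds = thresholds or QCThresholds()
    report = assess_library(sample, thresholds)
    processed = filter_nonfunctional(sample)
    processed = restrict_segments(processed, thresholds)
    processed = merge_error_clonotypes(processed, thresholds)
    report.reads_after = processed.total_reads
    report.clonotypes_after = processed.n_clonotypes
    report.reads_retained_fraction = (
        report.reads_after / report.reads_before if report.reads_before else 0.0
    )
    return processed, report
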