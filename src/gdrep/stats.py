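"""Segment usage, V-J pairing, CDR3 spectratypes, junctional inserts and
TCR convergence.

Profiles can be weighted by **reads** (each clonotype contributes its read
frequency; the default, matching how chord diagrams and spectratypes are
usually drawn) or by **clonotypes** (each distinct clonotype contributes
equally).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .types import ClonotypeRecord, RepertoireSample, UndefinedValueError

__all__ = [
    "UsageProfile",
    "SpectratypeProfile",
    "JunctionFeatures",
    "segment_usage",
    "vj_pairing_matrix",
    "spectratype",
    "mean_cdr3_length",
    "junction_inserts",
    "convergence_ratio",
]


@dataclass(slots=True)
class UsageProfile:
    level: str  # "V" | "J" | "VJ"
    weighting: str  # "reads" | "clonotypes"
    entries: dict  # segment (or "V|J" pair) -> fraction


@dataclass(slots=True)
class SpectratypeProfile:
    unit: str  # "aa" | "nt"
    weighting: str
    bins: dict[int, float]


@dataclass(slots=True)
class JunctionFeatures:
    """Junctional insert sizes in nucleotides.

    With a D segment, ``total_insert = vd_insert + dj_insert`` (the NDN added
    nucleotides); without one, ``total_insert`` is the single V-J insert and
    the per-side fields are ``None``.  Exonucleolytic overlaps clamp to 0:
    trimming is not negative insertion.
    """

    vd_insert: Optional[int]
    dj_insert: Optional[int]
    total_insert: int


def _key(record: ClonotypeRecord, level: str) -> str:
    if level == "V":
        return record.v_gene
    if level == "J":
        return record.j_gene
    if level == "VJ":
        return f"{record.v_gene}|{record.j_gene}"
    raise ValueError(f"unknown usage level {level!r}")


def segment_usage(
    sample: RepertoireSample, level: str = "V", weighting: str = "reads"
) -> UsageProfile:
    """Fraction of the repertoire attributed to each segment (or V-J pair)."""
    entries: dict[str, float] = {}
    if weighting == "reads":
        for c in sample.clonotypes:
            entries[_key(c, level)] = entries.get(_key(c, level), 0.0) + c.frequency
    elif weighting == "clonotypes":
        n = sample.n_clonotypes
        for c in sample.clonotypes:
            entries[_key(c, level)] = entries.get(_key(c, level), 0.0) + (1.0 / n if n else 0.0)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return UsageProfile(level=level, weighting=weighting, entries=entries)


def vj_pairing_matrix(
    samples: Sequence[RepertoireSample], weighting: str = "reads"
) -> UsageProfile:
    """Pooled V-J pairing profile: per-sample VJ profiles averaged with equal
    sample weight (each sample contributes 1/n regardless of depth)."""
    if not samples:
        return UsageProfile(level="VJ", weighting=weighting, entries={})
    chains = {s.chain for s in samples}
    if len(chains) > 1:
        raise ValueError(f"samples mix chains: {sorted(chains)}")
    pooled: dict[str, float] = {}
    n = len(samples)
    for s in samples:
        prof = segment_usage(s, level="VJ", weighting=weighting)
        for key, frac in prof.entries.items():
            pooled[key] = pooled.get(key, 0.0) + frac / n
    return UsageProfile(level="VJ", weighting=weighting, entries=pooled)


def spectratype(
    sample: RepertoireSample, unit: str = "aa", weighting: str = "reads"
) -> SpectratypeProfile:
    """CDR3 length histogram in amino acids or nucleotides."""
    if unit not in ("aa", "nt"):
        raise ValueError(f"unknown unit {unit!r}")
    bins: dict[int, float] = {}
    n = sample.n_clonotypes
    for c in sample.clonotypes:
        length = len(c.cdr3_aa) if unit == "aa" else len(c.cdr3_nt)
        w = c.frequency if weighting == "reads" else (1.0 / n if n else 0.0)
        bins[length] = bins.get(length, 0.0) + w
    return SpectratypeProfile(unit=unit, weighting=weighting, bins=bins)


def mean_cdr3_length(
    sample: RepertoireSample, unit: str = "aa", weighting: str = "reads"
) -> float:
    """Weighted mean CDR3 length of a sample."""
    if sample.n_clonotypes == 0:
        raise UndefinedValueError(f"{sample.sample_id}: mean CDR3 length of empty sample")
    prof = spectratype(sample, unit=unit, weighting=weighting)
    total = sum(prof.bins.values())
    return sum(length * w for length, w in prof.bins.items()) / total


def junction_inserts(record: ClonotypeRecord) -> Optional[JunctionFeatures]:
    """Insert sizes from junction coordinates.

    With a D segment: ``vd = max(0, d_start - v_end)``,
    ``dj = max(0, j_start - d_end)``.  Without one the single V-J insert is
    ``max(0, j_start - v_end)``.  Returns ``None`` when the needed coordinates
    are undefined (-1); such clonotypes are excluded from aggregates.
    """
    has_d = record.d_gene is not None and record.d_start >= 0 and record.d_end >= 0
    if has_d:
        if record.v_end < 0 or record.j_start < 0:
            return None
        vd = max(0, record.d_start - record.v_end)
        dj = max(0, record.j_start - record.d_end)
        return JunctionFeatures(vd_insert=vd, dj_insert=dj, total_insert=vd + dj)
    if record.v_end < 0 or record.j_start < 0:
        return None
    total = max(0, record.j_start - record.v_end)
    return JunctionFeatures(vd_insert=None, dj_insert=None, total_insert=total)


def convergence_ratio(sample: RepertoireSample) -> float:
    """Distinct nucleotide clonotypes per distinct amino-acid clonotype.

    Convergence means several nucleotide rearrangements encoding the same CDR3
    amino-acid sequence.  Both levels are keyed within (V, J) context so that
    identical junctions on different segments are not conflated; the ratio is
    >= 1 and equals 1 iff the nt->aa map is injective per (V, J).
    """
    if sample.n_clonotypes == 0:
        raise UndefinedValueError(f"{sample.sample_id}: convergence of empty sample")
    nt_keys = {(c.v_gene, c.cdr3_nt, c.j_gene) for c in sample.clonotypes}
    aa_keys = {(c.v_gene, c.cdr3_aa, c.j_gene) for c in sample.clonotypes}
    return len(nt_keys) / len(aa_keys)
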