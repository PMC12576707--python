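"""Cross-sample clonotype sharing: public/private classification, pairwise
Jaccard similarity and paired blood-skin overlap.

Clonotypes are compared by exact identity of a key: (V segment, J segment,
CDR3).  The CDR3 basis is amino acid by default — clonotypes are usually
named by segment plus junction amino-acid sequence — with a nucleotide basis
available for rearrangement-level questions.  Publicity is *subject*-level:
a key is public iff carried by at least two distinct subjects, so paired
blood/skin samples from one person never make a clonotype public.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .types import ClonotypeRecord, Cohort, RepertoireSample

__all__ = [
    "ClonotypeKey",
    "build_key",
    "sample_keys",
    "sharing_counts",
    "jaccard_matrix",
    "paired_overlap",
]


@dataclass(frozen=True, slots=True)
class ClonotypeKey:
    v_gene: str
    j_gene: str
    cdr3: str
    basis: str  # "aa" | "nt"


def build_key(record: ClonotypeRecord, basis: str = "aa") -> ClonotypeKey:
    if basis not in ("aa", "nt"):
        raise ValueError(f"unknown key basis {basis!r}")
    cdr3 = record.cdr3_aa if basis == "aa" else record.cdr3_nt
    return ClonotypeKey(v_gene=record.v_gene, j_gene=record.j_gene, cdr3=cdr3, basis=basis)


def sample_keys(
    sample: RepertoireSample, basis: str = "aa", segment: Optional[str] = None
) -> dict[ClonotypeKey, float]:
    """Key -> summed frequency for one sample (synonymous nt variants collapse
    under the aa basis, their frequencies adding up)."""
    out: dict[ClonotypeKey, float] = {}
    for c in sample.clonotypes:
        if segment is not None and c.v_gene != segment:
            continue
        key = build_key(c, basis)
        out[key] = out.get(key, 0.0) + c.frequency
    return out


def sharing_counts(
    cohort: Cohort,
    basis: str = "aa",
    tissue: Optional[str] = None,
    chain: Optional[str] = None,
) -> tuple[pd.DataFrame, float]:
    """Per-key sharing table and the public fraction of a stratum.

    Returns a table with one row per distinct key (v_gene, j_gene, cdr3,
    n_subjects_sharing, n_pv, n_hc, public) and the fraction of keys that are
    public (present in >= 2 distinct subjects).
    """
    samples = cohort.select(tissue=tissue, chain=chain)
    subjects_by_key: dict[ClonotypeKey, set[str]] = {}
    for s in samples:
        for key in sample_keys(s, basis):
            subjects_by_key.setdefault(key, set()).add(s.subject_id)
    n_subjects = len({s.subject_id for s in samples})
    if n_subjects < 2:
        raise ValueError(
            f"public fraction undefined: stratum has {n_subjects} subject(s)"
        )
    rows = []
    n_public = 0
    for key, subs in subjects_by_key.items():
        public = len(subs) >= 2
        n_public += public
        n_pv = sum(1 for sid in subs if cohort.subjects[sid].group == "PV")
        rows.append(
            {
                "v_gene": key.v_gene,
                "j_gene": key.j_gene,
                "cdr3": key.cdr3,
                "basis": basis,
                "n_subjects_sharing": len(subs),
                "n_pv": n_pv,
                "n_hc": len(subs) - n_pv,
                "public": public,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "v_gene",
            "j_gene",
            "cdr3",
            "basis",
            "n_subjects_sharing",
            "n_pv",
            "n_hc",
            "public",
        ],
    ).sort_values(["n_subjects_sharing", "v_gene", "j_gene", "cdr3"], ascending=[False, True, True, True]).reset_index(drop=True)
    public_fraction = n_public / len(subjects_by_key) if subjects_by_key else 0.0
    return table, public_fraction


def jaccard_matrix(
    samples: Sequence[RepertoireSample],
    basis: str = "aa",
    segment: Optional[str] = None,
) -> pd.DataFrame:
    """Pairwise Jaccard index |A ∩ B| / |A ∪ B| on clonotype key sets.

    Set-based, hence invariant to clone frequencies.  A sample with no keys
    (possible under segment stratification) has JI 0 against every other
    sample; the diagonal is 1 by convention.
    """
    if len(samples) < 2:
        raise ValueError("jaccard_matrix needs >= 2 samples")
    ids = [s.sample_id for s in samples]
    keysets = [set(sample_keys(s, basis, segment=segment)) for s in samples]
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for i in range(len(samples)):
        mat.iloc[i, i] = 1.0
        for jj in range(i + 1, len(samples)):
            a, b = keysets[i], keysets[jj]
            union = len(a | b)
            ji = len(a & b) / union if union else 0.0
            mat.iloc[i, jj] = ji
            mat.iloc[jj, i] = ji
    return mat


def paired_overlap(
    blood: RepertoireSample, skin: RepertoireSample, basis: str = "aa"
) -> pd.DataFrame:
    """Keys shared between a subject's blood and skin compartments, with the
    frequency of each in both and their mean cross-compartment frequency."""
    if blood.chain != skin.chain:
        raise ValueError(f"chain mismatch: {blood.chain} vs {skin.chain}")
    if blood.subject_id != skin.subject_id:
        raise ValueError(
            f"paired_overlap needs one subject: {blood.subject_id} vs {skin.subject_id}"
        )
    fb = sample_keys(blood, basis)
    fs = sample_keys(skin, basis)
    rows = []
    for key in sorted(set(fb) & set(fs), key=lambda k: (k.v_gene, k.j_gene, k.cdr3)):
        rows.append(
            {
                "v_gene": key.v_gene,
                "j_gene": key.j_gene,
                "cdr3": key.cdr3,
                "basis": basis,
                "blood_frequency": fb[key],
                "skin_frequency": fs[key],
                "mean_frequency": 0.5 * (fb[key] + fs[key]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "v_gene",
            "j_gene",
            "cdr3",
            "basis",
            "blood_frequency",
            "skin_frequency",
            "mean_frequency",
        ],
    )
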