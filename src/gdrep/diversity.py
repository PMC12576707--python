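"""Diversity, clonality and frequency-compartment statistics.

Implemented indices
-------------------
* **Shannon-Wiener** ``H = -sum p_i ln p_i`` (natural log; the base is
  configurable via ``base=``).
* **Inverse Simpson** ``1 / sum p_i^2``.
* **Chao1** ``S_obs + f1^2 / (2 f2)``, with the bias-corrected form
  ``S_obs + f1 (f1 - 1) / 2`` when no doubletons are observed.
* **Efron-Thisted** unseen-species estimate: ``S_obs + max(0, Delta)`` with
  ``Delta = sum_{k=1..K} (-1)^{k+1} f_k`` over the frequency-of-frequencies
  spectrum, Euler-transformed when the alternating series fails to decay.
* **D50**: the fraction of clonotypes, ranked by abundance, needed to reach
  50% of reads — small values indicate oligoclonality.

Frequency compartments follow the contiguous partition
small (0, 0.05%], medium (0.05%, 0.5%], large (0.5%, 5%], hyperexpanded
(5%, 100%], so that every clonotype lands in exactly one bin.

All indices obey the Hill-number ordering
``inv_simpson <= exp(shannon) <= S_obs`` and the richness estimators never
fall below the observed richness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import RepertoireSample, UndefinedValueError

__all__ = [
    "AbundanceSpectrum",
    "DiversityResult",
    "CompartmentProfile",
    "COMPARTMENT_BINS",
    "normalize_within_segment",
    "abundance_spectrum",
    "shannon_index",
    "inverse_simpson",
    "chao1",
    "efron_thisted",
    "d50",
    "compartment_profile",
    "top_n_cumulative",
    "diversity_result",
]

# (name, lower-exclusive, upper-inclusive) on the frequency scale
COMPARTMENT_BINS = (
    ("small", 0.0, 0.0005),
    ("medium", 0.0005, 0.005),
    ("large", 0.005, 0.05),
    ("hyperexpanded", 0.05, 1.0),
)


@dataclass(slots=True)
class AbundanceSpectrum:
    """Frequency-of-frequencies: ``f[k]`` = number of clonotypes observed
    exactly ``k`` times."""

    f: dict[int, int]
    s_obs: int
    n_reads: int


@dataclass(slots=True)
class DiversityResult:
    sample_id: str
    stratum: str  # "all" or a V-segment label
    richness: int
    d50: float
    chao1: float
    efron_thisted: float
    shannon: float
    inv_simpson: float


@dataclass(slots=True)
class CompartmentProfile:
    clonotype_fraction: dict[str, float] = field(default_factory=dict)
    space_fraction: dict[str, float] = field(default_factory=dict)


def normalize_within_segment(sample: RepertoireSample) -> dict[str, RepertoireSample]:
    """Split a sample by V segment and renormalise each sub-repertoire's
    frequencies to sum to 1, so per-segment diversity is independent of the
    segment's overall share of the repertoire."""
    out: dict[str, RepertoireSample] = {}
    for c in sample.clonotypes:
        sub = out.get(c.v_gene)
        if sub is None:
            sub = RepertoireSample(
                sample_id=f"{sample.sample_id}:{c.v_gene}",
                subject_id=sample.subject_id,
                tissue=sample.tissue,
                chain=sample.chain,
                clonotypes=[],
            )
            out[c.v_gene] = sub
        sub.clonotypes.append(c.copy())
    for sub in out.values():
        sub.recompute_frequencies()
    return out


def abundance_spectrum(counts: Sequence[int]) -> AbundanceSpectrum:
    f: dict[int, int] = {}
    for k in counts:
        if k < 1:
            raise ValueError(f"count {k} < 1 in abundance spectrum")
        f[int(k)] = f.get(int(k), 0) + 1
    return AbundanceSpectrum(f=f, s_obs=len(counts), n_reads=int(sum(counts)))


def shannon_index(freqs: Sequence[float], base: Optional[float] = None) -> float:
    """Shannon-Wiener entropy, in nats by default (0 ln 0 := 0)."""
    h = -sum(p * math.log(p) for p in freqs if p > 0)
    if base is not None:
        h /= math.log(base)
    return h


def inverse_simpson(freqs: Sequence[float]) -> float:
    return 1.0 / sum(p * p for p in freqs)


def chao1(spectrum: AbundanceSpectrum) -> float:
    f1 = spectrum.f.get(1, 0)
    f2 = spectrum.f.get(2, 0)
    if f2 > 0:
        return spectrum.s_obs + f1 * f1 / (2.0 * f2)
    return spectrum.s_obs + f1 * (f1 - 1) / 2.0


def _euler_transform_sum(terms: np.ndarray) -> float:
    """Sum the alternating series sum_k (-1)^k a_k (a_k = terms, all >= 0)
    by Euler's transformation: sum_n (-1)^n? -> sum_n Delta^n a_0 / 2^{n+1}
    with forward differences of the (finite) term sequence."""
    a = np.asarray(terms, dtype=float)
    total = 0.0
    for n in range(len(a)):
        total += a[0] / 2.0 ** (n + 1)
        a = a[1:] - a[:-1]  # forward difference, sign folded into the formula
        a = -a
    return total


def efron_thisted(spectrum: AbundanceSpectrum, max_terms: int = 20) -> float:
    """Unseen-species correction from the alternating series over f_k.

    ``Delta = f1 - f2 + f3 - ...`` truncated at ``min(max k observed,
    max_terms)``.  When the truncated series oscillates without decay
    (|last term| > |first term|) the Euler transformation is applied for
    stability.  ``Delta`` is floored at 0 so the estimate never drops below
    the observed richness.
    """
    if max_terms < 1:
        raise ValueError("max_terms must be >= 1")
    if not spectrum.f:
        return float(spectrum.s_obs)
    kmax = min(max(spectrum.f), max_terms)
    terms = np.array([spectrum.f.get(k, 0) for k in range(1, kmax + 1)], dtype=float)
    if len(terms) > 1 and abs(terms[-1]) > abs(terms[0]):
        delta = _euler_transform_sum(terms)
    else:
        delta = float(np.sum(terms * (-1.0) ** np.arange(len(terms))))
    return spectrum.s_obs + max(0.0, delta)


def d50(freqs: Sequence[float]) -> float:
    """Fraction of clonotypes (ranked by abundance, stable sort) needed to
    account for half of the reads."""
    if len(freqs) == 0:
        raise UndefinedValueError("D50 of an empty repertoire")
    order = sorted(range(len(freqs)), key=lambda i: -freqs[i])  # stable on ties
    cum = 0.0
    for rank, i in enumerate(order, start=1):
        cum += freqs[i]
        if cum >= 0.5 - 1e-12:
            return rank / len(freqs)
    return 1.0


def compartment_profile(freqs: Sequence[float]) -> CompartmentProfile:
    """Assign each clonotype to its frequency compartment and report both the
    clonotype-count fraction and the read-space fraction per bin (the two
    readings of "proportion of small clonotypes"; both are emitted)."""
    prof = CompartmentProfile(
        clonotype_fraction={name: 0.0 for name, _, _ in COMPARTMENT_BINS},
        space_fraction={name: 0.0 for name, _, _ in COMPARTMENT_BINS},
    )
    n = len(freqs)
    if n == 0:
        return prof
    for p in freqs:
        for name, lo, hi in COMPARTMENT_BINS:
            if lo < p <= hi or (p == 0.0 and name == "small"):
                prof.clonotype_fraction[name] += 1.0 / n
                prof.space_fraction[name] += p
                break
    return prof


def top_n_cumulative(
    sample: RepertoireSample, n: int = 10, stratify_by_segment: bool = False
):
    """Summed frequency of the ``n`` most abundant clonotypes.

    Stratified mode ranks clonotypes *within* each V segment but keeps
    frequencies on the whole-sample scale, so segment totals remain comparable
    across segments.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not stratify_by_segment:
        freqs = sorted(sample.frequencies(), reverse=True)
        return float(sum(freqs[:n]))
    by_seg: dict[str, list[float]] = {}
    for c in sample.clonotypes:
        by_seg.setdefault(c.v_gene, []).append(c.frequency)
    return {
        seg: float(sum(sorted(fs, reverse=True)[:n])) for seg, fs in by_seg.items()
    }


def diversity_result(
    sample: RepertoireSample, stratum: str = "all", max_terms: int = 20
) -> DiversityResult:
    """All diversity indices for one sample (or per-segment sub-repertoire)."""
    if sample.n_clonotypes == 0:
        raise UndefinedValueError(f"{sample.sample_id}: diversity of empty sample")
    freqs = sample.frequencies()
    spectrum = abundance_spectrum(sample.counts())
    return DiversityResult(
        sample_id=sample.sample_id,
        stratum=stratum,
        richness=sample.n_clonotypes,
        d50=d50(freqs),
        chao1=chao1(spectrum),
        efron_thisted=efron_thisted(spectrum, max_terms=max_terms),
        shannon=shannon_index(freqs),
        inv_simpson=inverse_simpson(freqs),
    )
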