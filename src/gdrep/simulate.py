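"""Synthetic gamma/delta TCR repertoire cohorts.

The generator emulates the statistical structure of blood and skin TRG/TRD
repertoires in a psoriasis case-control setting, providing ground truth for
every pipeline stage:

* canonical rearrangements dominate blood (TRGV9-TRGJP, TRDV2-TRDJ1) while
  skin usage is far more balanced, with a TRGJ2 skew;
* CDR3 amino-acid lengths follow per-V-segment discrete Gaussian mixtures,
  bimodal for TRDV1/TRDV3, broad and unimodal for TRGV9 and TRDV2;
* clone sizes follow a heavy-tailed Zipf law (rank-frequency exponent
  ``1/(clone_size_alpha - 1)``);
* a pool of germline-like public clonotypes is shared across configured
  subsets of subjects; synonymous nucleotide variants model TCR convergence;
* a small fraction of reads is emitted as 1-mismatch singleton error
  children, the target of the error-correction stage;
* subject covariates (age, sex, PASI, disease duration, CMV IgG) are drawn
  from distributions matched to the cohort the pipeline is meant for, and
  PASI / age act multiplicatively on expected log-richness of PV blood
  libraries: ``richness_i = exp(ln richness_base + beta_pasi z(pasi_i)
  + beta_age z(age_i) + noise)``.

Identical seeds give identical cohorts: all randomness flows from one
``numpy.random.SeedSequence`` spawned per subject and library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import ClonotypeRecord, Cohort, RepertoireSample, SubjectRecord

__all__ = [
    "PublicClonotype",
    "SimulationConfig",
    "generate_cohort",
    "sample_repertoire",
    "sample_cdr3",
    "inject_public_clonotypes",
    "default_public_pool",
    "DEFAULT_USAGE_PRIORS",
    "DEFAULT_LENGTH_MODELS",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# standard codon table, restricted to what we need: aa -> synonymous codons
CODONS: dict[str, list[str]] = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
_CODON_TO_AA = {codon: aa for aa, codons in CODONS.items() for codon in codons}
_STOP_CODONS = {"TAA", "TAG", "TGA"}


def translate(nt: str) -> str:
    """Translate an in-frame CDR3 nucleotide string; stop codons become '*'."""
    aas = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        aas.append("*" if codon in _STOP_CODONS else _CODON_TO_AA.get(codon, "X"))
    return "".join(aas)


# ---------------------------------------------------------------------------
# defaults: usage priors, CDR3 length mixtures, public pool
# ---------------------------------------------------------------------------

# V-J pair -> probability, per (tissue, chain).  Blood is dominated by the
# canonical TRGV9-TRGJP / TRDV2-TRDJ1 rearrangements; skin is near-uniform
# over the coding TRGV segments with a TRGJ2 skew and balanced TRDV1/TRDV2.
# Small probabilities on TRGV10 (pseudogene) and a TRAV/DV hybrid exercise the
# segment-restriction filter.
DEFAULT_USAGE_PRIORS: dict[tuple[str, str], dict[str, float]] = {
    ("blood", "TRG"): {
        "TRGV9|TRGJP": 0.55,
        "TRGV9|TRGJ2": 0.10,
        "TRGV9|TRGJP1": 0.03,
        "TRGV4|TRGJ2": 0.06,
        "TRGV2|TRGJP1": 0.05,
        "TRGV2|TRGJ2": 0.04,
        "TRGV3|TRGJ2": 0.04,
        "TRGV5|TRGJ2": 0.03,
        "TRGV8|TRGJ2": 0.04,
        "TRGV8|TRGJP": 0.02,
        "TRGV4|TRGJP1": 0.02,
        "TRGV10|TRGJ2": 0.02,
    },
    ("blood", "TRD"): {
        "TRDV2|TRDJ1": 0.60,
        "TRDV2|TRDJ3": 0.08,
        "TRDV1|TRDJ1": 0.15,
        "TRDV3|TRDJ1": 0.05,
        "TRDV2|TRDJ2": 0.04,
        "TRDV1|TRDJ2": 0.02,
        "TRDV3|TRDJ2": 0.02,
        "TRDV5|TRDJ1": 0.01,
        "TRDV4|TRDJ1": 0.01,
        "TRAV14/DV4|TRDJ1": 0.02,
    },
    ("skin", "TRG"): {
        **{
            f"{v}|{j}": w
            for v in ("TRGV2", "TRGV3", "TRGV4", "TRGV5", "TRGV8", "TRGV9")
            for j, w in (("TRGJ2", 0.10), ("TRGJP2", 0.03), ("TRGJP1", 0.025), ("TRGJP", 0.01))
        },
        "TRGV10|TRGJ2": 0.01,
    },
    ("skin", "TRD"): {
        "TRDV1|TRDJ1": 0.35,
        "TRDV2|TRDJ1": 0.30,
        "TRDV3|TRDJ1": 0.12,
        "TRDV1|TRDJ3": 0.06,
        "TRDV2|TRDJ3": 0.06,
        "TRDV1|TRDJ2": 0.04,
        "TRDV2|TRDJ2": 0.04,
        "TRDV3|TRDJ2": 0.03,
    },
}

# per-V mixtures of discrete Gaussians on amino-acid length: (mean, sd, weight)
DEFAULT_LENGTH_MODELS: dict[str, list[tuple[float, float, float]]] = {
    "TRGV9": [(15.0, 2.2, 1.0)],  # broad: ~3/4 of mass in 13-17 aa
    "TRGV2": [(12.5, 1.2, 1.0)],
    "TRGV3": [(12.5, 1.2, 1.0)],
    "TRGV4": [(12.5, 1.2, 1.0)],
    "TRGV5": [(12.5, 1.2, 1.0)],
    "TRGV8": [(12.5, 1.2, 1.0)],
    "TRGV10": [(12.5, 1.2, 1.0)],
    "TRDV1": [(13.0, 1.0, 0.55), (18.0, 1.2, 0.45)],  # bimodal
    "TRDV3": [(12.0, 1.0, 0.5), (17.0, 1.2, 0.5)],  # bimodal
    "TRDV2": [(16.0, 2.0, 1.0)],  # continuous, ~48-51 nt
}
_FALLBACK_LENGTH_MODEL = [(14.0, 2.0, 1.0)]


@dataclass(frozen=True, slots=True)
class PublicClonotype:
    """One germline-like public-pool entry and its sharing design."""

    v_gene: str
    j_gene: str
    cdr3_aa: str
    base_freq: float
    chain: str
    d_gene: Optional[str] = None
    share_blood: float = 0.5  # probability a subject's blood library carries it
    share_skin: float = 0.3  # probability a skin-sampled subject's skin carries it


def default_public_pool() -> list[PublicClonotype]:
    """Nine TRG public clonotypes (five germline-like TRGV9-TRGJP, three
    TRGV4-TRGJ2, one TRGV2-TRGJ2) plus two public TRDV2-TRDJ1 clonotypes."""
    return [
        PublicClonotype("TRGV9", "TRGJP", "CALWEVQELGKKIKVF", 0.040, "TRG", None, 0.8, 0.5),
        PublicClonotype("TRGV9", "TRGJP", "CALWEVRELGKKIKVF", 0.020, "TRG", None, 0.6, 0.5),
        PublicClonotype("TRGV9", "TRGJP", "CALWEVLELGKKIKVF", 0.015, "TRG", None, 0.5, 0.4),
        PublicClonotype("TRGV9", "TRGJP", "CALWEVQQLGKKIKVF", 0.010, "TRG", None, 0.4, 0.3),
        PublicClonotype("TRGV9", "TRGJP", "CALWEVKELGKKIKVF", 0.008, "TRG", None, 0.4, 0.3),
        PublicClonotype("TRGV4", "TRGJ2", "CATWDGPYYKKLF", 0.006, "TRG", None, 0.35, 0.4),
        PublicClonotype("TRGV4", "TRGJ2", "CATWDRSYYKKLF", 0.005, "TRG", None, 0.3, 0.3),
        PublicClonotype("TRGV4", "TRGJ2", "CATWDGGYYKKLF", 0.004, "TRG", None, 0.3, 0.3),
        PublicClonotype("TRGV2", "TRGJ2", "CATWDTYYKKLF", 0.004, "TRG", None, 0.3, 0.3),
        PublicClonotype("TRDV2", "TRDJ1", "CACDVLGDPYTDKLIF", 0.010, "TRD", "TRDD3", 0.45, 0.2),
        PublicClonotype("TRDV2", "TRDJ1", "CACDRLGDTDKLIF", 0.008, "TRD", "TRDD3", 0.3, 0.2),
    ]


@dataclass(slots=True)
class SimulationConfig:
    """All generator knobs.

    Depths and richness defaults approximate a cohort with ~1e5-1e6 reads and
    ~1e3 clonotypes per blood library and 10-100x less in skin; covariates
    match a moderate-to-severe psoriasis cohort (PASI median ~16, disease
    duration median ~9 y, high CMV seroprevalence, male-skewed).
    """

    n_pv: int = 30
    n_hc: int = 15
    tissues: tuple[str, ...] = ("blood", "skin")
    chains: tuple[str, ...] = ("TRG", "TRD")
    depth_blood: int = 400_000
    depth_skin: int = 16_000
    richness_base: float = 900.0  # expected distinct clonotypes, blood
    richness_skin: float = 60.0  # expected distinct clonotypes, skin
    richness_noise_sd: float = 0.25  # lognormal dispersion of richness
    clone_size_alpha: float = 2.0  # power-law exponent; rank exponent 1/(a-1)
    usage_priors: dict = field(default_factory=lambda: dict(DEFAULT_USAGE_PRIORS))
    cdr3_length_models: dict = field(default_factory=lambda: dict(DEFAULT_LENGTH_MODELS))
    beta_pasi: float = -0.5  # effect of z(PASI) on log-richness, PV blood
    beta_age: float = -0.3  # effect of z(age) on log-richness, PV blood
    public_pool: list = field(default_factory=default_public_pool)
    convergence_rate: float = 0.10  # P(clonotype carries a synonymous variant)
    error_rate: float = 0.01  # fraction of reads emitted as 1-mismatch singletons
    offtarget_mean: float = 0.125  # mean TRA/TRB read fraction per library
    skin_fraction: float = 0.3  # fraction of subjects with skin biopsies
    male_fraction: float = 0.75
    pasi_median: float = 16.0
    pasi_sigma: float = 0.6
    duration_median: float = 9.0
    duration_sigma: float = 0.7
    age_mean: float = 44.0
    age_sd: float = 12.0
    cmv_neg_prob_pv: float = 0.21
    cmv_neg_prob_hc: float = 0.033
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clone_size_alpha <= 1.0:
            raise ValueError("clone_size_alpha must exceed 1")
        for rate in (self.convergence_rate, self.error_rate, self.skin_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for key, prior in self.usage_priors.items():
            total = sum(prior.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"usage prior {key} sums to {total}, not 1")
        base_by_scope: dict[tuple[str, str], float] = {}
        for entry in self.public_pool:
            base_by_scope[("blood", entry.chain)] = (
                base_by_scope.get(("blood", entry.chain), 0.0) + entry.base_freq
            )
        if any(v >= 1.0 for v in base_by_scope.values()):
            raise ValueError("public pool base frequencies sum to >= 1 for one library type")


# ---------------------------------------------------------------------------
# CDR3 sampling
# ---------------------------------------------------------------------------


def _codons_for(rng: np.random.Generator, aa: str) -> str:
    return "".join(CODONS[a][rng.integers(len(CODONS[a]))] for a in aa)


def _coordinates(rng: np.random.Generator, nt_len: int, has_d: bool) -> tuple[int, int, int, int]:
    if has_d:
        v_end = int(rng.integers(6, max(7, nt_len // 3 + 1)))
        d_start = v_end + int(rng.integers(0, 7))
        d_end = d_start + int(rng.integers(3, 9))
        j_start = d_end + int(rng.integers(0, 7))
        j_start = min(j_start, nt_len)
        d_end = min(d_end, j_start)
        d_start = min(d_start, d_end)
        v_end = min(v_end, d_start)
        return v_end, d_start, d_end, j_start
    v_end = int(rng.integers(6, max(7, 2 * nt_len // 3)))
    j_start = min(nt_len, v_end + int(rng.integers(0, 10)))
    return v_end, -1, -1, j_start


def sample_cdr3(
    rng: np.random.Generator, aa_length: int, has_d: bool = False
) -> tuple[str, str, tuple[int, int, int, int]]:
    """Draw one CDR3: an anchored C...F amino-acid string, a consistent codon
    realization, and junction coordinates compatible with the insert model."""
    if aa_length < 5:
        raise ValueError("CDR3 amino-acid length must be >= 5")
    middle = "".join(
        AA_ALPHABET[i] for i in rng.integers(0, len(AA_ALPHABET), size=aa_length - 2)
    )
    aa = "C" + middle + "F"
    nt = _codons_for(rng, aa)
    return nt, aa, _coordinates(rng, len(nt), has_d)


def _draw_lengths(
    rng: np.random.Generator, model: list[tuple[float, float, float]], n: int
) -> np.ndarray:
    weights = np.array([w for _, _, w in model], dtype=float)
    weights /= weights.sum()
    comp = rng.choice(len(model), size=n, p=weights)
    means = np.array([m for m, _, _ in model])[comp]
    sds = np.array([s for _, s, _ in model])[comp]
    lengths = np.rint(rng.normal(means, sds)).astype(int)
    return np.clip(lengths, 6, 25)


_N_CODONS = {aa: len(c) for aa, c in CODONS.items()}


def _batch_cdr3(
    rng: np.random.Generator, lengths: np.ndarray, has_d: bool
) -> list[tuple[str, str, tuple[int, int, int, int]]]:
    """Draw many CDR3s at once; random numbers are drawn in bulk so the cost
    per clonotype stays small."""
    n = len(lengths)
    mids = lengths - 2
    aa_codes = rng.integers(0, len(AA_ALPHABET), size=int(mids.sum()))
    codon_rand = iter(rng.random(int(lengths.sum())))
    offsets = np.concatenate([[0], np.cumsum(mids)])
    nt_lens = 3 * lengths
    if has_d:
        r = rng.random((n, 4))
        v_end = 6 + np.floor(r[:, 0] * np.maximum(1, nt_lens // 3 + 1 - 6)).astype(int)
        d_start = v_end + np.floor(r[:, 1] * 7).astype(int)
        d_end = d_start + 3 + np.floor(r[:, 2] * 6).astype(int)
        j_start = np.minimum(d_end + np.floor(r[:, 3] * 7).astype(int), nt_lens)
        d_end = np.minimum(d_end, j_start)
        d_start = np.minimum(d_start, d_end)
        v_end = np.minimum(v_end, d_start)
        coords = np.stack([v_end, d_start, d_end, j_start], axis=1)
    else:
        r = rng.random((n, 2))
        v_end = 6 + np.floor(r[:, 0] * np.maximum(1, 2 * nt_lens // 3 - 6)).astype(int)
        j_start = np.minimum(nt_lens, v_end + np.floor(r[:, 1] * 10).astype(int))
        minus = np.full(n, -1)
        coords = np.stack([v_end, minus, minus, j_start], axis=1)
    out = []
    for i in range(n):
        middle = "".join(AA_ALPHABET[c] for c in aa_codes[offsets[i] : offsets[i + 1]])
        aa = "C" + middle + "F"
        nt = "".join(
            CODONS[a][int(next(codon_rand) * _N_CODONS[a])] for a in aa
        )
        out.append((nt, aa, tuple(int(x) for x in coords[i])))
    return out


# ---------------------------------------------------------------------------
# per-library generation
# ---------------------------------------------------------------------------


def _is_background_segment(v_gene: str) -> bool:
    """Pseudogenes and TRAV/DV hybrid rearrangements never form expanded
    functional clones; they appear only as low-abundance background."""
    return "TRAV" in v_gene or v_gene == "TRGV10"


def _zipf_frequencies(
    rng: np.random.Generator, n: int, alpha: float, background: np.ndarray | None = None
) -> np.ndarray:
    """Heavy-tailed rank-frequency law p_r ~ r^(-1/(alpha-1)), ranks assigned
    at random except that clonotypes flagged ``background`` are kept out of
    the dominant quartile of ranks."""
    s = 1.0 / (alpha - 1.0)
    w = np.arange(1, n + 1, dtype=float) ** (-s)
    order = rng.permutation(n)  # order[k] = clonotype holding rank k
    if background is not None and background.any() and n >= 4:
        cut = max(1, n // 4)
        top_bad = [k for k in range(cut) if background[order[k]]]
        low_good = [k for k in range(n - 1, cut - 1, -1) if not background[order[k]]]
        for k, swap in zip(top_bad, low_good):
            order[k], order[swap] = order[swap], order[k]
    freqs = np.empty(n)
    freqs[order] = w
    return freqs / freqs.sum()


def sample_repertoire(
    subject: SubjectRecord,
    tissue: str,
    chain: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    richness: Optional[int] = None,
) -> RepertoireSample:
    """Draw one library: clonotype identities from the usage priors and length
    mixtures, Zipf clone sizes realised as a multinomial read draw, synonymous
    convergence variants, and 1-mismatch singleton error children."""
    prior = config.usage_priors[(tissue, chain)]
    pairs = list(prior)
    probs = np.array([prior[p] for p in pairs], dtype=float)
    probs /= probs.sum()
    depth_mean = config.depth_blood if tissue == "blood" else config.depth_skin
    if richness is None:
        base = config.richness_base if tissue == "blood" else config.richness_skin
        richness = max(5, int(round(base * math.exp(rng.normal(0.0, config.richness_noise_sd)))))

    pair_idx = rng.choice(len(pairs), size=richness, p=probs)
    pair_vj = [p.split("|") for p in pairs]
    has_d = chain == "TRD"

    # lengths are drawn per V segment (one bulk draw per segment present)
    lengths = np.empty(richness, dtype=int)
    v_of = np.array([pair_vj[i][0] for i in pair_idx])
    for v in np.unique(v_of):
        mask = v_of == v
        model = config.cdr3_length_models.get(str(v), _FALLBACK_LENGTH_MODEL)
        lengths[mask] = _draw_lengths(rng, model, int(mask.sum()))

    cdr3s = _batch_cdr3(rng, lengths, has_d)
    d_genes = (
        [("TRDD1", "TRDD2", "TRDD3")[i] for i in rng.choice(3, size=richness, p=[0.1, 0.2, 0.7])]
        if has_d
        else [None] * richness
    )
    records: list[ClonotypeRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for i in range(richness):
        v, j = pair_vj[pair_idx[i]]
        nt, aa, coords = cdr3s[i]
        if (v, nt, j) in seen:  # rare collision: redraw individually
            for _ in range(20):
                nt, aa, coords = sample_cdr3(rng, int(lengths[i]), has_d=has_d)
                if (v, nt, j) not in seen:
                    break
        seen.add((v, nt, j))
        records.append(
            ClonotypeRecord(
                count=0,
                frequency=0.0,
                cdr3_nt=nt,
                cdr3_aa=aa,
                v_gene=v,
                d_gene=d_genes[i],
                j_gene=j,
                v_end=coords[0],
                d_start=coords[1],
                d_end=coords[2],
                j_start=coords[3],
            )
        )

    background = np.array([_is_background_segment(r.v_gene) for r in records])
    freqs = _zipf_frequencies(rng, richness, config.clone_size_alpha, background)

    # convergence: some clonotypes carry a synonymous nucleotide variant
    if config.convergence_rate > 0:
        carriers = np.flatnonzero(rng.random(richness) < config.convergence_rate)
        extra_records, extra_freqs = [], []
        for idx in carriers:
            parent = records[idx]
            for _ in range(20):
                variant_nt = _codons_for(rng, parent.cdr3_aa)
                if variant_nt != parent.cdr3_nt and (
                    parent.v_gene, variant_nt, parent.j_gene
                ) not in seen:
                    break
            else:
                continue
            seen.add((parent.v_gene, variant_nt, parent.j_gene))
            split = rng.uniform(0.2, 0.5)
            extra_records.append(
                replace(parent, cdr3_nt=variant_nt, count=0, frequency=0.0)
            )
            extra_freqs.append(freqs[idx] * split)
            freqs[idx] *= 1.0 - split
        if extra_records:
            records.extend(extra_records)
            freqs = np.concatenate([freqs, np.array(extra_freqs)])
            freqs /= freqs.sum()

    depth = max(1, int(rng.poisson(depth_mean)))
    counts = rng.multinomial(depth, freqs)
    keep = counts > 0
    records = [r for r, k in zip(records, keep) if k]
    counts = counts[keep]
    for rec, cnt in zip(records, counts):
        rec.count = int(cnt)

    # error injection: singleton children one mismatch away from their parent
    if config.error_rate > 0 and len(records) > 0:
        total = int(counts.sum())
        n_err = rng.binomial(total, config.error_rate)
        child_counts: dict[tuple[str, str, str], tuple[ClonotypeRecord, int]] = {}
        if n_err:
            parent_draw = rng.choice(len(records), size=n_err, p=counts / counts.sum())
            for pi in parent_draw:
                parent = records[pi]
                if parent.count <= 1:
                    continue
                pos = int(rng.integers(len(parent.cdr3_nt)))
                base = parent.cdr3_nt[pos]
                alt = "ACGT".replace(base, "")[rng.integers(3)]
                child_nt = parent.cdr3_nt[:pos] + alt + parent.cdr3_nt[pos + 1 :]
                key = (parent.v_gene, child_nt, parent.j_gene)
                if key in seen and key not in child_counts:
                    continue  # collision with a real clonotype: drop this error read
                parent.count -= 1
                if key in child_counts:
                    rec, c = child_counts[key]
                    child_counts[key] = (rec, c + 1)
                else:
                    child = replace(
                        parent,
                        cdr3_nt=child_nt,
                        cdr3_aa=translate(child_nt),
                        count=0,
                        frequency=0.0,
                    )
                    child.functional = child.is_functional()
                    child_counts[key] = (child, 1)
                    seen.add(key)
        for rec, c in child_counts.values():
            rec.count = c
            records.append(rec)

    records.sort(key=lambda r: (-r.count, r.cdr3_nt))
    sample = RepertoireSample(
        sample_id=f"{subject.subject_id}_{tissue}_{chain}",
        subject_id=subject.subject_id,
        tissue=tissue,
        chain=chain,
        clonotypes=records,
        off_target_reads=int(
            round(depth * rng.beta(2.0, 2.0 / config.offtarget_mean - 2.0))
        ),
    )
    sample.recompute_frequencies()
    return sample


# ---------------------------------------------------------------------------
# public-pool injection
# ---------------------------------------------------------------------------


def inject_public_clonotypes(
    samples: Sequence[RepertoireSample],
    pool: Sequence[PublicClonotype],
    placement: dict[tuple[str, str, str], list[PublicClonotype]],
    nt_realizations: dict[tuple[str, str, str], tuple[str, tuple[int, int, int, int]]],
) -> None:
    """Place pool keys into the designated libraries at their base frequencies.

    ``placement`` maps (subject_id, tissue, chain) to the entries that library
    carries; ``nt_realizations`` fixes one nucleotide realization per pool key
    so that shared clonotypes are identical across subjects down to the
    nucleotide level.  Counts are added so each key lands at approximately its
    base frequency after renormalisation; remaining mass rescales implicitly.
    """
    for sample in samples:
        entries = placement.get((sample.subject_id, sample.tissue, sample.chain), [])
        if not entries:
            continue
        base_sum = sum(e.base_freq for e in entries)
        if base_sum >= 1.0:
            raise ValueError("injected public frequencies sum to >= 1")
        total = sample.total_reads
        existing = {(c.v_gene, c.cdr3_nt, c.j_gene): c for c in sample.clonotypes}
        for e in entries:
            nt, coords = nt_realizations[(e.v_gene, e.j_gene, e.cdr3_aa)]
            count = max(1, int(round(e.base_freq * total / (1.0 - base_sum))))
            key = (e.v_gene, nt, e.j_gene)
            if key in existing:
                existing[key].count += count
            else:
                sample.clonotypes.append(
                    ClonotypeRecord(
                        count=count,
                        frequency=0.0,
                        cdr3_nt=nt,
                        cdr3_aa=e.cdr3_aa,
                        v_gene=e.v_gene,
                        d_gene=e.d_gene,
                        j_gene=e.j_gene,
                        v_end=coords[0],
                        d_start=coords[1],
                        d_end=coords[2],
                        j_start=coords[3],
                    )
                )
        sample.recompute_frequencies()


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _draw_subjects(config: SimulationConfig, rng: np.random.Generator) -> dict[str, SubjectRecord]:
    subjects: dict[str, SubjectRecord] = {}
    for group, n in (("PV", config.n_pv), ("HC", config.n_hc)):
        for i in range(n):
            sid = f"{group}-{i + 1:03d}"
            age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18.0, 75.0))
            sex = "M" if rng.random() < config.male_fraction else "F"
            neg_prob = config.cmv_neg_prob_pv if group == "PV" else config.cmv_neg_prob_hc
            seroneg = rng.random() < neg_prob
            cmv_igg = (
                float(rng.uniform(0.0, 10.0))
                if seroneg
                else float(rng.lognormal(math.log(100.0), 0.5))
            )
            subjects[sid] = SubjectRecord(
                subject_id=sid,
                group=group,
                age=age,
                sex=sex,
                pasi=(
                    float(rng.lognormal(math.log(config.pasi_median), config.pasi_sigma))
                    if group == "PV"
                    else None
                ),
                duration=(
                    float(rng.lognormal(math.log(config.duration_median), config.duration_sigma))
                    if group == "PV"
                    else None
                ),
                cmv_igg=cmv_igg,
                cmv_status="neg" if seroneg else "pos",
            )
    return subjects


def _true_richness(
    subject: SubjectRecord, tissue: str, config: SimulationConfig, rng: np.random.Generator
) -> int:
    base = config.richness_base if tissue == "blood" else config.richness_skin
    log_r = math.log(base)
    if subject.group == "PV" and tissue == "blood":
        if subject.pasi is not None:
            z_pasi = (math.log(subject.pasi) - math.log(config.pasi_median)) / config.pasi_sigma
            log_r += config.beta_pasi * z_pasi
        z_age = (subject.age - config.age_mean) / config.age_sd
        log_r += config.beta_age * z_age
    log_r += rng.normal(0.0, config.richness_noise_sd)
    return max(5, int(round(math.exp(log_r))))


def generate_cohort(config: SimulationConfig) -> tuple[Cohort, pd.DataFrame]:
    """Generate a full cohort.

    Returns the cohort (samples + subjects) and a truth table with one row per
    library recording the realized richness and the injected public keys.
    Deterministic given ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    n_subjects = config.n_pv + config.n_hc
    streams = ss.spawn(2 + n_subjects)
    rng_cov = np.random.default_rng(streams[0])
    rng_pool = np.random.default_rng(streams[1])

    subjects = _draw_subjects(config, rng_cov)
    sids = list(subjects)

    # which subjects have skin biopsies (first tissues stay deterministic)
    skin_ids: set[str] = set()
    if "skin" in config.tissues:
        n_skin = max(0, int(round(config.skin_fraction * n_subjects)))
        skin_ids = set(rng_pool.choice(sids, size=min(n_skin, n_subjects), replace=False))

    # one fixed nucleotide realization per public key
    pool = [e for e in config.public_pool if e.chain in config.chains]
    nt_realizations = {}
    for e in pool:
        nt = _codons_for(rng_pool, e.cdr3_aa)
        coords = _coordinates(rng_pool, len(nt), has_d=e.chain == "TRD")
        nt_realizations[(e.v_gene, e.j_gene, e.cdr3_aa)] = (nt, coords)

    # sharing design: which libraries carry which pool entries
    placement: dict[tuple[str, str, str], list[PublicClonotype]] = {}
    for e in pool:
        for sid in sids:
            if "blood" in config.tissues and rng_pool.random() < e.share_blood:
                placement.setdefault((sid, "blood", e.chain), []).append(e)
            if sid in skin_ids and rng_pool.random() < e.share_skin:
                placement.setdefault((sid, "skin", e.chain), []).append(e)

    samples: list[RepertoireSample] = []
    truth_rows = []
    for sid, stream in zip(sids, streams[2:]):
        subject = subjects[sid]
        tissues = [t for t in config.tissues if t == "blood" or sid in skin_ids]
        lib_streams = stream.spawn(len(tissues) * len(config.chains))
        k = 0
        for tissue in tissues:
            for chain in config.chains:
                rng = np.random.default_rng(lib_streams[k])
                k += 1
                richness = _true_richness(subject, tissue, config, rng)
                sample = sample_repertoire(
                    subject, tissue, chain, config, rng, richness=richness
                )
                samples.append(sample)
                injected = placement.get((sid, tissue, chain), [])
                truth_rows.append(
                    {
                        "sample_id": sample.sample_id,
                        "subject_id": sid,
                        "group": subject.group,
                        "tissue": tissue,
                        "chain": chain,
                        "true_richness": richness,
                        "age": subject.age,
                        "pasi": subject.pasi,
                        "n_public_injected": len(injected),
                        "injected_keys": ";".join(
                            f"{e.v_gene}|{e.j_gene}|{e.cdr3_aa}" for e in injected
                        ),
                    }
                )

    inject_public_clonotypes(samples, pool, placement, nt_realizations)
    truth = pd.DataFrame(truth_rows)
    return Cohort(samples=samples, subjects=subjects), truth
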