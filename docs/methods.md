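# Methods

## Scope and data model

`gdrep` operates on clonotype tables: one row per unique rearrangement with a
read count, CDR3 in nucleotide and amino-acid form (anchored by the conserved
C…F residues; lengths count all residues), segment-level V/D/J calls, and
optional junction coordinates. Coordinates are 0-based, half-open, relative
to the CDR3 nucleotide string; −1 encodes "undefined". Gene calls are
normalised at ingestion: allele suffixes (`*01`) are stripped and
multi-call fields keep the first call, because every downstream statistic is
segment-level. Frequencies are always recomputed from counts; frequency
columns on disk are advisory. Clonotype identity within a sample is the
triple (V, CDR3 nt, J).

## QC and error correction

Processing order is fixed: **library assessment → functional filter →
segment restriction → error merging**. The order matters only for the
accounting — the functional and segment filters commute — and merging is run
last so that error children of dropped clonotypes cannot rescue them.

Library assessment fails a library when any rule trips:

| rule | default | unit | rationale |
|---|---|---|---|
| `min_reads` | 1000 | reads | separates libraries with tens of reads from those with ≥ 10⁴–10⁶ |
| `min_clonotypes` | 10 | clonotypes (fail at ≤) | repertoires of ≤ 10 clonotypes carry no diversity signal |
| `max_offtarget_fraction` | 0.5 | TRA/TRB reads / all reads | flags libraries dominated (> 60–90%) by off-locus transcripts against a typical ~12% background |

These cut-offs are deliberately permissive — they separate clearly usable
from clearly failed libraries and are configurable per study.

Functionality, when no productive flag is present, is derived as: CDR3
nucleotide length divisible by 3 AND no stop (`*`) or frameshift (`_`)
marker in the amino-acid junction.

Segment restriction keeps the coding TRGV set {TRGV2, 3, 4, 5, 8, 9} for TRG
and TRDV1–TRDV8 for TRD; anything matching `TRAV` (hybrid TRAV/DV
rearrangements) or listed in `excluded_segments` is dropped.

Error merging absorbs a low-abundance child into the highest-count eligible
parent with identical V, J and CDR3 nucleotide length, Hamming distance ≤
`merge_max_mismatch` (default 1) and child/parent count ratio ≤
`merge_max_ratio` (default 0.1) — standard repertoire error-correction
practice for PCR/sequencing artifacts. Children are scanned once in
ascending count order; ties (equal counts, equal eligibility) break
lexicographically on CDR3 nt so output is deterministic. Each child merges
into at most one parent; total reads are conserved exactly. Re-running the
merge on its own output is a no-op on realistic data (error children are
orders of magnitude below their parents); pathological count configurations
could in principle expose new eligible pairs on a second pass, which is why
the idempotence guarantee is asserted on representative fixtures rather than
proved universally.

## Repertoire statistics

Usage profiles and spectratypes support two weightings: **reads** (each
clonotype contributes its read frequency; default, since expanded clones
dominate the biology) and **clonotypes** (each unique clonotype contributes
1/S). Pooled V–J pairing averages per-sample profiles with equal sample
weight, so deep libraries do not dominate.

Junctional inserts derive from junction coordinates: with a D segment,
`vd = max(0, d_start − v_end)` and `dj = max(0, j_start − d_end)`; without
one the single V–J insert is `max(0, j_start − v_end)`. Negative gaps clamp
to zero: exonucleolytic trimming is not negative insertion. Records with
undefined coordinates are excluded from aggregates rather than imputed.

Convergence is the count of distinct (V, CDR3 nt, J) triples divided by the
count of distinct (V, CDR3 aa, J) triples. Keying within V–J context is a
design choice: identical amino-acid junctions on different segments are
distinct receptors, and conflating them would overstate convergence. The
context-free variant is computable by collapsing keys first.

## Diversity

Shannon entropy uses natural log (nats) by default with a `base=` option;
the choice of base rescales but never reorders samples. Chao1 uses the
classic singleton/doubleton estimator with the bias-corrected branch at
`f₂ = 0`. The Efron–Thisted correction is the truncated alternating series
`Δ = f₁ − f₂ + f₃ − …` over at most `max_terms` (default 20) terms; when the
series fails to decay (|last term| > |first term|) the Euler transformation
is applied for numerical stability, and Δ is floored at 0 so the estimate
never drops below observed richness. D50 sorts descending with a stable
sort (ties keep insertion order) and returns k*/S_obs where k* is the
smallest rank reaching cumulative frequency 0.5 (tolerance 1e−12 at the
boundary).

Frequency compartments use the contiguous partition small (0, 0.05%],
medium (0.05%, 0.5%], large (0.5%, 5%], hyperexpanded (5%, 100%]; boundary
membership is upper-inclusive so the bins partition (0, 1] exactly. Both the
clonotype-count fraction and the read-space fraction are reported per bin,
since "proportion of small clonotypes" is meaningful in either reading.

Per-segment diversity renormalises frequencies within each V segment to sum
to 1 before computing indices, making per-segment diversity independent of
the segment's overall share. No rarefaction or downsampling is applied by
default; shallow libraries (skin TRD in particular) are therefore
under-sampled and their richness estimates are lower bounds.

## Overlap and publicity

Keys are exact (V, J, CDR3) triples; the default basis is amino acid, which
is how clonotypes are conventionally named, with a nucleotide basis for
rearrangement-level questions. Amino-acid keys merge synonymous variants and
sum their frequencies, so aa-basis publicity is always ≥ nt-basis publicity.
Publicity is subject-level (≥ 2 distinct subjects); Jaccard similarity is
set-based and therefore frequency-invariant. Group enrichment of individual
public clonotypes (case vs control presence) is delegated to the Fisher
exact test with BH correction.

## Association statistics

- **Spearman**: average ranks; exact two-sided p by full permutation
  enumeration for n ≤ 9 without ties (p = #{|ρ_perm| ≥ |ρ_obs|}/n!),
  otherwise `t = ρ√((n−2)/(1−ρ²))` on n−2 degrees of freedom. The
  t-approximation is accurate to a few 1e−3 in p at n ≈ 10–30.
- **Mann–Whitney U**: exact enumeration when min(n_A, n_B) ≤ 8 with no
  ties; otherwise the tie-corrected normal approximation with continuity
  correction. Two-sided.
- **Fisher**: two-sided by the minimum-likelihood convention (the dominant
  convention, implemented identically by scipy and R's `fisher.test`):
  sum of hypergeometric probabilities ≤ that of the observed table. The
  effect estimate is the conditional-MLE odds ratio. Degenerate margins
  return p = 1, flagged.
- **BH**: step-up FDR adjustment, capped at 1, order-invariant. Correction
  is applied within each feature family × covariate × stratum screen.

Age correlations in the patient stratum exclude the oldest patients who
exceed the oldest control's age (default: up to 4; `None` drops all of
them) — without age-matched controls those subjects dominate the age axis
and any monotone trend. The parameter exists because the right k depends on
the cohort's age overlap.

## Synthetic cohorts

The generator emulates the repertoire structure of a psoriasis (PV) vs
healthy-control (HC) γδ TCR study at configurable scale. Defaults:

| knob | default | what it emulates |
|---|---|---|
| `n_pv` / `n_hc` | 30 / 15 | blood-repertoire cohort sizes |
| `depth_blood` / `depth_skin` | 4×10⁵ / 1.6×10⁴ reads | observed per-library depths (blood ~2.5–5×10⁵; skin ~0.8–2.4×10⁴) |
| `richness_base` / `richness_skin` | 900 / 60 clonotypes | mean unique clonotypes per blood / skin library |
| `clone_size_alpha` | 2.0 | power-law clone sizes; rank exponent 1/(α−1) = 1, giving top-10 cumulative frequencies of ~30–45% |
| usage priors | TRGV9-TRGJP 0.55 of blood TRG; TRDV2-TRDJ1 0.60 of blood TRD; near-uniform skin with TRGJ2 skew | canonical-pair dominance in blood, balanced skin usage |
| length mixtures | TRGV9 N(15, 2.2); TRGV2–8 N(12.5, 1.2); TRDV1 0.55·N(13,1)+0.45·N(18,1.2); TRDV3 bimodal; TRDV2 N(16,2) | ~70–75% of blood TRG mass in 13–17 aa; bimodal TRDV1/TRDV3 spectratypes |
| `beta_pasi` / `beta_age` | −0.5 / −0.3 | log-richness contraction with severity and age in PV blood: `richness = exp(ln base + β_pasi·z(PASI) + β_age·z(age) + ε)`, ε ~ N(0, 0.25) |
| public pool | 9 TRG (5 germline-like TRGV9-TRGJP, 3 TRGV4-TRGJ2, 1 TRGV2-TRGJ2) + 2 TRDV2-TRDJ1 | shared public clonotypes; TRG pool larger than TRD so TRG publicity exceeds TRD publicity |
| `convergence_rate` | 0.10 | probability a clonotype carries a synonymous nt variant |
| `error_rate` | 0.01 | fraction of reads emitted as 1-mismatch singleton error children |
| `offtarget_mean` | 0.125 | typical TRA/TRB read background |
| covariates | age N(44, 12) on [18, 75]; PASI LogNormal(median 16, σ 0.6); duration LogNormal(median 9); CMV seronegative 21% PV / 3% HC; 75% male | a moderate-to-severe, male-skewed psoriasis cohort |

z-scores use the generator's own covariate moments (log-scale for PASI), so
β is the change in log-richness per covariate SD. Effects apply to PV blood
only; HC and skin libraries vary by the lognormal noise alone.

Nucleotide realisations use a fixed standard codon table with rng-chosen
synonymous codons; convergence re-draws codons for an existing amino-acid
clonotype; public-pool keys get one fixed nucleotide realisation per cohort
so sharing is exact down to the nucleotide. Pseudogene (TRGV10) and TRAV/DV
hybrid clonotypes are present at ~1–2% prior mass but are excluded from the
dominant quartile of clone-size ranks: clonal expansion implies a functional
receptor, and allowing a pseudogene rearrangement to be a top clone would
also break the empirical property that segment filtering preserves > 95% of
reads. All randomness flows from a single `SeedSequence` spawned per subject
and library, so identical seeds give identical cohorts across platforms.

**What the generator does not emulate.** Endogenous CDR3s are drawn at
random, so two subjects essentially never share a clonotype by convergent
recombination; only injected pool keys are public. Realized public
*fractions* are therefore far smaller than in real data (where
germline-proximal, low-insert junctions recur across individuals), even
though the orderings the pipeline tests — TRG more public than TRD, shared
keys exactly recovered — hold. There is no V(D)J recombination model, no
thymic or peripheral selection, no cross-sample contamination, and no
sequence-context-dependent error model (errors are uniform single
substitutions). Passing tests demonstrate the *statistics* are computed
correctly and that known effects are recovered; they do not validate the
generator as a model of real repertoire formation.

## Problem sizes in the validation suite

Repeated-run checks use reduced scales chosen to keep the full suite at a
few minutes on one CPU while leaving every tested effect identifiable:
read-preservation runs use 20 cohorts of 5 subjects (blood, both chains,
depth 2×10⁴, base richness 200, default 1% error injection);
effect-recovery and type-I runs use 100 and 500 cohorts of 30 PV subjects
(blood TRG only, depth 2×10⁴, base richness 300, β_pasi = −0.5 or 0, error
and convergence injection off since neither affects the richness–severity
association). The acceptance script simulates one full-default cohort.

## Known limitations

- Exact Spearman enumeration is O(n!) and is capped at n ≤ 9; ties always
  fall back to the t-approximation.
- The merge step is greedy single-pass; a globally optimal assignment of
  children to parents is not attempted.
- Diversity estimators are plug-in; no variance or confidence intervals are
  reported.
- Skin TRD libraries at default depths are sparse (tens of clonotypes);
  per-segment compartment analyses on them are noisy by construction, as in
  the data they emulate.
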