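"""Nonparametric clinical association statistics.

Conventions
-----------
* **Spearman**: rho from average-ranked data.  The two-sided p is exact by
  full permutation enumeration for n <= 9 with no ties, otherwise from the
  t-distributed statistic ``t = rho sqrt((n-2) / (1-rho^2))``.
* **Mann-Whitney U**: exact enumeration when ``min(nA, nB) <= 8`` and there
  are no ties, otherwise the tie-corrected, continuity-corrected normal
  approximation.  Two-sided.
* **Fisher's exact test**: two-sided by the minimum-likelihood convention
  (sum of hypergeometric probabilities no larger than the observed table's);
  the effect estimate is the conditional-MLE odds ratio.
* **Benjamini-Hochberg**: step-up FDR adjustment, capped at 1, invariant to
  input order.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import SubjectRecord

log = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "spearman_test",
    "mann_whitney_test",
    "fisher_exact",
    "bh_adjust",
    "correlate_features",
]


@dataclass(slots=True)
class ContingencyTable:
    """2x2 table: rows are groups, columns are outcome (pos, neg)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(slots=True)
class AssociationResult:
    statistic_name: str  # "spearman_rho" | "mann_whitney_U" | "fisher_or"
    estimate: float
    p_value: float
    n: tuple[int, ...]
    p_adjusted: Optional[float] = None
    flags: list[str] = field(default_factory=list)


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def spearman_test(x: Sequence[float], y: Sequence[float]) -> AssociationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("spearman_test needs n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return AssociationResult(
            statistic_name="spearman_rho",
            estimate=float("nan"),
            p_value=float("nan"),
            n=(n,),
            flags=["constant_input"],
        )
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _spearman_rho(rx, ry)
    ties = len(set(x)) < n or len(set(y)) < n
    if n <= 9 and not ties:
        # exact two-sided p by exhaustive permutation of one rank vector
        perms = np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)
        rc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        rhos = (pc @ rc) / math.sqrt(float(rc @ rc)) / np.sqrt((pc * pc).sum(axis=1))
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return AssociationResult(
        statistic_name="spearman_rho", estimate=rho, p_value=min(p, 1.0), n=(n,)
    )


def mann_whitney_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> AssociationResult:
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return AssociationResult(
        statistic_name="mann_whitney_U",
        estimate=float(res.statistic),
        p_value=float(res.pvalue),
        n=(len(a), len(b)),
    )


def fisher_exact(table: ContingencyTable) -> AssociationResult:
    arr = table.as_array()
    flags: list[str] = []
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        # a degenerate margin carries no information
        return AssociationResult(
            statistic_name="fisher_or",
            estimate=float("nan"),
            p_value=1.0,
            n=tuple(int(v) for v in arr.sum(axis=1)),
            flags=["degenerate_margin"],
        )
    p = float(sps.fisher_exact(arr, alternative="two-sided")[1])
    odds = float(sps.contingency.odds_ratio(arr, kind="conditional").statistic)
    return AssociationResult(
        statistic_name="fisher_or",
        estimate=odds,
        p_value=p,
        n=tuple(int(v) for v in arr.sum(axis=1)),
        flags=flags,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _age_exclusion(
    subjects: Sequence[SubjectRecord], k: Optional[int]
) -> set[str]:
    """Subject ids to drop before age correlations in the PV stratum.

    Without age-matched controls the oldest patients dominate the age axis, so
    PV subjects older than the oldest HC are excluded: the ``k`` oldest such
    subjects (default mirrors the usual "drop the few unmatched seniors"
    practice), or all of them when ``k`` is None (automatic mode).
    """
    hc_ages = [s.age for s in subjects if s.group == "HC"]
    if not hc_ages:
        return set()
    max_hc = max(hc_ages)
    over = sorted(
        (s for s in subjects if s.group == "PV" and s.age > max_hc),
        key=lambda s: -s.age,
    )
    if k is not None:
        over = over[:k]
    return {s.subject_id for s in over}


def correlate_features(
    features: pd.DataFrame,
    subjects: dict[str, SubjectRecord],
    covariate: str,
    group: str = "PV",
    exclude_oldest_pv: Optional[int] = 4,
) -> pd.DataFrame:
    """Spearman tests of every feature column against a clinical covariate.

    ``features`` holds one row per subject (``subject_id`` column plus numeric
    feature columns).  The test runs within ``group``; for ``covariate='age'``
    in the PV stratum the oldest unmatched PV subjects are excluded first (see
    :func:`_age_exclusion`).  BH correction is applied across the feature
    family.  Strata with fewer than 3 usable subjects are skipped with a
    notice.
    """
    if covariate not in ("age", "pasi", "duration", "cmv_igg"):
        raise ValueError(f"unknown covariate {covariate!r}")
    drop: set[str] = set()
    if covariate == "age" and group == "PV":
        drop = _age_exclusion(list(subjects.values()), exclude_oldest_pv)
    rows = []
    feature_cols = [c for c in features.columns if c != "subject_id"]
    for col in feature_cols:
        xs, ys = [], []
        for _, row in features.iterrows():
            sub = subjects.get(row["subject_id"])
            if sub is None or sub.group != group or sub.subject_id in drop:
                continue
            cov = getattr(sub, "duration" if covariate == "duration" else covariate)
            val = row[col]
            if cov is None or pd.isna(val):
                continue
            xs.append(float(val))
            ys.append(float(cov))
        if len(xs) < 3:
            log.info("feature %s vs %s: n=%d < 3, skipped", col, covariate, len(xs))
            continue
        res = spearman_test(xs, ys)
        rows.append(
            {
                "feature": col,
                "covariate": covariate,
                "group": group,
                "n": len(xs),
                "rho": res.estimate,
                "p_value": res.p_value,
            }
        )
    out = pd.DataFrame(rows, columns=["feature", "covariate", "group", "n", "rho", "p_value"])
    if len(out):
        valid = out["p_value"].notna()
        adjusted = np.full(len(out), np.nan)
        if valid.any():
            adjusted[valid.to_numpy()] = bh_adjust(out.loc[valid, "p_value"].to_numpy())
        out["p_adjusted"] = adjusted
    else:
        out["p_adjusted"] = []
    return out
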