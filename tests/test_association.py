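import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gdrep.association import (
    ContingencyTable,
    bh_adjust,
    correlate_features,
    fisher_exact,
    mann_whitney_test,
    spearman_test,
)
from gdrep.types import SubjectRecord


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def _rank(v):
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _rho(x, y):
    rx, ry = _rank(x), _rank(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def spearman_exact_oracle(x, y):
    obs = abs(_rho(x, y))
    count = 0
    total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(_rho(x, list(perm))) >= obs - 1e-12:
            count += 1
    return count / total


def mannwhitney_exact_oracle(a, b):
    """Two-sided exact p by enumerating all group assignments of the pooled
    sample (no ties assumed)."""
    pooled = list(a) + list(b)
    na = len(a)

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    obs = u_stat(a, b)
    mean_u = na * len(b) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if abs(u_stat(ga, gb) - mean_u) >= abs(obs - mean_u) - 1e-12:
            count += 1
    return count / total


def _hypergeom_pmf(a, row1, row2, col1):
    return (
        math.comb(row1, a)
        * math.comb(row2, col1 - a)
        / math.comb(row1 + row2, col1)
    )


def fisher_exact_oracle(a, b, c, d):
    """Two-sided minimum-likelihood p by full hypergeometric enumeration."""
    row1, row2, col1 = a + b, c + d, a + c
    p_obs = _hypergeom_pmf(a, row1, row2, col1)
    total = 0.0
    for k in range(max(0, col1 - row2), min(row1, col1) + 1):
        pk = _hypergeom_pmf(k, row1, row2, col1)
        if pk <= p_obs * (1 + 1e-12):
            total += pk
    return min(1.0, total)


def bh_oracle(ps):
    n = len(ps)
    order = sorted(range(n), key=lambda i: ps[i])
    adj = [0.0] * n
    prev = 1.0
    for rank_from_end in range(n, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, ps[i] * n / rank_from_end)
        adj[i] = val
        prev = val
    return adj


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman_test([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert res.estimate == pytest.approx(1.0)
        res = spearman_test([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert res.estimate == pytest.approx(-1.0)

    def test_exact_small_n_against_enumeration(self):
        x, y = [1, 2, 3, 4], [1, 3, 2, 4]
        res = spearman_test(x, y)
        assert res.estimate == pytest.approx(0.8)
        assert res.p_value == pytest.approx(spearman_exact_oracle(x, y), abs=1e-12)

    def test_random_small_cases_match_oracle(self, rng):
        for _ in range(15):
            n = int(rng.integers(4, 8))
            x = rng.permutation(n).tolist()
            y = rng.permutation(n).tolist()
            res = spearman_test(x, y)
            assert res.p_value == pytest.approx(spearman_exact_oracle(x, y), abs=1e-12)

    def test_constant_vector_flagged(self):
        res = spearman_test([1.0, 1.0, 1.0], [1, 2, 3])
        assert "constant_input" in res.flags and math.isnan(res.estimate)

    def test_t_approximation_for_moderate_n(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = spearman_test(x, y)
        rho = res.estimate
        t = rho * math.sqrt(28 / (1 - rho**2))
        from scipy.stats import t as tdist

        assert res.p_value == pytest.approx(2 * tdist.sf(abs(t), 28), abs=1e-12)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        res = mann_whitney_test([1, 2, 3], [4, 5, 6])
        assert res.estimate == 0.0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_one(self):
        res = mann_whitney_test([1, 5, 9, 13], [2, 6, 10, 14])
        assert res.p_value > 0.5

    def test_random_small_cases_match_oracle(self, rng):
        for _ in range(10):
            na, nb = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            pooled = rng.permutation(100)[: na + nb]
            a, b = pooled[:na].tolist(), pooled[na:].tolist()
            res = mann_whitney_test(a, b)
            assert res.p_value == pytest.approx(mannwhitney_exact_oracle(a, b), abs=1e-9)

    def test_power_against_one_sd_shift(self, rng):
        hits = 0
        n_runs = 200
        for _ in range(n_runs):
            a = rng.normal(0, 1, size=50)
            b = rng.normal(1, 1, size=50)
            if mann_whitney_test(a, b).p_value < 0.05:
                hits += 1
        assert hits / n_runs >= 0.90


# ---------------------------------------------------------------------------
# Fisher
# ---------------------------------------------------------------------------

class TestFisher:
    def test_perfect_separation(self):
        res = fisher_exact(ContingencyTable(5, 0, 0, 5))
        assert res.p_value == pytest.approx(2 / 252, abs=1e-12)

    def test_degenerate_margin_flagged(self):
        res = fisher_exact(ContingencyTable(0, 0, 3, 4))
        assert res.p_value == 1.0 and "degenerate_margin" in res.flags

    def test_random_tables_match_enumeration(self, rng):
        for _ in range(30):
            a, b, c, d = (int(v) for v in rng.integers(0, 11, size=4))
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            res = fisher_exact(ContingencyTable(a, b, c, d))
            assert res.p_value == pytest.approx(fisher_exact_oracle(a, b, c, d), abs=1e-9)

    def test_odds_ratio_direction(self):
        assert fisher_exact(ContingencyTable(9, 1, 1, 9)).estimate > 1
        assert fisher_exact(ContingencyTable(1, 9, 9, 1)).estimate < 1


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

class TestBH:
    def test_step_up_by_hand(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert bh_adjust([0.005, 0.1]) == pytest.approx([0.01, 0.1])
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_matches_oracle_and_order_invariance(self, rng):
        for _ in range(10):
            ps = rng.random(int(rng.integers(1, 12))).tolist()
            adj = bh_adjust(ps)
            assert adj == pytest.approx(bh_oracle(ps), abs=1e-12)
            perm = rng.permutation(len(ps))
            adj_perm = bh_adjust([ps[i] for i in perm])
            assert [adj_perm[i] for i in np.argsort(perm)] == pytest.approx(list(adj))

    def test_adjusted_at_least_raw(self, rng):
        ps = rng.random(8)
        assert (bh_adjust(ps) >= ps - 1e-12).all()


# ---------------------------------------------------------------------------
# feature-covariate screening
# ---------------------------------------------------------------------------

def _pv_cohort(n=20, rho_sign=-1, seed=5):
    rng = np.random.default_rng(seed)
    subjects, rows = {}, []
    for i in range(n):
        sid = f"PV-{i}"
        pasi = float(rng.lognormal(math.log(16), 0.6))
        subjects[sid] = SubjectRecord(sid, "PV", float(rng.uniform(25, 55)), "M", pasi=pasi)
        richness = math.exp(6 + rho_sign * 0.8 * math.log(pasi) + rng.normal(0, 0.1))
        rows.append({"subject_id": sid, "richness": richness})
    for i in range(5):
        sid = f"HC-{i}"
        subjects[sid] = SubjectRecord(sid, "HC", float(rng.uniform(25, 50)), "F")
    return pd.DataFrame(rows), subjects


class TestCorrelateFeatures:
    def test_recovers_negative_effect_sign(self):
        features, subjects = _pv_cohort(rho_sign=-1)
        res = correlate_features(features, subjects, covariate="pasi")
        assert len(res) == 1
        assert res.iloc[0]["rho"] < 0 and res.iloc[0]["p_value"] < 0.05

    def test_null_covariate_mostly_insignificant(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_runs = 200
        for run in range(n_runs):
            n = 20
            subjects = {
                f"P{i}": SubjectRecord(f"P{i}", "PV", 40.0, "M",
                                       pasi=float(rng.lognormal(2.5, 0.5)))
                for i in range(n)
            }
            features = pd.DataFrame(
                {"subject_id": [f"P{i}" for i in range(n)], "feat": rng.normal(size=n)}
            )
            res = correlate_features(features, subjects, covariate="pasi")
            if res.iloc[0]["p_value"] < 0.05:
                rejections += 1
        assert rejections / n_runs == pytest.approx(0.05, abs=0.04)

    def test_oldest_unmatched_pv_excluded_from_age_analysis(self):
        subjects = {}
        ages_pv = [30, 35, 40, 45, 62, 65, 70, 72]  # four exceed the oldest HC
        for i, age in enumerate(ages_pv):
            subjects[f"PV-{i}"] = SubjectRecord(f"PV-{i}", "PV", float(age), "M", pasi=10.0)
        for i, age in enumerate([28, 38, 48, 55]):
            subjects[f"HC-{i}"] = SubjectRecord(f"HC-{i}", "HC", float(age), "F")
        features = pd.DataFrame(
            {"subject_id": [f"PV-{i}" for i in range(len(ages_pv))],
             "richness": np.linspace(100, 30, len(ages_pv))}
        )
        res = correlate_features(features, subjects, covariate="age")
        assert res.iloc[0]["n"] == 4  # the 62/65/70/72-year-olds are excluded

    def test_small_stratum_skipped(self):
        subjects = {"P1": SubjectRecord("P1", "PV", 30.0, "M", pasi=5.0),
                    "P2": SubjectRecord("P2", "PV", 40.0, "M", pasi=8.0)}
        features = pd.DataFrame({"subject_id": ["P1", "P2"], "richness": [10, 20]})
        res = correlate_features(features, subjects, covariate="pasi")
        assert len(res) == 0

    def test_bh_applied_across_feature_family(self):
        features, subjects = _pv_cohort()
        rng = np.random.default_rng(3)
        features["noise1"] = rng.normal(size=len(features))
        features["noise2"] = rng.normal(size=len(features))
        res = correlate_features(features, subjects, covariate="pasi")
        assert (res["p_adjusted"] >= res["p_value"] - 1e-12).all()
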