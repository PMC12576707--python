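import itertools

import pytest

from gdrep.overlap import (
    build_key,
    jaccard_matrix,
    paired_overlap,
    sample_keys,
    sharing_counts,
)
from gdrep.types import Cohort, SubjectRecord

from conftest import make_record, make_sample, random_sample


def _subject(sid, group="PV"):
    return SubjectRecord(sid, group, 40.0, "M", pasi=10.0 if group == "PV" else None)


def _cohort(samples, groups=None):
    subjects = {}
    for s in samples:
        grp = (groups or {}).get(s.subject_id, "PV")
        subjects.setdefault(s.subject_id, _subject(s.subject_id, grp))
    return Cohort(samples=list(samples), subjects=subjects)


class TestKeys:
    def test_aa_key_fields(self):
        rec = make_record(1, cdr3_aa="CALWEVQELGKKIKVF", v="TRGV9", j="TRGJP")
        key = build_key(rec, "aa")
        assert (key.v_gene, key.j_gene, key.cdr3) == ("TRGV9", "TRGJP", "CALWEVQELGKKIKVF")

    def test_synonymous_variants_collapse_under_aa_not_nt(self):
        a = make_record(1, cdr3_nt="TGTGCTTTT", cdr3_aa="CAF")
        b = make_record(1, cdr3_nt="TGTGCCTTT", cdr3_aa="CAF")
        assert build_key(a, "aa") == build_key(b, "aa")
        assert build_key(a, "nt") != build_key(b, "nt")

    def test_aa_keys_sum_frequencies(self):
        s = make_sample([
            make_record(3, cdr3_nt="TGTGCTTTT", cdr3_aa="CAF"),
            make_record(1, cdr3_nt="TGTGCCTTT", cdr3_aa="CAF"),
        ])
        keys = sample_keys(s, "aa")
        assert list(keys.values()) == [pytest.approx(1.0)]


class TestSharing:
    def test_public_requires_two_subjects(self):
        shared = dict(cdr3_aa="CALWEVQELGKKIKVF", v="TRGV9", j="TRGJP")
        s1 = make_sample([make_record(5, **{"cdr3_aa": shared["cdr3_aa"]})], sample_id="A",
                         subject_id="P1")
        s2 = make_sample([make_record(5, **{"cdr3_aa": shared["cdr3_aa"]})], sample_id="B",
                         subject_id="P2")
        s3 = make_sample([make_record(5, cdr3_aa="CAWDVKF")], sample_id="C", subject_id="P3")
        table, pf = sharing_counts(_cohort([s1, s2, s3]))
        by_cdr3 = table.set_index("cdr3")
        assert bool(by_cdr3.loc["CALWEVQELGKKIKVF", "public"]) is True
        assert bool(by_cdr3.loc["CAWDVKF", "public"]) is False
        assert pf == pytest.approx(0.5)

    def test_public_fraction_arithmetic(self):
        pub = "CALWEVQELGKKIKVF"
        s1 = make_sample([make_record(1, cdr3_aa=pub),
                          make_record(1, cdr3_aa="CAWDVKF"),
                          make_record(1, cdr3_aa="CAWDVLF")], sample_id="A", subject_id="P1")
        s2 = make_sample([make_record(1, cdr3_aa=pub),
                          make_record(1, cdr3_aa="CAWDVMF")], sample_id="B", subject_id="P2")
        _, pf = sharing_counts(_cohort([s1, s2]))
        assert pf == pytest.approx(0.25)

    def test_identical_repertoires_fully_public(self, rng):
        base = random_sample(rng, n_clones=5)
        s1 = base.copy(); s1.sample_id, s1.subject_id = "A", "P1"
        s2 = base.copy(); s2.sample_id, s2.subject_id = "B", "P2"
        _, pf = sharing_counts(_cohort([s1, s2]))
        assert pf == 1.0

    def test_same_subject_two_tissues_not_public(self):
        blood = make_sample([make_record(5, cdr3_aa="CALWEVQELGKKIKVF")], sample_id="A",
                            subject_id="P1", tissue="blood")
        skin = make_sample([make_record(5, cdr3_aa="CALWEVQELGKKIKVF")], sample_id="B",
                           subject_id="P1", tissue="skin")
        other = make_sample([make_record(5, cdr3_aa="CAWDVKF")], sample_id="C", subject_id="P2")
        table, pf = sharing_counts(_cohort([blood, skin, other]))
        assert not table["public"].any()

    def test_single_subject_stratum_flagged(self):
        s = make_sample([make_record(1)], subject_id="P1")
        with pytest.raises(ValueError, match="undefined"):
            sharing_counts(_cohort([s]))

    def test_aa_publicity_at_least_nt_publicity(self, rng):
        for _ in range(10):
            samples = [random_sample(rng, n_clones=20, sample_id=f"S{i}", subject_id=f"P{i}")
                       for i in range(4)]
            # copy some clones across subjects so there is sharing
            for i in range(1, 4):
                donor = samples[0].clonotypes[i]
                samples[i].clonotypes.append(donor.copy())
                samples[i].recompute_frequencies()
            cohort = _cohort(samples)
            _, pf_aa = sharing_counts(cohort, basis="aa")
            _, pf_nt = sharing_counts(cohort, basis="nt")
            assert pf_aa >= pf_nt - 1e-12


class TestJaccard:
    def test_worked_example(self):
        kws = dict(v="TRGV9", j="TRGJP")
        mk = lambda aa: make_record(1, cdr3_aa=aa, **kws)
        s1 = make_sample([mk("CAF"), mk("CDF"), mk("CEF")], sample_id="A", subject_id="P1")
        s2 = make_sample([mk("CDF"), mk("CEF"), mk("CGF")], sample_id="B", subject_id="P2")
        mat = jaccard_matrix([s1, s2])
        assert mat.loc["A", "B"] == pytest.approx(0.5)

    def test_identity_and_disjoint(self, rng):
        s1 = random_sample(rng, n_clones=8, sample_id="A", subject_id="P1")
        s2 = s1.copy(); s2.sample_id = "B"
        s3 = random_sample(rng, n_clones=8, sample_id="C", subject_id="P3")
        mat = jaccard_matrix([s1, s2, s3])
        assert mat.loc["A", "B"] == 1.0
        assert mat.loc["A", "A"] == 1.0
        assert mat.loc["A", "C"] == 0.0  # random CDR3s almost surely disjoint

    def test_symmetry_and_frequency_invariance(self, rng):
        samples = [random_sample(rng, n_clones=10, sample_id=f"S{i}", subject_id=f"P{i}")
                   for i in range(3)]
        mat = jaccard_matrix(samples)
        assert (mat.values == mat.values.T).all()
        for s in samples:
            for c in s.clonotypes:
                c.count *= 13
            s.recompute_frequencies()
        assert (jaccard_matrix(samples).values == mat.values).all()

    def test_brute_force_equivalence(self, rng):
        samples = [random_sample(rng, n_clones=int(rng.integers(3, 20)),
                                 sample_id=f"S{i}", subject_id=f"P{i}") for i in range(5)]
        mat = jaccard_matrix(samples, basis="aa")
        for a, b in itertools.combinations(samples, 2):
            ka = {(c.v_gene, c.cdr3_aa, c.j_gene) for c in a.clonotypes}
            kb = {(c.v_gene, c.cdr3_aa, c.j_gene) for c in b.clonotypes}
            expected = len(ka & kb) / len(ka | kb)
            assert mat.loc[a.sample_id, b.sample_id] == pytest.approx(expected, abs=1e-12)


class TestPairedOverlap:
    def test_shared_key_with_frequencies(self):
        blood = make_sample([make_record(1, cdr3_aa="CAF"), make_record(1, cdr3_aa="CDF")],
                            sample_id="B", subject_id="P1", tissue="blood")
        skin = make_sample([make_record(5, cdr3_aa="CDF")], sample_id="S", subject_id="P1",
                           tissue="skin")
        table = paired_overlap(blood, skin)
        assert len(table) == 1
        row = table.iloc[0]
        assert (row["blood_frequency"], row["skin_frequency"]) == (0.5, 1.0)
        assert row["mean_frequency"] == pytest.approx(0.75)

    def test_disjoint_pair_empty(self, rng):
        blood = random_sample(rng, sample_id="B", subject_id="P1", tissue="blood")
        skin = random_sample(rng, sample_id="S", subject_id="P1", tissue="skin")
        assert len(paired_overlap(blood, skin)) == 0

    def test_mean_cross_compartment_frequency(self):
        blood = make_sample([make_record(1, cdr3_aa="CAF"), make_record(4, cdr3_aa="CDF")],
                            sample_id="B", subject_id="P1", tissue="blood")
        skin = make_sample([make_record(2, cdr3_aa="CAF"), make_record(3, cdr3_aa="CDF")],
                           sample_id="S", subject_id="P1", tissue="skin")
        table = paired_overlap(blood, skin).set_index("cdr3")
        assert table.loc["CAF", "mean_frequency"] == pytest.approx(0.3)

    def test_chain_mismatch_rejected(self):
        blood = make_sample([make_record(1)], sample_id="B", subject_id="P1", chain="TRG")
        skin = make_sample([make_record(1, v="TRDV2", j="TRDJ1")], sample_id="S",
                           subject_id="P1", tissue="skin", chain="TRD")
        with pytest.raises(ValueError, match="chain"):
            paired_overlap(blood, skin)
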