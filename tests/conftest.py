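import numpy as np
import pytest

from gdrep.simulate import CODONS
from gdrep.types import ClonotypeRecord, RepertoireSample

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_record(
    count=1,
    cdr3_aa=None,
    cdr3_nt=None,
    v="TRGV9",
    d=None,
    j="TRGJP",
    coords=(-1, -1, -1, -1),
    rng=None,
):
    """Build a consistent clonotype: nt derived from aa via the codon table
    (first codon each) unless given explicitly."""
    if cdr3_aa is None and cdr3_nt is None:
        cdr3_aa = "CALWEVF"
    if cdr3_nt is None:
        if rng is None:
            cdr3_nt = "".join(CODONS[a][0] for a in cdr3_aa)
        else:
            cdr3_nt = "".join(CODONS[a][rng.integers(len(CODONS[a]))] for a in cdr3_aa)
    if cdr3_aa is None:
        from gdrep.simulate import translate

        cdr3_aa = translate(cdr3_nt)
    return ClonotypeRecord(
        count=count,
        frequency=0.0,
        cdr3_nt=cdr3_nt,
        cdr3_aa=cdr3_aa,
        v_gene=v,
        d_gene=d,
        j_gene=j,
        v_end=coords[0],
        d_start=coords[1],
        d_end=coords[2],
        j_start=coords[3],
    )


def make_sample(records, sample_id="S1", subject_id="SUBJ1", tissue="blood", chain="TRG",
                off_target_reads=0):
    s = RepertoireSample(
        sample_id=sample_id,
        subject_id=subject_id,
        tissue=tissue,
        chain=chain,
        clonotypes=records,
        off_target_reads=off_target_reads,
    )
    s.recompute_frequencies()
    return s


def random_sample(rng, n_clones=None, sample_id="R1", subject_id="RS1", chain="TRG",
                  tissue="blood", max_count=50):
    """Small random repertoire for property tests and brute-force oracles."""
    if n_clones is None:
        n_clones = int(rng.integers(1, 21))
    vs = ["TRGV9", "TRGV4", "TRGV2"] if chain == "TRG" else ["TRDV1", "TRDV2"]
    js = ["TRGJP", "TRGJ2"] if chain == "TRG" else ["TRDJ1", "TRDJ3"]
    records = []
    seen = set()
    while len(records) < n_clones:
        length = int(rng.integers(6, 18))
        aa = "C" + "".join(AA[i] for i in rng.integers(0, 20, size=length - 2)) + "F"
        nt = "".join(CODONS[a][rng.integers(len(CODONS[a]))] for a in aa)
        v = vs[rng.integers(len(vs))]
        j = js[rng.integers(len(js))]
        if (v, nt, j) in seen:
            continue
        seen.add((v, nt, j))
        records.append(
            make_record(count=int(rng.integers(1, max_count + 1)), cdr3_aa=aa, cdr3_nt=nt, v=v, j=j)
        )
    return make_sample(records, sample_id=sample_id, subject_id=subject_id, chain=chain,
                       tissue=tissue)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
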