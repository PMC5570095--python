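"""Small-ORF discovery, leader cleavage and peptide mass arithmetic."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from bgckit.ripp_utils import (
    START_CODONS,
    STOP_CODONS,
    MassResult,
    cleave_precursor,
    find_small_orfs,
    peptide_mass,
)
from bgckit.seqio import CdsFeature, SeqRecordT

PEPTIDE = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30)


# --- brute-force 6-frame scanner (independent oracle) ------------------------

def orf_oracle(record, min_aa, max_aa, overlap_allowance):
    """Stop-anchored scan: for each stop, the earliest in-frame start since the
    previous stop, on both strands, filtered by length and CDS overlap."""
    found = set()
    for strand in (1, -1):
        seq = record.sequence if strand == 1 else str(
            Seq(record.sequence).reverse_complement()
        )
        n = len(seq)
        for frame in range(3):
            stops = [frame - 3] + [
                p for p in range(frame, n - 2, 3) if seq[p:p + 3] in STOP_CODONS
            ]
            for prev, stop in zip(stops, stops[1:]):
                starts = [
                    p for p in range(prev + 3, stop, 3)
                    if seq[p:p + 3] in START_CODONS
                ]
                if not starts:
                    continue
                s = starts[0]
                aa_len = (stop - s) // 3
                if not min_aa <= aa_len <= max_aa:
                    continue
                if strand == 1:
                    g = (s, stop + 3, 1)
                else:
                    g = (n - (stop + 3), n - s, -1)
                overlap = max(
                    (min(g[1], f.end) - max(g[0], f.start) for f in record.features),
                    default=0,
                )
                if overlap > overlap_allowance:
                    continue
                found.add(g)
    return found


def random_record(rng, length, with_cds=False):
    seq = "".join(rng.choice(list("ACGT"), size=length))
    features = []
    if with_cds and length > 120:
        start = int(rng.integers(0, length - 90))
        features.append(
            CdsFeature(locus_tag="x", start=start, end=start + 90, strand=1)
        )
    return SeqRecordT(id="r", sequence=seq, features=features)


def test_find_small_orfs_matches_bruteforce_scan():
    rng = np.random.default_rng(17)
    for trial in range(20):
        record = random_record(rng, int(rng.integers(300, 2000)), with_cds=trial % 2)
        got = {
            (o.start, o.end, o.strand)
            for o in find_small_orfs(record, min_aa=5, max_aa=120)
            if o.source == "intergenic_scan"
        }
        assert got == orf_oracle(record, 5, 120, 10)


def test_planted_forward_orf():
    body = "TGC" * 20
    seq = "CCTCCT" + "ATG" + body + "TAA" + "CCTCCT"
    record = SeqRecordT(id="r", sequence=seq)
    orfs = find_small_orfs(record, min_aa=5, max_aa=120)
    assert len(orfs) == 1
    (orf,) = orfs
    assert (orf.start, orf.end, orf.strand) == (6, 6 + 3 + 60 + 3, 1)
    assert orf.protein == "M" + "C" * 20
    assert orf.source == "intergenic_scan"


def test_reverse_strand_orf_reported_on_forward_axis():
    body = "TGC" * 20
    fwd = "CCTCCT" + "ATG" + body + "TAA" + "CCTCCT"
    rc_record = SeqRecordT(id="r", sequence=str(Seq(fwd).reverse_complement()))
    orfs = find_small_orfs(rc_record, min_aa=5, max_aa=120)
    assert len(orfs) == 1
    (orf,) = orfs
    n = len(fwd)
    assert (orf.start, orf.end, orf.strand) == (n - 72, n - 6, -1)
    assert orf.protein == "M" + "C" * 20


def test_orf_inside_annotated_cds_excluded():
    body = "TGC" * 20
    seq = "CCTCCT" + "ATG" + body + "TAA" + "CCTCCT"
    record = SeqRecordT(
        id="r", sequence=seq,
        features=[CdsFeature(locus_tag="big", start=0, end=len(seq), strand=1)],
    )
    got = [o for o in find_small_orfs(record, min_aa=5, max_aa=120)
           if o.source == "intergenic_scan"]
    assert got == []


def test_annotated_small_gene_reported(toy_genbank):
    from bgckit.seqio import read_genbank

    path, manifest = toy_genbank
    (record,) = read_genbank(path)
    annotated = [o for o in find_small_orfs(record) if o.source == "annotated"]
    assert [o.protein for o in annotated] == [
        c["translation"] for c in manifest["cds"]
        if c["locus_tag"] in manifest["annotated_small_orf_tags"]
    ]


# --- cleavage ----------------------------------------------------------------

@pytest.mark.parametrize(
    "precursor,site,expected",
    [
        ("MKKLLALA", 4, ("MKKL", "LALA")),
        ("MK", 1, ("M", "K")),
        ("MKKLLALA", 7, ("MKKLLAL", "A")),
    ],
)
def test_cleave_precursor(precursor, site, expected):
    assert cleave_precursor(precursor, site) == expected


@pytest.mark.parametrize("site", [0, 8, -1, 100])
def test_cleave_precursor_bad_site(site):
    with pytest.raises(ValueError):
        cleave_precursor("MKKLLALA", site)


@given(precursor=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=40),
       site_frac=st.floats(0.01, 0.99))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_cleavage_roundtrip(precursor, site_frac):
    site = max(1, min(len(precursor) - 1, int(site_frac * len(precursor))))
    leader, core = cleave_precursor(precursor, site)
    assert leader + core == precursor


# --- mass --------------------------------------------------------------------

def test_glycine_mass():
    res = peptide_mass("G")
    assert res.monoisotopic_da == pytest.approx(75.03203, abs=1e-4)
    assert res.average_da == pytest.approx(75.07, abs=0.01)


def test_macrolactam_removes_one_water():
    core = "GCCANNK".replace("N", "Q")
    lin = peptide_mass(core)
    ring = peptide_mass(core, macrolactam=True)
    assert lin.monoisotopic_da - ring.monoisotopic_da == pytest.approx(18.01056, abs=1e-5)
    assert lin.average_da - ring.average_da == pytest.approx(18.015, abs=0.01)


def test_each_disulfide_removes_two_hydrogens():
    no_ss = peptide_mass("CCGGCC", n_disulfides=0)
    two_ss = peptide_mass("CCGGCC", n_disulfides=2)
    assert no_ss.monoisotopic_da - two_ss.monoisotopic_da == pytest.approx(
        2 * 2.01565, abs=1e-4
    )


def test_mass_errors():
    with pytest.raises(ValueError, match="X"):
        peptide_mass("GXG")
    with pytest.raises(ValueError, match="cysteine"):
        peptide_mass("CGC", n_disulfides=2)
    with pytest.raises(ValueError):
        peptide_mass("")


def test_mono_not_above_average_for_real_peptides():
    for core in ("GG", "MKVLWCCA", "ACDEFGHIKLMNPQRSTVWY"):
        res = peptide_mass(core)
        assert res.monoisotopic_da <= res.average_da


@given(a=PEPTIDE, b=PEPTIDE)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_mass_additivity_minus_water(a, b):
    """Condensing two peptides loses exactly one water, both mass types."""
    ab = peptide_mass(a + b)
    ma, mb = peptide_mass(a), peptide_mass(b)
    assert ab.monoisotopic_da == pytest.approx(
        ma.monoisotopic_da + mb.monoisotopic_da - 18.0105646837, abs=1e-6
    )
    assert ab.average_da == pytest.approx(
        ma.average_da + mb.average_da - 18.0153, abs=1e-2
    )
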