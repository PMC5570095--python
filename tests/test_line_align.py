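"""Top-n selection, UPGMA clustering and domain-level alignment."""

import functools

import numpy as np
import pytest

from bgckit.assembly_metric import AssemblyLine, DomainInstance, combined_distance, distance_matrix
from bgckit.line_align import (
    CLADE_GAP,
    CLADE_MATCH,
    CLADE_MISMATCH,
    align_clade_strings,
    build_alignment_report,
    domain_pair_identity,
    percent_identity,
    progressive_align,
    select_top_n,
    upgma,
)

L = AssemblyLine.from_clades


# --- independent optimal-alignment enumerator --------------------------------

def best_alignment_score(a, b):
    """Exhaustive recursion over all global alignments of two label tuples."""

    @functools.lru_cache(maxsize=None)
    def go(i, j):
        if i == len(a) and j == len(b):
            return 0
        opts = []
        if i < len(a) and j < len(b):
            s = CLADE_MATCH if a[i] == b[j] else CLADE_MISMATCH
            opts.append(s + go(i + 1, j + 1))
        if i < len(a):
            opts.append(CLADE_GAP + go(i + 1, j))
        if j < len(b):
            opts.append(CLADE_GAP + go(i, j + 1))
        return max(opts)

    return go(0, 0)


def test_align_identical_lines():
    cols, score = align_clade_strings(L("a", ["k1", "k2", "k3"]), L("b", ["k1", "k2", "k3"]))
    assert cols == [(0, 0), (1, 1), (2, 2)]
    assert score == 6


def test_align_with_insertion_uses_stated_tie_order():
    cols, score = align_clade_strings(L("a", ["k1", "k2"]), L("b", ["k1", "k3", "k2"]))
    assert cols == [(0, 0), (None, 1), (1, 2)]
    assert score == 3


def test_align_single_mismatch_preferred_over_double_gap():
    cols, score = align_clade_strings(L("a", ["k1"]), L("b", ["k2"]))
    assert score == -2
    assert cols == [(0, 0)]


def test_align_matches_enumeration_oracle():
    """Score equality with exhaustive alignment enumeration, lengths <= 6."""
    rng = np.random.default_rng(20)
    vocab = ["k1", "k2", "k3", "k4"]
    for _ in range(200):
        a = tuple(rng.choice(vocab, size=rng.integers(1, 7)))
        b = tuple(rng.choice(vocab, size=rng.integers(1, 7)))
        cols, score = align_clade_strings(L("a", a), L("b", b))
        assert score == best_alignment_score(a, b)
        # the reported alignment actually achieves the reported score
        achieved = 0
        for ia, ib in cols:
            if ia is None or ib is None:
                achieved += CLADE_GAP
            else:
                achieved += CLADE_MATCH if a[ia] == b[ib] else CLADE_MISMATCH
        assert achieved == score


# --- UPGMA -------------------------------------------------------------------

def test_upgma_two_leaves():
    tree = upgma(np.array([[0, 0.4], [0.4, 0]]), ["A", "B"])
    assert tree.root.height == pytest.approx(0.2)


def test_upgma_hand_agglomeration():
    mat = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
    tree = upgma(mat, ["A", "B", "C"])
    assert tree.newick() == "((A:0.100000,B:0.100000):0.200000,C:0.300000);"
    coph, names = tree.cophenetic()
    assert names == ["A", "B", "C"]
    assert np.allclose(coph, mat)


def random_ultrametric(rng, n):
    """Ultrametric matrix built by random agglomeration at increasing heights."""
    clusters = [[i] for i in range(n)]
    mat = np.zeros((n, n))
    height = 0.0
    while len(clusters) > 1:
        height += float(rng.uniform(0.05, 0.5))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                mat[a, b] = mat[b, a] = 2 * height
        clusters[i] = clusters[i] + clusters.pop(j)
    return mat


def test_upgma_cophenetic_identity_on_ultrametric_inputs():
    rng = np.random.default_rng(11)
    for _ in range(50):
        n = int(rng.integers(3, 8))
        mat = random_ultrametric(rng, n)
        ids = [f"t{i}" for i in range(n)]
        tree = upgma(mat, ids)
        coph, names = tree.cophenetic()
        order = [names.index(i) for i in ids]
        assert np.allclose(coph[np.ix_(order, order)], mat, atol=1e-9)


def test_upgma_output_is_always_ultrametric():
    rng = np.random.default_rng(12)
    for _ in range(30):
        n = int(rng.integers(3, 7))
        mat = rng.uniform(0.1, 1.0, size=(n, n))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        tree = upgma(mat, [f"t{i}" for i in range(n)])

        def check(node):
            for ch in node.children:
                assert ch.height <= node.height + 1e-12
                check(ch)

        check(tree.root)


def test_upgma_rejects_bad_matrices():
    with pytest.raises(ValueError):
        upgma(np.array([[0, 1], [2, 0]]), ["A", "B"])
    with pytest.raises(ValueError):
        upgma(np.array([[0, np.nan], [np.nan, 0]]), ["A", "B"])


# --- top-n selection ---------------------------------------------------------

def test_select_top_n_counts_and_order(assembly_fixture):
    query, refs, truth = assembly_fixture
    top = select_top_n(query, refs, n=15)
    assert len(top) == 15
    dists = [d for _, d in top]
    assert dists == sorted(dists)
    assert [lid for lid, _ in top] == truth["ranking"][:15]
    # identical copy ranks first at distance 0
    assert top[0] == ("ref_001", 0.0)


def test_select_top_n_fewer_refs_than_n(assembly_fixture):
    query, refs, _ = assembly_fixture
    assert len(select_top_n(query, refs[:3], n=15)) == 3


def test_select_top_n_monotone_in_n(assembly_fixture):
    query, refs, _ = assembly_fixture
    prev = []
    for n in (1, 5, 10, 15):
        cur = select_top_n(query, refs, n=n)
        assert cur[: len(prev)] == prev
        prev = cur


def test_select_top_n_empty_refs_rejected(assembly_fixture):
    query, _, _ = assembly_fixture
    with pytest.raises(ValueError):
        select_top_n(query, [], n=15)


# --- progressive alignment ---------------------------------------------------

def test_progressive_two_lines_reduces_to_pairwise():
    a, b = L("a", ["k1", "k2"]), L("b", ["k1", "k3", "k2"])
    mat, ids = distance_matrix([a, b])
    aln = progressive_align([a, b], upgma(mat, ids))
    pair_cols, _ = align_clade_strings(a, b)
    assert [(c["a"], c["b"]) for c in aln.columns] == pair_cols


def test_progressive_identical_lines_have_no_gaps():
    lines = [L(f"l{i}", ["k1", "k2", "k3"]) for i in range(3)]
    mat, ids = distance_matrix(lines)
    aln = progressive_align(lines, upgma(mat, ids))
    assert len(aln.columns) == 3
    assert all(None not in col.values() for col in aln.columns)


def test_progressive_gap_column_for_inserted_domain():
    lines = [L("a", ["k1", "k2"]), L("b", ["k1", "k2"]), L("c", ["k1", "k3", "k2"])]
    mat, ids = distance_matrix(lines)
    aln = progressive_align(lines, upgma(mat, ids))
    gap_cols = [col for col in aln.columns if None in col.values()]
    assert len(gap_cols) == 1
    (col,) = gap_cols
    assert col["c"] is not None and col["a"] is None and col["b"] is None


def test_progressive_preserves_domain_order(assembly_fixture):
    query, refs, _ = assembly_fixture
    lines = [query] + refs[:6]
    mat, ids = distance_matrix(lines)
    aln = progressive_align(lines, upgma(mat, ids))
    for line in lines:
        seen = [col[line.id] for col in aln.columns if col[line.id] is not None]
        assert seen == list(range(len(line)))


# --- identity ----------------------------------------------------------------

def test_percent_identity_examples():
    assert percent_identity("AAAA", "AAAA") == 100.0
    assert percent_identity("AAAA", "AAAT") == 75.0
    assert percent_identity("AAAA", "TTTT") == 0.0


def test_domain_pair_identity_unavailable_without_sequence():
    d1 = DomainInstance(clade="k1", sequence="MKVL")
    d2 = DomainInstance(clade="k1")
    assert domain_pair_identity(d1, d2) is None
    assert domain_pair_identity(d1, d1) == 100.0


# --- report ------------------------------------------------------------------

def test_report_contains_query_plus_top15(assembly_fixture):
    query, refs, _ = assembly_fixture
    report = build_alignment_report(query, refs)
    assert len(report["alignment"]["line_ids"]) == 16
    assert query.id in report["alignment"]["line_ids"]
    assert len(report["top_n"]) == 15
    assert report["tree_newick"].endswith(";")
    assert report["identities"], "homologous same-clade pairs should be reported"
    for entry in report["identities"]:
        assert 0.0 <= entry["percent_identity"] <= 100.0


def test_report_deterministic(assembly_fixture, tmp_path):
    from bgckit.seqio import write_report

    query, refs, _ = assembly_fixture
    p1, p2 = tmp_path / "r1.json", tmp_path / "r2.json"
    write_report(build_alignment_report(query, refs), p1)
    write_report(build_alignment_report(query, refs), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_report_requires_refs(assembly_fixture):
    query, _, _ = assembly_fixture
    with pytest.raises(ValueError):
        build_alignment_report(query, [])
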