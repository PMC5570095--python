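"""Assembly-line selection, UPGMA clustering and domain-level alignment.

Given a query trans-AT PKS assembly line and a reference collection, the
closest references (default: the top 15) are selected by the combined
clade-profile distance, clustered by UPGMA with the same metric, and aligned
at the domain level so that homologous KS domains line up in columns.  Where
domain sequences are available, per-pair percent identity is reported for
homologous (same-clade) aligned domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from .assembly_metric import (
    DEFAULT_WEIGHTS,
    AssemblyLine,
    DomainInstance,
    combined_distance,
    distance_matrix,
)

DEFAULT_TOP_N = 15

# clade-string alignment scoring
CLADE_MATCH = 2
CLADE_MISMATCH = -2
CLADE_GAP = -1

__all__ = [
    "DEFAULT_TOP_N",
    "UpgmaTree",
    "LineAlignment",
    "select_top_n",
    "upgma",
    "align_clade_strings",
    "progressive_align",
    "domain_pair_identity",
    "build_alignment_report",
]


# --- top-n selection ---------------------------------------------------------

def select_top_n(
    query: AssemblyLine,
    refs: Sequence[AssemblyLine],
    n: int = DEFAULT_TOP_N,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
) -> list[tuple[str, float]]:
    """The ``n`` references closest to the query, ascending by distance.

    Ties are broken by lexicographic line id; fewer than ``n`` references
    returns them all.
    """
    if not refs:
        raise ValueError("select_top_n requires a non-empty reference collection")
    if n < 1:
        raise ValueError("n must be >= 1")
    scored = [
        (r.id, combined_distance(query, r, weights).d_combined) for r in refs
    ]
    scored.sort(key=lambda t: (t[1], t[0]))
    return scored[:n]


# --- UPGMA -------------------------------------------------------------------

@dataclass
class _Node:
    height: float
    name: Optional[str] = None
    children: list["_Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class UpgmaTree:
    """Ultrametric binary tree from UPGMA; node heights are merge distances / 2."""

    def __init__(self, root: _Node):
        self.root = root

    def leaf_names(self) -> list[str]:
        out: list[str] = []

        def walk(node: _Node) -> None:
            if node.is_leaf:
                out.append(node.name)  # type: ignore[arg-type]
            for ch in node.children:
                walk(ch)

        walk(self.root)
        return out

    def newick(self) -> str:
        def fmt(node: _Node, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{bl:.6f}"
            inner = ",".join(fmt(ch, node.height) for ch in node.children)
            return f"({inner}):{bl:.6f}"

        root = self.root
        if root.is_leaf:
            return f"{root.name}:0.0;"
        inner = ",".join(fmt(ch, root.height) for ch in root.children)
        return f"({inner});"

    def cophenetic(self) -> tuple[np.ndarray, list[str]]:
        """Pairwise cophenetic distances (2 x height of the lowest common ancestor)."""
        names = self.leaf_names()
        idx = {n: i for i, n in enumerate(names)}
        mat = np.zeros((len(names), len(names)))

        def walk(node: _Node) -> list[str]:
            if node.is_leaf:
                return [node.name]  # type: ignore[list-item]
            groups = [walk(ch) for ch in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            d = 2.0 * node.height
                            mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = d
            return [leaf for g in groups for leaf in g]

        walk(self.root)
        return mat, names


def upgma(matrix: np.ndarray, ids: Sequence[str]) -> UpgmaTree:
    """Unweighted pair-group agglomeration with arithmetic-mean update.

    At each step the minimal-distance cluster pair is merged (ties broken by
    the lexicographically smallest pair of cluster representatives, a cluster
    being represented by its smallest leaf id); the new node's height is half
    the merge distance and distances to the merged cluster are size-weighted
    arithmetic means, which makes the output ultrametric by construction.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = len(ids)
    if matrix.shape != (n, n) or n < 2:
        raise ValueError("upgma requires a square matrix over >= 2 ids")
    if np.isnan(matrix).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(matrix, matrix.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(matrix), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal is not zero")

    # cluster state: representative id (smallest leaf), size, node, distances
    clusters: dict[int, dict] = {
        i: {"rep": ids[i], "size": 1, "node": _Node(height=0.0, name=ids[i])}
        for i in range(n)
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): matrix[i, j] for i in range(n) for j in range(i + 1, n)
    }
    next_key = n
    while len(clusters) > 1:
        best = None
        for (i, j), d in dist.items():
            rep_pair = tuple(sorted((clusters[i]["rep"], clusters[j]["rep"])))
            key = (d, rep_pair)
            if best is None or key < best[0]:
                best = (key, (i, j))
        (d_min, _), (i, j) = best  # type: ignore[misc]
        ci, cj = clusters.pop(i), clusters.pop(j)
        merged = {
            "rep": min(ci["rep"], cj["rep"]),
            "size": ci["size"] + cj["size"],
            "node": _Node(
                height=d_min / 2.0,
                children=sorted(
                    [ci["node"], cj["node"]],
                    key=lambda nd: min(l for l in _leaf_names(nd)),
                ),
            ),
        }
        new_dist: dict[tuple[int, int], float] = {}
        for (a, b), d in dist.items():
            if i in (a, b) or j in (a, b):
                continue
            new_dist[(a, b)] = d
        for k in clusters:
            d_ik = dist[tuple(sorted((i, k)))]
            d_jk = dist[tuple(sorted((j, k)))]
            new_dist[tuple(sorted((k, next_key)))] = (
                ci["size"] * d_ik + cj["size"] * d_jk
            ) / (ci["size"] + cj["size"])
        clusters[next_key] = merged
        dist = new_dist
        next_key += 1
    return UpgmaTree(next(iter(clusters.values()))["node"])


def _leaf_names(node: _Node) -> list[str]:
    if node.is_leaf:
        return [node.name]  # type: ignore[list-item]
    return [l for ch in node.children for l in _leaf_names(ch)]


# --- pairwise and progressive clade alignment --------------------------------

def align_clade_strings(
    a: AssemblyLine,
    b: AssemblyLine,
) -> tuple[list[tuple[Optional[int], Optional[int]]], int]:
    """Global alignment of two clade-label sequences.

    Needleman-Wunsch with match +2, mismatch -2, gap -1; traceback prefers
    diagonal over up (gap in ``b``) over left (gap in ``a``).  Returns the
    aligned columns as (index-in-a, index-in-b) pairs (``None`` marks a gap)
    and the optimal score.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("align_clade_strings requires non-empty lines")
    cols, score = _profile_align(
        [[c] for c in a.clades], [[c] for c in b.clades]
    )
    out: list[tuple[Optional[int], Optional[int]]] = []
    for ia, ib in cols:
        out.append((ia, ib))
    return out, int(score)


def _column_score(labels_a: list[str], labels_b: list[str]) -> float:
    """Average cross-pair substitution score between two profile columns."""
    total = 0
    npairs = 0
    for x in labels_a:
        for y in labels_b:
            total += CLADE_MATCH if x == y else CLADE_MISMATCH
            npairs += 1
    return total / npairs if npairs else 0.0


def _profile_align(
    prof_a: list[list[str]], prof_b: list[list[str]]
) -> tuple[list[tuple[Optional[int], Optional[int]]], float]:
    """DP alignment of two column profiles (each column = its non-gap labels).

    Gap cost is per column.  For single-sequence profiles this is exactly the
    pairwise clade alignment.  Tie order: diagonal > up > left.
    """
    n, m = len(prof_a), len(prof_b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = np.arange(n + 1) * CLADE_GAP
    score[0, :] = np.arange(m + 1) * CLADE_GAP
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _column_score(prof_a[i - 1], prof_b[j - 1])
            score[i, j] = max(
                score[i - 1, j - 1] + s,
                score[i - 1, j] + CLADE_GAP,
                score[i, j - 1] + CLADE_GAP,
            )
    cols: list[tuple[Optional[int], Optional[int]]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(
            score[i, j],
            score[i - 1, j - 1] + _column_score(prof_a[i - 1], prof_b[j - 1]),
        ):
            cols.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and np.isclose(score[i, j], score[i - 1, j] + CLADE_GAP):
            cols.append((i - 1, None))
            i -= 1
        else:
            cols.append((None, j - 1))
            j -= 1
    cols.reverse()
    return cols, float(score[n, m])


@dataclass
class LineAlignment:
    """Multi-line domain alignment: each column maps line id -> domain index or None."""

    line_ids: list[str]
    columns: list[dict[str, Optional[int]]]

    def column_clade(
        self, col: dict[str, Optional[int]], lines: dict[str, AssemblyLine]
    ) -> Optional[str]:
        """The column's clade label when all non-gap members agree, else None."""
        labels = {
            lines[lid].domains[idx].clade
            for lid, idx in col.items()
            if idx is not None
        }
        return labels.pop() if len(labels) == 1 else None


def progressive_align(
    lines: Sequence[AssemblyLine], guide: UpgmaTree
) -> LineAlignment:
    """Merge pairwise alignments along the UPGMA guide tree.

    Each internal node aligns the profiles of its children; columns already
    formed are treated as meta-symbols and never split ("once a gap, always a
    gap").  Domain order within every line is preserved.
    """
    by_id = {line.id: line for line in lines}
    leaf_names = guide.leaf_names()
    if sorted(by_id) != sorted(leaf_names):
        raise ValueError("guide-tree leaves do not match the provided lines")

    def build(node: _Node) -> tuple[list[str], list[dict[str, Optional[int]]]]:
        if node.is_leaf:
            line = by_id[node.name]  # type: ignore[index]
            return [line.id], [{line.id: i} for i in range(len(line))]
        ids_a, cols_a = build(node.children[0])
        for extra in node.children[1:]:
            ids_b, cols_b = build(extra)
            prof_a = [
                [by_id[lid].domains[idx].clade for lid, idx in col.items() if idx is not None]
                for col in cols_a
            ]
            prof_b = [
                [by_id[lid].domains[idx].clade for lid, idx in col.items() if idx is not None]
                for col in cols_b
            ]
            merged_cols, _ = _profile_align(prof_a, prof_b)
            out_cols: list[dict[str, Optional[int]]] = []
            for ia, ib in merged_cols:
                col: dict[str, Optional[int]] = {}
                col.update(cols_a[ia] if ia is not None else {lid: None for lid in ids_a})
                col.update(cols_b[ib] if ib is not None else {lid: None for lid in ids_b})
                out_cols.append(col)
            ids_a, cols_a = ids_a + ids_b, out_cols
        return ids_a, cols_a

    ids, cols = build(guide.root)
    # normalise: every column carries every line id
    full_cols = [
        {lid: col.get(lid) for lid in ids} for col in cols
    ]
    return LineAlignment(line_ids=ids, columns=full_cols)


# --- per-domain sequence identity --------------------------------------------

_protein_aligner = Align.PairwiseAligner()
_protein_aligner.mode = "global"
_protein_aligner.match_score = 1
_protein_aligner.mismatch_score = -1
_protein_aligner.open_gap_score = -2
_protein_aligner.extend_gap_score = -2


def percent_identity(seq1: str, seq2: str) -> float:
    """Percent identity from a global alignment, excluding terminal overhangs.

    Scoring: match +1, mismatch -1, gap -2.  Identity = 100 x identical
    columns / aligned columns, where aligned columns run from the first to
    the last column in which both sequences are non-gap.
    """
    if not seq1 or not seq2:
        raise ValueError("percent_identity requires two non-empty sequences")
    aln = _protein_aligner.align(seq1, seq2)[0]
    row1, row2 = str(aln[0]), str(aln[1])
    both = [k for k in range(len(row1)) if row1[k] != "-" and row2[k] != "-"]
    if not both:
        return 0.0
    lo, hi = both[0], both[-1]
    aligned = hi - lo + 1
    identical = sum(1 for k in range(lo, hi + 1) if row1[k] == row2[k])
    return 100.0 * identical / aligned


def domain_pair_identity(
    d1: DomainInstance, d2: DomainInstance
) -> Optional[float]:
    """Percent identity between two domains' protein sequences.

    Returns ``None`` (identity unavailable) when either domain carries no
    sequence — deliberately distinct from an identity of 0.
    """
    if not d1.sequence or not d2.sequence:
        return None
    return percent_identity(d1.sequence, d2.sequence)


# --- full report -------------------------------------------------------------

def build_alignment_report(
    query: AssemblyLine,
    refs: Sequence[AssemblyLine],
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    n: int = DEFAULT_TOP_N,
    clade_descriptions: Optional[dict[str, str]] = None,
) -> dict:
    """Top-n selection + UPGMA tree + progressive alignment + identities.

    The bundle is a plain dict (deterministic given the inputs) suitable for
    :func:`bgckit.seqio.write_report`.
    """
    if not refs:
        raise ValueError("build_alignment_report requires at least one reference")
    top = select_top_n(query, refs, n=n, weights=weights)
    selected_ids = {lid for lid, _ in top}
    lines = [query] + [r for r in refs if r.id in selected_ids]
    mat, ids = distance_matrix(lines, weights)
    tree = upgma(mat, ids)
    aln = progressive_align(lines, tree)
    by_id = {line.id: line for line in lines}

    identities = []
    for ci, col in enumerate(aln.columns):
        present = [(lid, idx) for lid, idx in col.items() if idx is not None]
        for a in range(len(present)):
            for b in range(a + 1, len(present)):
                (lid1, i1), (lid2, i2) = present[a], present[b]
                dom1, dom2 = by_id[lid1].domains[i1], by_id[lid2].domains[i2]
                if dom1.clade != dom2.clade:
                    continue  # only homologous (same-clade) pairs
                ident = domain_pair_identity(dom1, dom2)
                identities.append(
                    {
                        "column": ci,
                        "line_1": lid1,
                        "domain_1": i1,
                        "line_2": lid2,
                        "domain_2": i2,
                        "clade": dom1.clade,
                        "percent_identity": ident,
                    }
                )

    descriptions = clade_descriptions or {}
    return {
        "query": query.id,
        "top_n": [{"id": lid, "distance": d} for lid, d in top],
        "tree_newick": tree.newick(),
        "alignment": {
            "line_ids": aln.line_ids,
            "columns": [
                {lid: col[lid] for lid in aln.line_ids} for col in aln.columns
            ],
            "column_clades": [
                aln.column_clade(col, by_id) for col in aln.columns
            ],
        },
        "identities": identities,
        "clade_descriptions": {
            c: descriptions.get(c, "")
            for c in sorted({d.clade for line in lines for d in line.domains})
        },
    }
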