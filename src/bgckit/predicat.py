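"""Phylogeny-based chemistry prediction (monophyly rule).

A query enzyme is placed in a neighbor-joining tree together with a labelled
reference set (labels are e.g. terpene cyclization patterns such as
"1,10-cyclization", NRPS adenylation-domain substrates, or KS clades).  After
midpoint rooting, the query's sister group is inspected: when every reference
in it carries one and the same label, that label is assigned as the
prediction; a mixed sister group yields no prediction.  Independently of the
monophyly outcome, the nearest characterized homolog and the percent identity
to it are always reported.

Terpene predictions are gated on the presence of the terpene synthase Pfam
domains PF01397 (N-terminal) and/or PF03936 (C-terminal); clusters encoding
only phytoene synthases, tetraterpene/oxidosqualene/lycopene cyclases,
tryptophan dimethylallyltransferases or GGPP synthases are not eligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from skbio import TreeNode

from .assembly_metric import DomainInstance
from .line_align import percent_identity

TERPENE_CYCLASE_PFAMS = frozenset({"PF01397", "PF03936"})
UNCLASSIFIED = "unclassified"

__all__ = [
    "ReferenceEntry",
    "ReferenceSet",
    "PredicatResult",
    "pairwise_identity_matrix",
    "build_nj_tree",
    "predict_label",
    "predict_labels",
    "terpene_eligible",
    "assign_ks_clades",
    "TERPENE_CYCLASE_PFAMS",
]


@dataclass(frozen=True)
class ReferenceEntry:
    id: str
    sequence: str
    label: str
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference {self.id!r} has an empty sequence")


@dataclass
class ReferenceSet:
    """Labelled reference proteins for monophyly-based prediction."""

    entries: list[ReferenceEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate reference ids: {dupes}")

    @property
    def labels(self) -> set[str]:
        return {e.label for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_fasta(cls, path: Union[str, Path]) -> "ReferenceSet":
        """FASTA whose description lines carry ``label=<...> name=<...>`` pairs."""
        from Bio import SeqIO

        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            meta = dict(
                kv.split("=", 1)
                for kv in rec.description.split()
                if "=" in kv
            )
            if "label" not in meta:
                raise ValueError(
                    f"{path}: reference {rec.id!r} lacks a label=... tag"
                )
            entries.append(
                ReferenceEntry(
                    id=rec.id,
                    sequence=str(rec.seq),
                    label=meta["label"],
                    display_name=meta.get("name", rec.id),
                )
            )
        return cls(entries=entries)

    def to_fasta(self) -> str:
        out = []
        for e in self.entries:
            name = e.display_name or e.id
            out.append(f">{e.id} label={e.label} name={name}")
            out.append(e.sequence)
        return "\n".join(out) + "\n"


@dataclass(frozen=True)
class PredicatResult:
    predicted_label: Optional[str]
    support_leaf_count: int
    nearest_homolog: tuple[str, str]  # (display_name, id)
    nearest_identity: float


def pairwise_identity_matrix(
    seqs: Sequence[tuple[str, str]]
) -> tuple[np.ndarray, list[str]]:
    """All-vs-all percent identity (global alignment); diagonal 100."""
    ids = [i for i, _ in seqs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence ids: {dupes}")
    if len(seqs) < 3:
        raise ValueError("pairwise_identity_matrix requires >= 3 sequences")
    n = len(seqs)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = percent_identity(seqs[i][1], seqs[j][1])
            mat[i, j] = mat[j, i] = ident
    return mat, ids


def build_nj_tree(dist: np.ndarray, ids: Sequence[str]) -> TreeNode:
    """Neighbor joining (Saitou-Nei) with deterministic tie handling.

    Distances are typically 1 - identity/100.  Negative branch lengths are
    clamped to zero; ties in the Q criterion are broken by the
    lexicographically smallest pair of cluster representatives.  An all-zero
    matrix yields a star tree with zero branch lengths.  The returned tree is
    unrooted (trifurcating root) for > 3 taxa.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(ids)
    if dist.shape != (n, n) or n < 3:
        raise ValueError("build_nj_tree requires a square matrix over >= 3 taxa")
    if not np.allclose(dist, dist.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    if np.allclose(dist, 0.0):
        root = TreeNode()
        for name in sorted(ids):
            root.append(TreeNode(name=name, length=0.0))
        return root

    # active clusters: key -> (representative id, TreeNode)
    nodes = {i: TreeNode(name=ids[i], length=None) for i in range(n)}
    reps = {i: ids[i] for i in range(n)}
    D = {
        (i, j): float(dist[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }

    def d(a: int, b: int) -> float:
        return D[(a, b) if a < b else (b, a)]

    next_key = n
    while len(nodes) > 3:
        active = sorted(nodes)
        r = len(active)
        row_sums = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                a, b = active[ii], active[jj]
                q = (r - 2) * d(a, b) - row_sums[a] - row_sums[b]
                rep_pair = tuple(sorted((reps[a], reps[b])))
                key = (q, rep_pair)
                if best is None or key < best[0]:
                    best = (key, (a, b))
        _, (a, b) = best  # type: ignore[misc]
        dab = d(a, b)
        la = dab / 2.0 + (row_sums[a] - row_sums[b]) / (2.0 * (r - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length, child_b.length = la, lb
        parent = TreeNode(children=sorted([child_a, child_b], key=_min_leaf_name))
        new_D = {}
        for (x, y), v in D.items():
            if a in (x, y) or b in (x, y):
                continue
            new_D[(x, y)] = v
        for k in nodes:
            dk = max((d(a, k) + d(b, k) - dab) / 2.0, 0.0)
            new_D[(k, next_key) if k < next_key else (next_key, k)] = dk
        nodes[next_key] = parent
        reps[next_key] = min(reps[a], reps[b])
        D = new_D
        next_key += 1

    keys = sorted(nodes)
    root = TreeNode()
    if len(keys) == 2:
        a, b = keys
        dab = d(a, b)
        nodes[a].length = nodes[b].length = max(dab / 2.0, 0.0)
        for k in keys:
            root.append(nodes[k])
    else:
        a, b, c = keys
        la = max((d(a, b) + d(a, c) - d(b, c)) / 2.0, 0.0)
        lb = max((d(a, b) + d(b, c) - d(a, c)) / 2.0, 0.0)
        lc = max((d(a, c) + d(b, c) - d(a, b)) / 2.0, 0.0)
        for k, lk in zip(keys, (la, lb, lc)):
            nodes[k].length = lk
            root.append(nodes[k])
    return root


def _min_leaf_name(node: TreeNode) -> str:
    if node.is_tip():
        return node.name
    return min(t.name for t in node.tips())


def _midpoint_root(tree: TreeNode) -> TreeNode:
    total = sum(t.length or 0.0 for t in tree.postorder() if t.length)
    if total <= 0:
        return tree
    try:
        return tree.root_at_midpoint()
    except Exception:  # degenerate geometry: keep the unrooted form
        return tree


def predict_label(
    query: tuple[str, str],
    refs: ReferenceSet,
    min_sister_size: int = 1,
    _ref_matrix: Optional[tuple[np.ndarray, list[str]]] = None,
) -> PredicatResult:
    """Monophyly-rule prediction for one query protein.

    Builds an NJ tree on references + query from 1 - identity/100 distances,
    midpoint-roots it, and assigns the sister group's label when it is
    uniform (and at least ``min_sister_size`` leaves).  The nearest
    characterized homolog and identity are reported regardless of whether a
    label could be assigned.
    """
    qid, qseq = query
    if len(refs) < 2:
        raise ValueError("predict_label requires at least 2 references")
    if qid in {e.id for e in refs.entries}:
        raise ValueError(f"query id {qid!r} collides with a reference id")

    ref_ids = [e.id for e in refs.entries]
    if _ref_matrix is not None:
        ref_mat, cached_ids = _ref_matrix
        if cached_ids != ref_ids:
            raise ValueError("cached reference matrix does not match reference set")
        q_row = np.array(
            [percent_identity(qseq, e.sequence) for e in refs.entries]
        )
        n = len(ref_ids) + 1
        ident = np.full((n, n), 100.0)
        ident[: n - 1, : n - 1] = ref_mat
        ident[n - 1, : n - 1] = q_row
        ident[: n - 1, n - 1] = q_row
        ids = ref_ids + [qid]
    else:
        seqs = [(e.id, e.sequence) for e in refs.entries] + [(qid, qseq)]
        ident, ids = pairwise_identity_matrix(seqs)

    # nearest characterized homolog: argmax identity, ties by lexicographic id
    by_id = {e.id: e for e in refs.entries}
    q_idx = ids.index(qid)
    best_id, best_ident = None, -1.0
    for k, rid in enumerate(ids):
        if rid == qid:
            continue
        val = ident[q_idx, k]
        if val > best_ident or (val == best_ident and rid < best_id):
            best_id, best_ident = rid, float(val)
    nearest = by_id[best_id]  # type: ignore[index]

    dist = 1.0 - ident / 100.0
    np.fill_diagonal(dist, 0.0)
    tree = build_nj_tree(dist, ids)
    tree = _midpoint_root(tree)

    query_tip = next(t for t in tree.tips() if t.name == qid)
    parent = query_tip.parent
    predicted: Optional[str] = None
    support = 0
    if parent is not None:
        sister_leaves = [t.name for t in parent.tips() if t.name != qid]
        support = len(sister_leaves)
        labels = {by_id[name].label for name in sister_leaves}
        if len(labels) == 1 and support >= min_sister_size:
            predicted = labels.pop()
    return PredicatResult(
        predicted_label=predicted,
        support_leaf_count=support,
        nearest_homolog=(nearest.display_name or nearest.id, nearest.id),
        nearest_identity=best_ident,
    )


def predict_labels(
    queries: Sequence[tuple[str, str]],
    refs: ReferenceSet,
    min_sister_size: int = 1,
) -> list[PredicatResult]:
    """Batch prediction; the reference-vs-reference identity block is computed once."""
    if len(refs) >= 3:
        seqs = [(e.id, e.sequence) for e in refs.entries]
        cache = pairwise_identity_matrix(seqs)
    else:
        cache = None
    return [
        predict_label(q, refs, min_sister_size=min_sister_size, _ref_matrix=cache)
        for q in queries
    ]


def terpene_eligible(domain_labels: set[str]) -> bool:
    """Whether a cluster's Pfam domain content licenses terpene-cyclization prediction.

    True iff the mono-/sesqui-/diterpene cyclase families PF01397 and/or
    PF03936 are present; families such as phytoene synthases, tetraterpene
    cyclases, oxidosqualene cyclases, tryptophan dimethylallyltransferases,
    GGPP synthases and lycopene cyclases do not qualify on their own.
    """
    return bool(TERPENE_CYCLASE_PFAMS & set(domain_labels))


def assign_ks_clades(
    domains: Sequence[DomainInstance],
    ks_refs: ReferenceSet,
    min_sister_size: int = 1,
) -> list[DomainInstance]:
    """Assign each KS domain to a reference clade via the monophyly rule.

    Domains whose sister group is not uniformly labelled come back with clade
    ``"unclassified"``.
    """
    from dataclasses import replace

    for d in domains:
        if not d.sequence:
            raise ValueError("assign_ks_clades requires every domain to carry a sequence")
    queries = [(f"query_domain_{i}", d.sequence) for i, d in enumerate(domains)]
    results = predict_labels(queries, ks_refs, min_sister_size=min_sister_size)
    return [
        replace(d, clade=res.predicted_label or UNCLASSIFIED)
        for d, res in zip(domains, results)
    ]
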