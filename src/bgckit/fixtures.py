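"""Deterministic synthetic test data for every module.

Nothing here claims biological realism: clade labels, reference families and
the toy genome are constructed objects whose ground truth is known exactly,
so that scans and predictors can be checked against planted features.  All
randomness flows from a single seed through one :class:`numpy.random.Generator`.

The toy GenBank record is engineered so that the planted features are the
*only* recoverable ones: intergenic filler uses only C/T (whose reverse
complement is A/G), which makes start codons (ATG/GTG/TTG) and stop codons
(TAA/TAG/TGA) impossible outside the planted genes and ORF on either strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .assembly_metric import AssemblyLine, DomainInstance, combined_distance
from .predicat import ReferenceEntry, ReferenceSet

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# codons drawn only from {C,T}: the encoded residues F/L/S/P keep gene bodies
# free of A/G and therefore free of start/stop codons in every other frame
_CT_CODONS = {"F": "TTC", "L": "CTC", "S": "TCC", "P": "CCT"}
_CT_RESIDUES = "FLSP"

DEFAULT_CLADES = tuple(f"KS{i:02d}" for i in range(1, 9))
DEFAULT_CYCLIZATION_LABELS = ("1,6-cyclization", "1,10-cyclization", "1,11-cyclization")

__all__ = [
    "FixtureSpec",
    "make_assembly_lines",
    "make_reference_families",
    "make_toy_genbank",
]


@dataclass(frozen=True)
class FixtureSpec:
    """All knobs of the generators; a fixed seed makes every output reproducible."""

    seed: int = 42
    n_ref_lines: int = 30
    clade_vocabulary: tuple[str, ...] = DEFAULT_CLADES
    n_labels: int = 3
    seqs_per_label: int = 5
    within_divergence: float = 0.05
    between_divergence: float = 0.40
    n_queries: int = 50
    query_line_length: int = 12
    protein_length: int = 150

    def __post_init__(self) -> None:
        if not (0 <= self.within_divergence < 1 and 0 <= self.between_divergence < 1):
            raise ValueError("divergences must lie in [0, 1)")
        if self.within_divergence >= self.between_divergence:
            raise ValueError("within_divergence must be < between_divergence")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))

def _mutate_protein(
    rng: np.random.Generator, seq: str, divergence: float
) -> str:
    """Substitute an exact round(divergence * L) count of positions."""
    n_mut = round(divergence * len(seq))
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in positions:
        choices = [a for a in AMINO_ACIDS if a != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


# --- assembly-line collections -----------------------------------------------

def make_assembly_lines(
    spec: FixtureSpec,
) -> tuple[AssemblyLine, list[AssemblyLine], dict]:
    """A query line plus references at increasing edit distance from it.

    Reference ``i`` is the query after ``i - 1`` random edits (clade
    substitution, domain duplication, adjacent swap), so reference 1 is an
    exact copy (distance 0) and edit counts increase with rank.  The returned
    truth manifest records the per-reference edit counts and the combined-
    distance ranking.  Every domain carries a synthetic protein sequence
    (per-clade ancestor mutated at 2%) so identity display can be exercised.
    """
    if spec.n_ref_lines < 2:
        raise ValueError("need at least 2 reference lines")
    rng = spec.rng()
    vocab = list(spec.clade_vocabulary)
    ancestors = {c: _random_protein(rng, 60) for c in vocab}

    query_clades = [vocab[rng.integers(len(vocab))] for _ in range(spec.query_line_length)]

    def build_line(line_id: str, clades: Sequence[str]) -> AssemblyLine:
        domains = []
        pos = 0
        for k, c in enumerate(clades):
            seq = _mutate_protein(rng, ancestors[c], 0.02)
            domains.append(
                DomainInstance(
                    clade=c,
                    parent_protein=f"{line_id}_orfA",
                    aa_start=pos,
                    aa_end=pos + len(seq),
                    sequence=seq,
                )
            )
            pos += len(seq)
        return AssemblyLine(id=line_id, domains=tuple(domains))

    query = build_line("query", query_clades)

    refs: list[AssemblyLine] = []
    edit_counts: dict[str, int] = {}
    for i in range(1, spec.n_ref_lines + 1):
        clades = list(query_clades)
        n_edits = i - 1
        for _ in range(n_edits):
            op = ("sub", "dup", "swap")[rng.integers(3)]
            pos = int(rng.integers(len(clades)))
            if op == "sub":
                choices = [c for c in vocab if c != clades[pos]]
                clades[pos] = choices[rng.integers(len(choices))]
            elif op == "dup":
                clades.insert(pos, clades[pos])
            elif op == "swap" and len(clades) > 1:
                q = min(pos, len(clades) - 2)
                clades[q], clades[q + 1] = clades[q + 1], clades[q]
        rid = f"ref_{i:03d}"
        refs.append(build_line(rid, clades))
        edit_counts[rid] = n_edits

    ranked = sorted(
        refs, key=lambda r: (combined_distance(query, r).d_combined, r.id)
    )
    truth = {
        "edit_counts": edit_counts,
        "ranking": [r.id for r in ranked],
    }
    return query, refs, truth


# --- labelled reference families ---------------------------------------------

def make_reference_families(
    spec: FixtureSpec,
) -> tuple[ReferenceSet, list[tuple[str, str]], dict[str, str]]:
    """Labelled protein families with controlled divergence, plus held-out queries.

    One ancestor per label, all derived from a common root mutated at
    ``between_divergence / 2`` (so pairwise ancestor separation is close to
    ``between_divergence``); members and queries are the label's ancestor
    mutated at ``within_divergence``.  Returns ``(refs, queries, true_labels)``
    with queries as (id, sequence) and ``true_labels`` keyed by query id.
    """
    if spec.n_labels < 2:
        raise ValueError("need at least 2 labels")
    rng = spec.rng()
    if spec.n_labels == len(DEFAULT_CYCLIZATION_LABELS):
        labels = list(DEFAULT_CYCLIZATION_LABELS)
    else:
        labels = [f"label_{k:02d}" for k in range(1, spec.n_labels + 1)]

    root = _random_protein(rng, spec.protein_length)
    ancestors = {
        lab: _mutate_protein(rng, root, spec.between_divergence / 2.0)
        for lab in labels
    }
    entries = []
    for lab_i, lab in enumerate(labels):
        for m in range(spec.seqs_per_label):
            seq = _mutate_protein(rng, ancestors[lab], spec.within_divergence)
            rid = f"ref_{lab_i:02d}_{m:02d}"
            entries.append(
                ReferenceEntry(
                    id=rid, sequence=seq, label=lab,
                    display_name=f"characterized enzyme {rid}",
                )
            )
    refs = ReferenceSet(entries=entries)

    queries: list[tuple[str, str]] = []
    true_labels: dict[str, str] = {}
    for q in range(spec.n_queries):
        lab = labels[q % len(labels)]
        seq = _mutate_protein(rng, ancestors[lab], spec.within_divergence)
        qid = f"query_{q:03d}"
        queries.append((qid, seq))
        true_labels[qid] = lab
    return refs, queries, true_labels


# --- toy GenBank with planted features ---------------------------------------

def _filler(rng: np.random.Generator, length: int) -> str:
    """Intergenic filler over {C,T}: start codon- and stop codon-free on both strands."""
    if length < 2:
        return "CT"[:length]
    body = "".join(rng.choice(["C", "T"], size=length - 2))
    return "C" + body + "T"  # 'T' before any following ATG forecloses a reverse-strand CAT


def _gene_dna(protein_body: str, tta_codon_indices: Sequence[int] = ()) -> str:
    """ATG + C/T-only codons + TAA; TTA (Leu) planted at the given codon indices.

    ``tta_codon_indices`` count the start codon as codon 0, so they must be
    >= 1 and <= len(protein_body).
    """
    codons = [_CT_CODONS[a] for a in protein_body]
    for idx in tta_codon_indices:
        codons[idx - 1] = "TTA"
    return "ATG" + "".join(codons) + "TAA"


def _ct_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_CT_RESIDUES), size=length))


def make_toy_genbank(
    spec: FixtureSpec,
    path: Union[str, Path],
) -> dict:
    """Write a toy GenBank record with planted CDS, TTA codons and a small ORF.

    The ground-truth manifest is returned and also written next to the record
    as ``<path>.manifest.json``.  Planted features: three CDS (two large, one
    small/annotated; the middle one on the reverse strand), three in-frame TTA
    codons, and one unannotated 25-aa ORF in intergenic space.
    """
    rng = spec.rng()
    path = Path(path)

    g1_body = _ct_protein(rng, 149)       # 150 aa with start M
    g1_tta = [10, 100]
    g2_body = _ct_protein(rng, 149)
    g2_tta = [25]
    g3_body = _ct_protein(rng, 39)        # 40 aa annotated small gene
    orf_body = _ct_protein(rng, 24)       # 25 aa planted intergenic ORF

    g1_dna = _gene_dna(g1_body, g1_tta)
    g2_dna = _gene_dna(g2_body, g2_tta)
    g3_dna = _gene_dna(g3_body)
    orf_dna = _gene_dna(orf_body)

    parts: list[str] = []
    offset = 0

    def push(seg: str) -> int:
        nonlocal offset
        start = offset
        parts.append(seg)
        offset += len(seg)
        return start

    push(_filler(rng, 60))
    g1_start = push(g1_dna)
    push(_filler(rng, 45))
    g2_start = push(str(Seq(g2_dna).reverse_complement()))
    push(_filler(rng, 50))
    orf_start = push(orf_dna)
    push(_filler(rng, 40))
    g3_start = push(g3_dna)
    push(_filler(rng, 60))
    sequence = "".join(parts)

    def protein_of(dna: str) -> str:
        return str(Seq(dna).translate(table=11)).rstrip("*")

    cds_specs = [
        ("g001", g1_start, g1_start + len(g1_dna), 1, protein_of(g1_dna)),
        ("g002", g2_start, g2_start + len(g2_dna), -1, protein_of(g2_dna)),
        ("g003", g3_start, g3_start + len(g3_dna), 1, protein_of(g3_dna)),
    ]

    record = SeqRecord(
        Seq(sequence),
        id="BGCKIT_TOY",
        name="BGCKIT_TOY",
        description="synthetic toy record with planted features",
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    for tag, start, end, strand, protein in cds_specs:
        record.features.append(
            SeqFeature(
                SimpleLocation(start, end, strand),
                type="CDS",
                qualifiers={"locus_tag": [tag], "translation": [protein]},
            )
        )
    SeqIO.write([record], str(path), "genbank")

    tta_hits = []
    for k in g1_tta:
        tta_hits.append(
            {
                "locus_tag": "g001",
                "codon_index": k,
                "genomic_start": g1_start + 3 * k,
                "genomic_end": g1_start + 3 * k + 3,
                "strand": 1,
            }
        )
    g2_end = g2_start + len(g2_dna)
    for k in g2_tta:
        tta_hits.append(
            {
                "locus_tag": "g002",
                "codon_index": k,
                "genomic_start": g2_end - 3 * (k + 1),
                "genomic_end": g2_end - 3 * k,
                "strand": -1,
            }
        )
    tta_hits.sort(key=lambda h: h["genomic_start"])

    manifest = {
        "record_id": "BGCKIT_TOY",
        "length": len(sequence),
        "cds": [
            {"locus_tag": t, "start": s, "end": e, "strand": st, "translation": p}
            for t, s, e, st, p in cds_specs
        ],
        "tta_hits": tta_hits,
        "planted_orf": {
            "start": orf_start,
            "end": orf_start + len(orf_dna),
            "strand": 1,
            "protein": protein_of(orf_dna),
        },
        "annotated_small_orf_tags": ["g003"],
    }
    Path(str(path) + ".manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
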