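"""RiPP precursor utilities: small-ORF discovery, leader cleavage, peptide mass.

RiPPs (ribosomally synthesized and post-translationally modified peptides)
begin as short gene-encoded precursors that standard gene callers frequently
miss.  :func:`find_small_orfs` therefore re-scans the intergenic space of an
annotated record for small open reading frames on both strands, alongside the
small genes already annotated.  :func:`cleave_precursor` splits a precursor at
a given leader/core boundary, and :func:`peptide_mass` computes monoisotopic
and average masses for a core peptide, optionally as a lasso peptide — i.e.
with an N-terminal macrolactam (isopeptide bond, loss of one water) and a
given number of disulfide bridges (loss of two hydrogens each).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq
from pyteomics import mass as _pmass

from .seqio import SeqRecordT, CdsFeature

START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_MIN_AA = 20
DEFAULT_MAX_AA = 120
DEFAULT_OVERLAP_ALLOWANCE_NT = 10

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

WATER_MONO = _pmass.calculate_mass(formula="H2O")
WATER_AVG = _pmass.calculate_mass(formula="H2O", average=True)
H_MONO = _pmass.calculate_mass(formula="H")
H_AVG = _pmass.calculate_mass(formula="H", average=True)

__all__ = [
    "OrfCandidate",
    "MassResult",
    "find_small_orfs",
    "cleave_precursor",
    "peptide_mass",
    "START_CODONS",
    "STOP_CODONS",
]


@dataclass(frozen=True)
class OrfCandidate:
    """A small-ORF candidate; coordinates are 0-based half-open on the forward axis.

    The extent includes the stop codon; ``protein`` does not include the stop
    and starts with M (alternative starts GTG/TTG are initiated with
    formyl-methionine in bacteria).
    """

    start: int
    end: int
    strand: int
    protein: str
    source: str  # "annotated" | "intergenic_scan"

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF extent must be a whole number of codons")
        if self.source not in ("annotated", "intergenic_scan"):
            raise ValueError(f"unknown ORF source {self.source!r}")


@dataclass(frozen=True)
class MassResult:
    monoisotopic_da: float
    average_da: float
    n_disulfides: int
    macrolactam: bool


def _max_cds_overlap(start: int, end: int, features: Sequence[CdsFeature]) -> int:
    best = 0
    for f in features:
        best = max(best, min(end, f.end) - max(start, f.start))
    return best


def _scan_strand(
    seq: str, min_aa: int, max_aa: int, starts: frozenset
) -> list[tuple[int, int, str]]:
    """All maximal start->stop ORFs on the forward reading of ``seq``.

    Per stop codon and frame the longest complete ORF (earliest start since
    the previous stop) is reported.  Returns (start, end, protein) tuples.
    """
    found = []
    n = len(seq)
    for frame in range(3):
        pending: Optional[int] = None  # earliest start since last stop
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if codon in STOP_CODONS:
                if pending is not None:
                    aa_len = (pos - pending) // 3
                    if min_aa <= aa_len <= max_aa:
                        coding = seq[pending:pos]
                        protein = str(Seq(coding).translate(table=11))
                        protein = "M" + protein[1:]
                        found.append((pending, pos + 3, protein))
                pending = None
            elif codon in starts and pending is None:
                pending = pos
    return found


def find_small_orfs(
    record: SeqRecordT,
    min_aa: int = DEFAULT_MIN_AA,
    max_aa: int = DEFAULT_MAX_AA,
    starts: frozenset = START_CODONS,
    overlap_allowance_nt: int = DEFAULT_OVERLAP_ALLOWANCE_NT,
) -> list[OrfCandidate]:
    """Small-ORF candidates: annotated small genes plus intergenic-scan hits.

    The six-frame scan reports every maximal start->stop ORF within the
    length bounds whose extent overlaps no annotated CDS by more than
    ``overlap_allowance_nt``.  Annotated CDS whose protein length falls within
    the bounds are returned with ``source="annotated"``.  Results are sorted
    by start coordinate.
    """
    out: list[OrfCandidate] = []
    for f in record.features:
        aa_len = len(f) // 3 - 1  # minus stop codon
        if min_aa <= aa_len <= max_aa:
            if f.translation is not None:
                protein = f.translation
            else:
                raw = record.sequence[f.start:f.end]
                if f.strand == -1:
                    raw = str(Seq(raw).reverse_complement())
                protein = str(Seq(raw).translate(table=11)).rstrip("*")
                if raw[:3] in START_CODONS:
                    protein = "M" + protein[1:]
            out.append(
                OrfCandidate(
                    start=f.start, end=f.end, strand=f.strand,
                    protein=protein, source="annotated",
                )
            )

    seq = record.sequence
    n = len(seq)
    hits: list[tuple[int, int, int, str]] = []
    for s, e, prot in _scan_strand(seq, min_aa, max_aa, starts):
        hits.append((s, e, 1, prot))
    rc = str(Seq(seq).reverse_complement())
    for s, e, prot in _scan_strand(rc, min_aa, max_aa, starts):
        hits.append((n - e, n - s, -1, prot))
    for s, e, strand, prot in hits:
        if _max_cds_overlap(s, e, record.features) > overlap_allowance_nt:
            continue
        out.append(
            OrfCandidate(start=s, end=e, strand=strand, protein=prot,
                         source="intergenic_scan")
        )
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def cleave_precursor(precursor: str, cleavage_site: int) -> tuple[str, str]:
    """Split a precursor at the first core residue: (leader, core).

    ``cleavage_site`` is the 0-based index of the first core residue; the
    concatenation of the two parts always restores the input.
    """
    if not 0 < cleavage_site < len(precursor):
        raise ValueError(
            f"cleavage_site must lie strictly inside the precursor "
            f"(got {cleavage_site} for length {len(precursor)})"
        )
    return precursor[:cleavage_site], precursor[cleavage_site:]


def peptide_mass(
    core: str,
    n_disulfides: int = 0,
    macrolactam: bool = False,
) -> MassResult:
    """Monoisotopic and average mass of a core peptide.

    mass = sum(residue masses) + water - (one water if macrolactam)
           - n_disulfides * 2 H

    The macrolactam term models the lasso peptide's N-terminal isopeptide
    ring (a condensation, losing one water); each disulfide bridge removes
    two hydrogens.  ``n_disulfides`` may not exceed the number of cysteine
    pairs in the core.
    """
    bad = sorted(set(core) - STANDARD_RESIDUES)
    if not core:
        raise ValueError("core peptide is empty")
    if bad:
        raise ValueError(f"non-standard residue(s) in core peptide: {', '.join(bad)}")
    if n_disulfides < 0:
        raise ValueError("n_disulfides must be >= 0")
    max_ss = core.count("C") // 2
    if n_disulfides > max_ss:
        raise ValueError(
            f"{n_disulfides} disulfide(s) requested but only {max_ss} cysteine "
            f"pair(s) available"
        )
    mono = _pmass.calculate_mass(sequence=core)
    avg = _pmass.calculate_mass(sequence=core, average=True)
    if macrolactam:
        mono -= WATER_MONO
        avg -= WATER_AVG
    mono -= n_disulfides * 2 * H_MONO
    avg -= n_disulfides * 2 * H_AVG
    return MassResult(
        monoisotopic_da=mono,
        average_da=avg,
        n_disulfides=n_disulfides,
        macrolactam=macrolactam,
    )
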