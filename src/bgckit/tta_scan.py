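"""TTA codon scanning and GC content.

In high-GC actinobacteria such as *Streptomyces*, the leucine codon TTA is
rare and read only by the *bldA* tRNA, whose expression is restricted to late
growth stages; genes carrying in-frame TTA codons are therefore subject to an
extra layer of translational regulation.  :func:`scan_tta` reports every
in-frame TTA codon within annotated CDS features (reverse-strand codons are
mapped back to forward-axis coordinates); :func:`gc_content` supplies the
genomic context that makes the signal meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

from .seqio import SeqRecordT

logger = logging.getLogger("bgckit")

GC_WARN_THRESHOLD = 0.6  # the biological rationale targets >70% GC genomes

__all__ = ["TtaHit", "scan_tta", "gc_content", "GC_WARN_THRESHOLD"]


@dataclass(frozen=True)
class TtaHit:
    """One in-frame TTA codon; genomic coordinates are 0-based half-open, forward axis."""

    locus_tag: str
    codon_index: int
    genomic_start: int
    genomic_end: int
    strand: int

    def __post_init__(self) -> None:
        if self.genomic_end - self.genomic_start != 3:
            raise ValueError("a TTA hit must span exactly one codon (3 nt)")

    def to_display(self) -> dict:
        """1-based inclusive coordinates for reports."""
        return {
            "locus_tag": self.locus_tag,
            "codon_index": self.codon_index,
            "start": self.genomic_start + 1,
            "end": self.genomic_end,
            "strand": "+" if self.strand == 1 else "-",
        }


def scan_tta(
    record: SeqRecordT,
    region: Optional[tuple[int, int]] = None,
    gc_gate: bool = True,
) -> list[TtaHit]:
    """All in-frame TTA codons in the record's CDS features.

    Only whole codons read on the coding strand count (the *bldA* rationale
    concerns translated leucines, not arbitrary TTA trinucleotides).  When
    ``region`` (0-based half-open) is given, only CDS overlapping it are
    scanned and only hits inside it reported.  A CDS length not divisible by
    3 leaves a trailing partial codon, which is ignored with a warning.
    With ``gc_gate`` a warning (never suppression) is logged when GC content
    is below the actinobacterial range.
    """
    if record.molecule_type != "dna":
        raise ValueError(f"record {record.id!r} is not DNA")
    if gc_gate and record.sequence:
        gc = gc_content(record)
        if gc < GC_WARN_THRESHOLD:
            logger.warning(
                "record %s GC content %.1f%% is below the high-GC range where "
                "TTA/bldA regulation applies; results may not be meaningful",
                record.id, 100 * gc,
            )
    hits: list[TtaHit] = []
    for cds in record.features:
        if region is not None:
            r0, r1 = region
            if cds.end <= r0 or cds.start >= r1:
                continue
        if len(cds) % 3 != 0:
            logger.warning(
                "CDS %s length %d not divisible by 3; trailing partial codon ignored",
                cds.locus_tag, len(cds),
            )
        coding = record.sequence[cds.start:cds.end]
        if cds.strand == -1:
            coding = str(Seq(coding).reverse_complement())
        n_codons = len(coding) // 3
        for k in range(n_codons):
            if coding[3 * k:3 * k + 3] != "TTA":
                continue
            if cds.strand == 1:
                g_start = cds.start + 3 * k
            else:
                g_start = cds.end - 3 * (k + 1)
            g_end = g_start + 3
            if region is not None and not (region[0] <= g_start and g_end <= region[1]):
                continue
            hits.append(
                TtaHit(
                    locus_tag=cds.locus_tag,
                    codon_index=k,
                    genomic_start=g_start,
                    genomic_end=g_end,
                    strand=cds.strand,
                )
            )
    hits.sort(key=lambda h: (h.genomic_start, h.locus_tag))
    return hits


def gc_content(record: SeqRecordT) -> float:
    """(G+C) / (A+C+G+T); N bases are excluded entirely."""
    seq = record.sequence
    if not seq:
        raise ValueError(f"record {record.id!r} has an empty sequence")
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"record {record.id!r} contains no unambiguous bases")
    return (counts["G"] + counts["C"]) / total
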