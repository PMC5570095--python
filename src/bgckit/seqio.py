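"""Input/output layer: GenBank and FASTA(+GFF3) reading, JSON report writing.

All records are normalised into a single light-weight model (:class:`SeqRecordT`
holding :class:`CdsFeature` annotations) with 0-based half-open coordinates
internally; anything user-facing (reports, GenBank feature fragments) is
printed 1-based inclusive, following the GenBank convention.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq, UndefinedSequenceError

logger = logging.getLogger("bgckit")

DNA_ALPHABET = set("ACGTN")
DEFAULT_TRANSLATION_TABLE = 11  # bacterial / archaeal / plant-plastid

__all__ = [
    "SeqRecordT",
    "CdsFeature",
    "ParseError",
    "read_genbank",
    "read_fasta_with_gff3",
    "extract_cds_translations",
    "write_report",
    "tta_feature_fragment",
]


class ParseError(ValueError):
    """Malformed input file (message names the offending location)."""


@dataclass(frozen=True)
class CdsFeature:
    """A coding sequence with 0-based half-open genomic coordinates.

    ``start``/``end`` give the overall extent on the forward axis; ``strand``
    is +1 or -1.  ``translation`` is the stored protein when the source
    annotation carried one.
    """

    locus_tag: str
    start: int
    end: int
    strand: int
    translation: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"CDS {self.locus_tag!r}: start must be < end, got {self.start}..{self.end}"
            )
        if self.strand not in (1, -1):
            raise ValueError(f"CDS {self.locus_tag!r}: strand must be +1/-1")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SeqRecordT:
    """One sequence record with its CDS features.

    ``molecule_type`` is ``"dna"`` or ``"protein"``; DNA sequences are
    uppercased and restricted to A/C/G/T/N.
    """

    id: str
    sequence: str
    features: list[CdsFeature] = field(default_factory=list)
    molecule_type: str = "dna"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.molecule_type == "dna":
            bad = set(self.sequence) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"record {self.id!r}: non-DNA characters {sorted(bad)}"
                )
        for f in self.features:
            if self.sequence and f.end > len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: feature {f.locus_tag!r} extends past "
                    f"sequence end ({f.end} > {len(self.sequence)})"
                )


def _locus_tag(biofeature, index: int) -> str:
    q = biofeature.qualifiers
    for key in ("locus_tag", "gene", "protein_id"):
        if key in q and q[key]:
            return str(q[key][0])
    return f"cds_{index}"


def read_genbank(path: Union[str, Path]) -> list[SeqRecordT]:
    """Parse a GenBank flat file into :class:`SeqRecordT` records.

    GenBank 1-based inclusive locations are converted to 0-based half-open;
    ``join(...)``/``complement(...)`` locations are resolved to a single
    extent min(start)..max(end) with strand ±1.  A record without an ORIGIN
    section is returned with an empty sequence and a logged warning.
    """
    path = Path(path)
    records: list[SeqRecordT] = []
    try:
        parsed = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ParseError(f"{path}: malformed GenBank record: {exc}") from exc
    if not parsed:
        raise ParseError(f"{path}: no GenBank records found")
    for rec in parsed:
        try:
            sequence = str(rec.seq)
        except UndefinedSequenceError:
            logger.warning("record %s has no ORIGIN sequence; flagged empty", rec.id)
            sequence = ""
        features: list[CdsFeature] = []
        seen_tags: set[str] = set()
        for i, f in enumerate(rec.features):
            if f.type != "CDS":
                continue
            tag = _locus_tag(f, i)
            if tag in seen_tags:
                raise ParseError(
                    f"{path}: record {rec.id}: duplicate locus_tag {tag!r}"
                )
            seen_tags.add(tag)
            # Biopython already exposes 0-based half-open coordinates; a
            # compound (join) location is collapsed to its overall extent.
            strand = f.location.strand
            if strand not in (1, -1):
                raise ParseError(
                    f"{path}: record {rec.id}: CDS {tag!r} has no usable strand"
                )
            translation = None
            if "translation" in f.qualifiers:
                translation = str(f.qualifiers["translation"][0])
            features.append(
                CdsFeature(
                    locus_tag=tag,
                    start=int(f.location.start),
                    end=int(f.location.end),
                    strand=int(strand),
                    translation=translation,
                )
            )
        features.sort(key=lambda c: (c.start, c.end, c.locus_tag))
        records.append(
            SeqRecordT(id=rec.id, sequence=sequence, features=features,
                       molecule_type="dna")
        )
    return records


def _parse_gff3_cds(path: Path) -> list[tuple[str, int, int, int, str]]:
    """Yield (seqid, start0, end, strand, id) for each GFF3 CDS line, in file order."""
    from gffutils.iterators import DataIterator

    out = []
    n = 0
    for feat in DataIterator(str(path)):
        if feat.featuretype != "CDS":
            continue
        n += 1
        if feat.strand == "-":
            strand = -1
        elif feat.strand == "+":
            strand = 1
        else:
            raise ParseError(
                f"{path}: CDS at {feat.seqid}:{feat.start}..{feat.end} lacks a strand"
            )
        ident = (
            feat.attributes.get("ID", [None])[0]
            or feat.attributes.get("locus_tag", [None])[0]
            or f"cds_{n}"
        )
        out.append((feat.seqid, feat.start - 1, feat.end, strand, ident))
    return out


def read_fasta_with_gff3(
    fasta: Union[str, Path],
    gff3: Optional[Union[str, Path]] = None,
) -> list[SeqRecordT]:
    """Read FASTA sequences, optionally annotated by a GFF3 file.

    CDS features are taken from GFF3 ``CDS`` lines (1-based inclusive
    converted to 0-based half-open).  Every GFF3 seqid must name a FASTA
    record; unmatched ids raise :class:`ParseError` listing them all.
    Without a GFF3 file the records carry no features.
    """
    fasta = Path(fasta)
    records = {
        rec.id: SeqRecordT(id=rec.id, sequence=str(rec.seq), molecule_type="dna")
        for rec in SeqIO.parse(str(fasta), "fasta")
    }
    if not records:
        raise ParseError(f"{fasta}: no FASTA records found")
    if gff3 is not None:
        cds_lines = _parse_gff3_cds(Path(gff3))
        unmatched = sorted({seqid for seqid, *_ in cds_lines if seqid not in records})
        if unmatched:
            raise ParseError(
                f"{gff3}: GFF3 seqids not present in FASTA: {', '.join(unmatched)}"
            )
        counters: dict[str, int] = {}
        for seqid, start, end, strand, ident in cds_lines:
            counters[seqid] = counters.get(seqid, 0) + 1
            records[seqid].features.append(
                CdsFeature(locus_tag=ident, start=start, end=end, strand=strand)
            )
    out = list(records.values())
    for rec in out:
        # re-run coordinate validation now that features are attached
        rec.__post_init__()
    return out


def _coding_sequence(record: SeqRecordT, cds: CdsFeature) -> str:
    raw = record.sequence[cds.start:cds.end]
    if cds.strand == -1:
        raw = str(Seq(raw).reverse_complement())
    return raw


def extract_cds_translations(
    record: SeqRecordT,
    table: int = DEFAULT_TRANSLATION_TABLE,
) -> list[tuple[str, str]]:
    """Protein sequences for every CDS of a DNA record.

    A stored ``/translation`` always wins; otherwise the coding-strand codons
    are translated with the given genetic code (default: table 11) and the
    trailing stop removed.  A CDS whose length is not divisible by 3 and that
    has no stored translation is skipped with a warning.
    """
    if record.molecule_type != "dna":
        raise ValueError(f"record {record.id!r} is not DNA")
    out: list[tuple[str, str]] = []
    for cds in record.features:
        if cds.translation is not None:
            out.append((cds.locus_tag, cds.translation))
            continue
        if len(cds) % 3 != 0:
            logger.warning(
                "CDS %s length %d not divisible by 3 and no stored translation; skipped",
                cds.locus_tag, len(cds),
            )
            continue
        coding = _coding_sequence(record, cds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # partial-codon warnings are pre-checked
            protein = str(Seq(coding).translate(table=table))
        out.append((cds.locus_tag, protein.rstrip("*")))
    return out


# --- report writing ----------------------------------------------------------

REPORT_VERSION = "bgckit-report/1"


def _round_floats(obj, sig: int = 6):
    """Recursively round floats to ``sig`` significant digits for stable output."""
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def write_report(results, path: Union[str, Path]) -> None:
    """Write a result bundle as deterministic JSON.

    Keys are sorted and floats rounded to 6 significant digits, so identical
    inputs always produce byte-identical files.
    """
    payload = {"version": REPORT_VERSION, "results": _round_floats(results)}
    text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
    Path(path).write_text(text)


def tta_feature_fragment(hits) -> str:
    """GenBank feature-table fragment annotating TTA codon hits.

    Coordinates are printed 1-based inclusive; reverse-strand hits use the
    ``complement(...)`` form.
    """
    lines = []
    for h in hits:
        loc = f"{h.genomic_start + 1}..{h.genomic_end}"
        if h.strand == -1:
            loc = f"complement({loc})"
        lines.append(f"     misc_feature    {loc}")
        lines.append(f'                     /note="TTA codon"')
        lines.append(f'                     /locus_tag="{h.locus_tag}"')
    return "\n".join(lines) + ("\n" if lines else "")
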