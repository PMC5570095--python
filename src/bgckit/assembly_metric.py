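"""Clade-profile distance between trans-AT PKS assembly lines.

A trans-AT polyketide synthase assembly line is modelled as the ordered
sequence of its ketosynthase (KS) domains, each labelled with the phylogenetic
clade it belongs to.  Because KS clades correlate with the chemistry of the
chain extension they catalyse, two assembly lines with similar clade profiles
are expected to produce related polyketides.

The distance between two lines combines three components:

* Jaccard distance on the *sets* of clade labels (which chemistries occur),
* Goodman-Kruskal gamma rank-correlation distance on the relative order of
  shared clades (in what order the chemistries occur),
* a domain duplication distance on per-clade copy numbers (how often each
  chemistry occurs),

weighted 0.5 / 0.25 / 0.25 by default.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np

DEFAULT_WEIGHTS = (0.5, 0.25, 0.25)

__all__ = [
    "DEFAULT_WEIGHTS",
    "DomainInstance",
    "AssemblyLine",
    "DistanceComponents",
    "jaccard_distance",
    "gamma_distance",
    "duplication_distance",
    "combined_distance",
    "distance_matrix",
    "lines_to_json",
    "lines_from_json",
    "lines_from_tsv",
]


class EmptyLineError(ValueError):
    """Raised when a distance is requested for an assembly line with no domains."""


@dataclass(frozen=True)
class DomainInstance:
    """One KS domain occurrence inside an assembly line.

    ``clade`` is the phylogenetic clade label; ``aa_start``/``aa_end`` locate
    the domain within ``parent_protein`` (0-based, half-open).  ``sequence``
    optionally carries the domain's amino-acid sequence so that per-domain
    identities can be reported.
    """

    clade: str
    parent_protein: str = ""
    aa_start: Optional[int] = None
    aa_end: Optional[int] = None
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.clade:
            raise ValueError("DomainInstance requires a non-empty clade label")
        if (
            self.aa_start is not None
            and self.aa_end is not None
            and not self.aa_start < self.aa_end
        ):
            raise ValueError(
                f"domain coordinates must satisfy aa_start < aa_end, "
                f"got {self.aa_start}..{self.aa_end}"
            )


@dataclass(frozen=True)
class AssemblyLine:
    """An ordered (N-to-C, gene order) sequence of clade-labelled KS domains."""

    id: str
    domains: tuple[DomainInstance, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "domains", tuple(self.domains))

    @property
    def clades(self) -> tuple[str, ...]:
        return tuple(d.clade for d in self.domains)

    def __len__(self) -> int:
        return len(self.domains)

    @classmethod
    def from_clades(cls, id: str, clades: Iterable[str]) -> "AssemblyLine":
        return cls(id=id, domains=tuple(DomainInstance(clade=c) for c in clades))


@dataclass(frozen=True)
class DistanceComponents:
    """The three metric components and their weighted combination."""

    d_jaccard: float
    d_gamma: float
    d_dup: float
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    d_combined: float = field(init=False)

    def __post_init__(self) -> None:
        w = self.weights
        combined = w[0] * self.d_jaccard + w[1] * self.d_gamma + w[2] * self.d_dup
        object.__setattr__(self, "d_combined", combined)


def _require_nonempty(*lines: AssemblyLine) -> None:
    for line in lines:
        if len(line) == 0:
            raise EmptyLineError(
                f"assembly line {line.id!r} has no domains; distance undefined"
            )


def jaccard_distance(a: AssemblyLine, b: AssemblyLine) -> float:
    """1 - |S_a ∩ S_b| / |S_a ∪ S_b| over the sets of clade labels."""
    _require_nonempty(a, b)
    sa, sb = set(a.clades), set(b.clades)
    return 1.0 - len(sa & sb) / len(sa | sb)


def _first_occurrence(clades: Sequence[str]) -> dict[str, int]:
    seen: dict[str, int] = {}
    for i, c in enumerate(clades):
        seen.setdefault(c, i)
    return seen


def gamma_distance(a: AssemblyLine, b: AssemblyLine) -> float:
    """Goodman-Kruskal gamma rank-concordance distance on shared clades.

    Every unordered pair of clade labels present in both lines is concordant
    when the first occurrences of the two labels appear in the same relative
    order in both lines, discordant otherwise; gamma = (C - D) / (C + D) is
    mapped onto a distance via (1 - gamma) / 2.  Degenerate cases: no shared
    label -> 1 (no order information, lines maximally unrelated); exactly one
    shared label -> 0 (one label carries no order conflict).
    """
    _require_nonempty(a, b)
    shared = set(a.clades) & set(b.clades)
    if len(shared) == 0:
        return 1.0
    if len(shared) == 1:
        return 0.0
    pa = _first_occurrence(a.clades)
    pb = _first_occurrence(b.clades)
    concordant = discordant = 0
    for x, y in combinations(sorted(shared), 2):
        if (pa[x] - pa[y]) * (pb[x] - pb[y]) > 0:
            concordant += 1
        else:
            discordant += 1
    gamma = (concordant - discordant) / (concordant + discordant)
    return (1.0 - gamma) / 2.0


def duplication_distance(a: AssemblyLine, b: AssemblyLine) -> float:
    """Copy-number disagreement over shared clades: sum|Δn| / sum max(n_a, n_b).

    Restricted to shared labels so that presence/absence (already measured by
    the Jaccard component) is not counted twice; no shared labels -> 1.
    """
    _require_nonempty(a, b)
    ca, cb = Counter(a.clades), Counter(b.clades)
    shared = set(ca) & set(cb)
    if not shared:
        return 1.0
    num = sum(abs(ca[c] - cb[c]) for c in shared)
    den = sum(max(ca[c], cb[c]) for c in shared)
    return num / den


def _check_weights(weights: Sequence[float]) -> tuple[float, float, float]:
    w = tuple(float(x) for x in weights)
    if len(w) != 3 or any(x < 0 for x in w):
        raise ValueError(f"weights must be three non-negative numbers, got {weights!r}")
    if abs(sum(w) - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got sum {sum(w)!r})")
    return w  # type: ignore[return-value]


def combined_distance(
    a: AssemblyLine,
    b: AssemblyLine,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
) -> DistanceComponents:
    """All three components plus their weighted sum (default weights 0.5/0.25/0.25)."""
    w = _check_weights(weights)
    return DistanceComponents(
        d_jaccard=jaccard_distance(a, b),
        d_gamma=gamma_distance(a, b),
        d_dup=duplication_distance(a, b),
        weights=w,
    )


def distance_matrix(
    lines: Sequence[AssemblyLine],
    weights: Sequence[float] = DEFAULT_WEIGHTS,
) -> tuple[np.ndarray, list[str]]:
    """Symmetric combined-distance matrix over ``lines``.

    Returns ``(matrix, ids)`` with a zero diagonal; line ids must be unique.
    """
    if len(lines) < 2:
        raise ValueError("distance_matrix requires at least 2 assembly lines")
    ids = [line.id for line in lines]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate assembly-line ids: {dupes}")
    n = len(lines)
    mat = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = combined_distance(lines[i], lines[j], weights).d_combined
            mat[i, j] = mat[j, i] = d
    return mat, ids


# --- assembly-line serialization (JSON and 3-column TSV) ---------------------

def lines_to_json(lines: Sequence[AssemblyLine]) -> str:
    payload = [
        {
            "id": line.id,
            "domains": [
                {
                    "clade": d.clade,
                    "protein": d.parent_protein,
                    "start": d.aa_start,
                    "end": d.aa_end,
                    **({"sequence": d.sequence} if d.sequence else {}),
                }
                for d in line.domains
            ],
        }
        for line in lines
    ]
    return json.dumps(payload, indent=2, sort_keys=True)


def lines_from_json(text: str) -> list[AssemblyLine]:
    raw = json.loads(text)
    if isinstance(raw, dict):
        raw = [raw]
    lines = []
    for entry in raw:
        domains = tuple(
            DomainInstance(
                clade=d["clade"],
                parent_protein=d.get("protein", ""),
                aa_start=d.get("start"),
                aa_end=d.get("end"),
                sequence=d.get("sequence"),
            )
            for d in entry.get("domains", [])
        )
        lines.append(AssemblyLine(id=entry["id"], domains=domains))
    return lines


def lines_from_tsv(text: str) -> list[AssemblyLine]:
    """3-column TSV: line_id, position (0-based), clade."""
    rows: dict[str, list[tuple[int, str]]] = {}
    order: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        raw = raw.strip()
        if not raw or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) != 3:
            raise ValueError(f"TSV line {lineno}: expected 3 columns, got {len(parts)}")
        line_id, pos, clade = parts
        if line_id not in rows:
            rows[line_id] = []
            order.append(line_id)
        rows[line_id].append((int(pos), clade))
    return [
        AssemblyLine.from_clades(lid, [c for _, c in sorted(rows[lid])])
        for lid in order
    ]
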