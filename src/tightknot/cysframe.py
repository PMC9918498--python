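"""Cysteine framework extraction and disulfide-connectivity classification.

Cysteine-rich arthropod peptides are classified by their disulfide
pairing pattern, written in cysteine-ordinal space (C1..Cn by order of
appearance in the sequence), not by sequence homology. The registry holds
the scaffold families relevant to spider venom/digestive peptides:
the inhibitor cystine knot (ICK), the disulfide-directed beta-hairpin
(DDH), Kunitz, Kazal, HAND and the five-disulfide colipase-like
MIT1/atracotoxin fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .seqprops import ProteinSequence


@dataclass(frozen=True)
class CysFramework:
    """Cysteine positions (1-based), count and inter-cysteine spacings."""

    positions: tuple[int, ...]
    count: int
    spacings: tuple[int, ...]


@dataclass(frozen=True)
class ConnectivityPattern:
    """Disulfide bonds as unordered pairs of cysteine ordinals (i < j)."""

    bonds: frozenset[tuple[int, int]]

    @classmethod
    def from_pairs(cls, pairs) -> "ConnectivityPattern":
        bonds = set()
        seen = set()
        for i, j in pairs:
            i, j = int(i), int(j)
            if i == j:
                raise ValidationError(f"bonds: ordinal C{i} paired with itself")
            i, j = min(i, j), max(i, j)
            for o in (i, j):
                if o < 1:
                    raise ValidationError("bonds: ordinals are 1-based")
                if o in seen:
                    raise ValidationError(f"bonds: ordinal C{o} appears in more than one bond")
                seen.add(o)
            bonds.add((i, j))
        return cls(frozenset(bonds))

    @classmethod
    def from_string(cls, text: str) -> "ConnectivityPattern":
        """Parse "1-4,2-5,3-6" style bond lists."""
        pairs = []
        for part in text.replace(" ", "").split(","):
            i, j = part.split("-")
            pairs.append((int(i), int(j)))
        return cls.from_pairs(pairs)

    @property
    def n_cys(self) -> int:
        return max((o for b in self.bonds for o in b), default=0)


@dataclass(frozen=True)
class FamilyTemplate:
    name: str
    n_cys: int
    connectivity: ConnectivityPattern | None
    valid: bool = True          # False: pattern recorded verbatim but not matchable
    source_note: str = ""


def _pattern(pairs):
    bonds = frozenset((min(i, j), max(i, j)) for i, j in pairs)
    return ConnectivityPattern(bonds)


#: Scaffold family registry. The DDH pattern circulating in the
#: literature, (C1-C2, C2-C4), reuses C2 and cannot be a valid pairing;
#: it is stored verbatim with ``valid=False`` and never exact-matched.
#: HAND is described only by its cysteine count; its connectivity is
#: unspecified and it participates only in count pre-screening.
FAMILY_REGISTRY: tuple[FamilyTemplate, ...] = (
    FamilyTemplate("ICK", 6, _pattern([(1, 4), (2, 5), (3, 6)]),
                   source_note="inhibitor cystine knot, three disulfides"),
    FamilyTemplate("DDH", 4, _pattern([(1, 2), (2, 4)]), valid=False,
                   source_note="disulfide-directed beta-hairpin; published "
                               "pattern reuses C2 and is stored verbatim"),
    FamilyTemplate("Kunitz", 6, _pattern([(1, 6), (2, 4), (3, 5)]),
                   source_note="Kunitz serine-protease inhibitor domain"),
    FamilyTemplate("Kazal", 6, _pattern([(1, 5), (2, 4), (3, 6)]),
                   source_note="Kazal serine-protease inhibitor domain"),
    FamilyTemplate("HAND", 6, None,
                   source_note="arthropod HAND motif; connectivity unspecified"),
    FamilyTemplate("MIT1-colipase", 10,
                   _pattern([(1, 4), (2, 5), (3, 7), (6, 9), (8, 10)]),
                   source_note="colipase-like/MIT1 atracotoxin fold, five disulfides"),
)


@dataclass(frozen=True)
class FamilyMatch:
    name: str | None
    exact: bool
    score: float                      # bond-set Jaccard similarity
    mismatches: tuple[tuple[int, int], ...]   # symmetric difference of bonds
    ambiguous_with: tuple[str, ...] = ()


def get_template(name: str) -> FamilyTemplate:
    for t in FAMILY_REGISTRY:
        if t.name == name:
            return t
    raise ValidationError(f"template: unknown family {name!r}; "
                          f"known: {[t.name for t in FAMILY_REGISTRY]}")


def extract_framework(seq: ProteinSequence) -> CysFramework:
    """All cysteine positions with inter-cysteine spacings (residues between)."""
    positions = tuple(i + 1 for i, a in enumerate(seq.residues) if a == "C")
    spacings = tuple(b - a - 1 for a, b in zip(positions, positions[1:]))
    return CysFramework(positions=positions, count=len(positions), spacings=spacings)


def classify_connectivity(pattern: ConnectivityPattern) -> FamilyMatch:
    """Match a disulfide pattern against the family registry.

    An exact bond-set match wins; otherwise the nearest valid template by
    Jaccard similarity of bond sets is reported with the mismatching
    bonds, and ties are flagged as ambiguous.
    """
    matchable = [t for t in FAMILY_REGISTRY if t.valid and t.connectivity is not None]
    scored = []
    for t in matchable:
        tb = t.connectivity.bonds
        union = pattern.bonds | tb
        jac = len(pattern.bonds & tb) / len(union) if union else 1.0
        scored.append((jac, t))
    scored.sort(key=lambda x: (-x[0], x[1].name))
    best_score, best = scored[0]
    if pattern.bonds == best.connectivity.bonds:
        return FamilyMatch(name=best.name, exact=True, score=1.0, mismatches=())
    ties = tuple(t.name for s, t in scored[1:] if s == best_score)
    mism = tuple(sorted(pattern.bonds ^ best.connectivity.bonds))
    return FamilyMatch(name=best.name, exact=False, score=best_score,
                       mismatches=mism, ambiguous_with=ties)


def candidate_families(framework: CysFramework) -> list[FamilyTemplate]:
    """Sequence-only pre-screen: templates with a matching cysteine count."""
    return sorted((t for t in FAMILY_REGISTRY if t.n_cys == framework.count),
                  key=lambda t: t.name)


def conserved_cys_columns(alignment, gap_tolerance: float = 0.0) -> list[int]:
    """1-based alignment columns conserved as cysteine.

    ``alignment`` is a list of equal-length aligned strings (or objects
    with a ``residues``/``seq`` attribute). A column qualifies when every
    non-gap symbol is C and the gap fraction is <= ``gap_tolerance``.
    """
    rows = []
    for entry in alignment:
        s = getattr(entry, "residues", None) or str(getattr(entry, "seq", entry))
        rows.append(s.upper())
    if len(rows) < 2:
        raise ValidationError("alignment: at least 2 sequences required")
    if len({len(r) for r in rows}) != 1:
        raise ValidationError("alignment: ragged (unequal aligned lengths)")
    cols = []
    for c in range(len(rows[0])):
        column = [r[c] for r in rows]
        gaps = sum(x in "-." for x in column)
        nongap = [x for x in column if x not in "-."]
        if nongap and all(x == "C" for x in nongap) and gaps / len(column) <= gap_tolerance:
            cols.append(c + 1)
    return cols
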