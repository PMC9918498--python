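"""Sequence-level physicochemistry and motif analysis.

Covers the desk computations routinely reported for a newly isolated
peptide: theoretical average/monoisotopic mass, isoelectric point by
charge-balance bisection, mature-chain derivation from an annotated
signal-peptide cleavage site, PEST degradation-motif scoring, global
pairwise identity, peptide-to-protein sequence coverage and molecular
mass estimation from SDS-PAGE relative migration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .errors import ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
WATER_AVERAGE = 18.01528
WATER_MONOISOTOPIC = 18.010565

#: Average residue (amino acid minus water) masses in Da.
RESIDUE_MASS_AVERAGE = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

#: Monoisotopic residue masses in Da.
RESIDUE_MASS_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

#: Kyte-Doolittle hydropathy values.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Bjellqvist pKa values as used by the ExPASy Compute pI tool. The
#: terminal pKa depends on the terminal residue; ``n_term``/``c_term``
#: are the generic values and ``n_term_by_residue``/``c_term_by_residue``
#: the residue-specific overrides.
BJELLQVIST_PKA = {
    "n_term": 7.5, "c_term": 3.55,
    "K": 10.0, "R": 12.0, "H": 5.98,
    "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
    "n_term_by_residue": {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36,
                          "T": 6.82, "V": 7.44, "E": 7.7},
    "c_term_by_residue": {"D": 4.55, "E": 4.75},
}


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with optional signal-peptide annotation.

    Parameters
    ----------
    id : str
        Sequence identifier.
    residues : str
        One-letter residues over the 20-letter alphabet; ``X`` marks an
        unknown residue and is excluded from mass and pI arithmetic.
    cleavage : int, optional
        1-based index of the last signal-peptide residue; cleavage occurs
        after this position.
    """

    id: str
    residues: str
    cleavage: int | None = None

    def __post_init__(self):
        if not self.residues:
            raise ValidationError("residues: sequence must be non-empty")
        bad = set(self.residues.upper()) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValidationError(f"residues: invalid letters {sorted(bad)}")
        object.__setattr__(self, "residues", self.residues.upper())
        if self.cleavage is not None and not 0 < self.cleavage < len(self.residues):
            raise ValidationError("cleavage: index must satisfy 0 < cleavage < length")

    def __len__(self):
        return len(self.residues)


@dataclass(frozen=True)
class PestMotif:
    """A PEST candidate window with its score.

    ``start``/``end`` are 1-based inclusive coordinates of the scored core
    (positively charged flanks excluded); ``window_sequence`` includes the
    leading flank residue, when present, for display.
    """

    start: int
    end: int
    window_sequence: str
    score: float


@dataclass(frozen=True)
class PhysChemProfile:
    average_mass: float
    monoisotopic_mass: float
    pi: float
    length: int


def read_fasta(path) -> list[ProteinSequence]:
    return [ProteinSequence(id=r.id, residues=str(r.seq)) for r in SeqIO.parse(path, "fasta")]


def write_fasta(seqs, path) -> None:
    with open(path, "w") as fh:
        for s in seqs if isinstance(seqs, (list, tuple)) else [seqs]:
            fh.write(f">{s.id}\n{s.residues}\n")


def _clean(seq: ProteinSequence, allow_unknown: bool) -> str:
    residues = seq.residues
    if "X" in residues:
        if not allow_unknown:
            raise ValidationError("residues: unknown residue X present "
                                  "(pass allow_unknown=True to skip it)")
        residues = residues.replace("X", "")
        if not residues:
            raise ValidationError("residues: no known residues left after removing X")
    return residues


def average_mass(seq: ProteinSequence, allow_unknown: bool = False) -> float:
    """Average (isotope-abundance-weighted) mass in Da, including one water.

    Sum of average residue masses plus one water, so concatenation is
    exactly additive up to one water per peptide bond.
    """
    residues = _clean(seq, allow_unknown)
    return sum(RESIDUE_MASS_AVERAGE[a] for a in residues) + WATER_AVERAGE


def monoisotopic_mass(seq: ProteinSequence, allow_unknown: bool = False) -> float:
    """Monoisotopic mass in Da, including one water."""
    residues = _clean(seq, allow_unknown)
    return sum(RESIDUE_MASS_MONO[a] for a in residues) + WATER_MONOISOTOPIC


def net_charge(seq: ProteinSequence, ph: float, pka: dict | None = None) -> float:
    """Net charge at ``ph`` from Henderson–Hasselbalch terms.

    Positive contributions: N-terminus, K, R, H. Negative: C-terminus,
    D, E, C, Y. The pKa table defaults to the Bjellqvist set and is
    swappable.
    """
    pka = pka or BJELLQVIST_PKA
    residues = _clean(seq, allow_unknown=True)
    counts = {aa: residues.count(aa) for aa in "KRHDECY"}
    pk_n = pka.get("n_term_by_residue", {}).get(residues[0], pka["n_term"])
    pk_c = pka.get("c_term_by_residue", {}).get(residues[-1], pka["c_term"])
    pos = 1.0 / (1.0 + 10 ** (ph - pk_n))
    for aa in "KRH":
        pos += counts[aa] / (1.0 + 10 ** (ph - pka[aa]))
    neg = 1.0 / (1.0 + 10 ** (pk_c - ph))
    for aa in "DECY":
        neg += counts[aa] / (1.0 + 10 ** (pka[aa] - ph))
    return pos - neg


def isoelectric_point(seq: ProteinSequence, pka: dict | None = None,
                      tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so the root is
    unique.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def mature_sequence(seq: ProteinSequence) -> ProteinSequence:
    """Chain remaining after signal-peptide cleavage, id suffixed ``_mature``."""
    if seq.cleavage is None:
        raise ValidationError("cleavage: annotation required to derive the mature chain")
    return ProteinSequence(id=seq.id + "_mature",
                           residues=seq.residues[seq.cleavage:])


# ---------------------------------------------------------------------------
# PEST motif scoring
# ---------------------------------------------------------------------------

PEST_RESIDUES = "DEPST"
POSITIVE_FLANKS = "KRH"


def pest_score(window: str, *, mass_weighted: bool = True,
               one_equivalent: bool = True, strip_flanks: bool = True) -> float:
    """PEST-find score of a candidate window.

    score = 0.55 * DEPST - 0.5 * hydrophobicity index, where DEPST is the
    percent of D/E/P/S/T in the window (mass-weighted by default, with one
    equivalent each of D-or-E, P and S-or-T subtracted so only the excess
    beyond the qualifying minimum counts) and the hydrophobicity index is
    the mole-fraction average of Kyte-Doolittle hydropathy rescaled to
    0 (Arg) .. 90 (Ile) via 10*(h + 4.5).

    A leading/trailing positively charged flank residue (K/R/H) is
    stripped before scoring unless ``strip_flanks`` is False; flanks
    delimit the motif but are not part of it.
    """
    window = window.upper()
    if strip_flanks:
        if window and window[0] in POSITIVE_FLANKS:
            window = window[1:]
        if window and window[-1] in POSITIVE_FLANKS:
            window = window[:-1]
    if not window:
        raise ValidationError("window: empty after flank removal")
    n = len(window)
    if mass_weighted:
        total = sum(RESIDUE_MASS_AVERAGE[a] for a in window)
        pest = sum(RESIDUE_MASS_AVERAGE[a] for a in window if a in PEST_RESIDUES)
        if one_equivalent:
            for group in ("DE", "P", "ST"):
                masses = [RESIDUE_MASS_AVERAGE[a] for a in window if a in group]
                if masses:
                    pest -= min(masses)
        depst = 100.0 * pest / total
    else:
        count = sum(1 for a in window if a in PEST_RESIDUES)
        if one_equivalent:
            count -= sum(1 for g in ("DE", "P", "ST") if any(a in g for a in window))
        depst = 100.0 * count / n
    hydro = sum(10.0 * (KYTE_DOOLITTLE[a] + 4.5) for a in window) / n
    return 0.55 * depst - 0.5 * hydro


def find_pest(seq: ProteinSequence, min_core: int = 12, **score_kw) -> list[PestMotif]:
    """Candidate PEST motifs: maximal stretches between positive flanks.

    A stretch qualifies if its core (between K/R/H flanks) has length >=
    ``min_core`` and contains at least one P, one D or E and one S or T.
    """
    s = seq.residues
    motifs = []
    i = 0
    while i < len(s):
        if s[i] in POSITIVE_FLANKS or s[i] == "X":
            i += 1
            continue
        j = i
        while j < len(s) and s[j] not in POSITIVE_FLANKS and s[j] != "X":
            j += 1
        core = s[i:j]
        if (len(core) >= min_core and "P" in core
                and any(a in core for a in "DE") and any(a in core for a in "ST")):
            display = (s[i - 1] if i > 0 and s[i - 1] in POSITIVE_FLANKS else "") + core
            motifs.append(PestMotif(start=i + 1, end=j,
                                    window_sequence=display,
                                    score=pest_score(core, strip_flanks=False, **score_kw)))
        i = j
    return motifs


# ---------------------------------------------------------------------------
# Identity, coverage, gel migration
# ---------------------------------------------------------------------------

def _aligner(matrix: str, open_gap: float, extend_gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(open_gap)
    aligner.extend_gap_score = -abs(extend_gap)
    return aligner


def pairwise_identity(a: ProteinSequence, b: ProteinSequence, *,
                      matrix: str = "BLOSUM62", open_gap: float = 10.0,
                      extend_gap: float = 0.5,
                      denominator: str = "columns") -> float:
    """Percent identity from a global alignment (affine gaps).

    ``denominator``: "columns" (alignment length including gaps, the
    default) or "shorter" (length of the shorter sequence); the choice
    matters only when gaps are opened.
    """
    aln = _aligner(matrix, open_gap, extend_gap).align(a.residues, b.residues)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(s1, s2))
    if denominator == "columns":
        denom = len(s1)
    elif denominator == "shorter":
        denom = min(len(a), len(b))
    else:
        raise ValidationError(f"denominator: unknown convention {denominator!r}")
    return 100.0 * matches / denom


def sequence_coverage(peptides: list[str], protein: ProteinSequence) -> float:
    """Percent of protein residues covered by exact peptide matches.

    All occurrences of each peptide contribute; overlapping spans are
    merged. Peptides absent from the protein contribute nothing and are
    reported via a warning.
    """
    if not peptides or any(not p for p in peptides):
        raise ValidationError("peptides: non-empty strings required")
    covered = np.zeros(len(protein), dtype=bool)
    unmatched = []
    target = protein.residues
    for pep in peptides:
        pep = pep.upper()
        start, hit = 0, False
        while (idx := target.find(pep, start)) != -1:
            covered[idx:idx + len(pep)] = True
            hit = True
            start = idx + 1
        if not hit:
            unmatched.append(pep)
    if unmatched:
        warnings.warn(f"{len(unmatched)} peptide(s) not found in {protein.id}: "
                      f"{unmatched[:5]}", stacklevel=2)
    return 100.0 * covered.sum() / len(protein)


def mass_from_relative_migration(rm: float, standards: list[tuple[float, float]]) -> float:
    """Molecular mass (kDa) from SDS-PAGE relative migration.

    Fits log10(mass) linearly against Rm over the marker standards
    (``(mass_kDa, rm)`` pairs) and evaluates the fit at ``rm``.
    """
    if len(standards) < 2:
        raise ValidationError("standards: at least two (mass, rm) pairs required")
    if not 0 < rm <= 1:
        raise ValidationError("rm: relative migration must lie in (0, 1]")
    masses, rms = zip(*standards)
    b, a = np.polyfit(rms, np.log10(masses), 1)
    return float(10 ** (a + b * rm))


def physchem_profile(seq: ProteinSequence, pka: dict | None = None,
                     allow_unknown: bool = False) -> PhysChemProfile:
    return PhysChemProfile(
        average_mass=average_mass(seq, allow_unknown),
        monoisotopic_mass=monoisotopic_mass(seq, allow_unknown),
        pi=isoelectric_point(seq, pka),
        length=len(seq),
    )
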