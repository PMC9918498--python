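"""Geometry analysis of enzyme-inhibitor structure models.

Works on docking poses or experimental coordinates in PDB format:
hydrogen-bond detection across two chains, interface residue pairs with
main-chain/side-chain classification, point distance measurements and
sequence-level identification of candidate reactive-site loops (the
substrate-like Lys/Arg-bearing loops a canonical serine-protease
inhibitor inserts into the S1 pocket).

Hydrogen atoms are usually absent from models, so donors are identified
heavy-atom-only: nitrogen atoms and hydroxyl/thiol-bearing oxygens that
carry hydrogens in standard residue templates, paired with N/O
acceptors by a distance criterion (default 3.5 A).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import ParseError, ValidationError
from .cysframe import CysFramework, extract_framework
from .seqprops import ProteinSequence

MAIN_CHAIN_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: Side-chain oxygens carrying a hydrogen in standard residue templates.
HYDROXYL_OXYGENS = {"OG", "OG1", "OH", "OW"}

#: His ring nitrogens can accept when unprotonated.
RING_N_ACCEPTORS = {"ND1", "NE2"}


@dataclass(frozen=True)
class AtomRef:
    chain: str
    res_name: str
    res_id: int
    atom_name: str

    def __str__(self):
        return f"{self.chain}/{self.res_name}{self.res_id}/{self.atom_name}"


@dataclass(frozen=True)
class HydrogenBond:
    donor: AtomRef
    acceptor: AtomRef
    distance: float


@dataclass(frozen=True)
class InterfaceContact:
    residue_a: tuple[str, int]        # (res_name, res_id) on chain A
    residue_b: tuple[str, int]
    min_distance: float
    contact_class: str                # main-main / main-side / side-side
    flagged: bool = False


@dataclass(frozen=True)
class InterfaceReport:
    chain_a: str
    chain_b: str
    cutoff: float
    contacts: tuple[InterfaceContact, ...]


@dataclass(frozen=True)
class CandidateLoop:
    label: str
    positions: tuple[int, ...]        # contiguous 1-based residue indices
    basic_residues: dict              # position -> K or R


class StructureModel:
    """Thin wrapper around a biotite ``AtomArray``."""

    def __init__(self, atoms: struc.AtomArray):
        if len(atoms) == 0:
            raise ParseError("structure: no atoms")
        if np.any(~np.isfinite(atoms.coord)):
            raise ValidationError("structure: non-finite coordinates")
        keys = list(zip(atoms.chain_id, atoms.res_id, atoms.atom_name))
        if len(keys) != len(set(keys)):
            raise ValidationError("structure: duplicate (chain, residue, atom) records")
        self.atoms = atoms

    @property
    def chains(self) -> list[str]:
        return sorted(set(self.atoms.chain_id))

    def __len__(self):
        return len(self.atoms)

    def chain(self, chain_id: str) -> struc.AtomArray:
        sel = self.atoms[self.atoms.chain_id == chain_id]
        if len(sel) == 0:
            raise ValidationError(f"chain: {chain_id!r} not present (have {self.chains})")
        return sel

    def atom(self, ref) -> struc.Atom:
        chain, res_id, atom_name = (ref.chain, ref.res_id, ref.atom_name) \
            if isinstance(ref, AtomRef) else ref
        mask = ((self.atoms.chain_id == chain)
                & (self.atoms.res_id == int(res_id))
                & (self.atoms.atom_name == atom_name))
        if mask.sum() != 1:
            raise ValidationError(f"atom: reference {chain}/{res_id}/{atom_name} "
                                  f"resolved {int(mask.sum())} atoms")
        return self.atoms[mask][0]


def parse_structure(text: str, include_hetatm: bool = False) -> StructureModel:
    """Parse PDB-format text into a structure model.

    Raises a parse error naming the line when a coordinate field is
    malformed, and when no ATOM record is present.
    """
    for ln, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            try:
                [float(line[i:j]) for i, j in ((30, 38), (38, 46), (46, 54))]
            except ValueError as exc:
                raise ParseError(f"line {ln}: malformed coordinate field: {line!r}") from exc
    pdb = PDBFile.read(io.StringIO(text))
    try:
        atoms = pdb.get_structure(model=1)
    except Exception as exc:
        raise ParseError(f"structure: {exc}") from exc
    if not include_hetatm:
        atoms = atoms[~atoms.hetero]
    if len(atoms) == 0:
        raise ParseError("structure: no ATOM records")
    return StructureModel(atoms)


def write_pdb(model: StructureModel) -> str:
    pdb = PDBFile()
    pdb.set_structure(model.atoms)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


def measure_distance(model: StructureModel, ref_1, ref_2) -> float:
    """Euclidean distance (A) between two atom references."""
    a = model.atom(ref_1)
    b = model.atom(ref_2)
    return float(np.linalg.norm(a.coord - b.coord))


def _is_donor(atom) -> bool:
    name = atom.atom_name
    if name.startswith("N"):
        return True
    return name in HYDROXYL_OXYGENS


def _is_acceptor(atom) -> bool:
    name = atom.atom_name
    if name.startswith("O"):
        return True
    return name in RING_N_ACCEPTORS


def _ref(atom) -> AtomRef:
    return AtomRef(chain=str(atom.chain_id), res_name=str(atom.res_name),
                   res_id=int(atom.res_id), atom_name=str(atom.atom_name))


def find_hbonds(model: StructureModel, chain_a: str, chain_b: str,
                cutoff: float = 3.5) -> list[HydrogenBond]:
    """Inter-chain hydrogen bonds by heavy-atom distance criterion.

    Donor/acceptor pairs are evaluated in both directions (donors of
    either chain against acceptors of the other); results are sorted by
    distance.
    """
    a = model.chain(chain_a)
    b = model.chain(chain_b)
    bonds = []
    for donors, acceptors in ((a, b), (b, a)):
        don = donors[[_is_donor(at) for at in donors]]
        acc = acceptors[[_is_acceptor(at) for at in acceptors]]
        if len(don) == 0 or len(acc) == 0:
            continue
        d = np.linalg.norm(don.coord[:, None, :] - acc.coord[None, :, :], axis=-1)
        for i, j in zip(*np.where(d <= cutoff)):
            bonds.append(HydrogenBond(donor=_ref(don[int(i)]),
                                      acceptor=_ref(acc[int(j)]),
                                      distance=float(d[i, j])))
    bonds.sort(key=lambda h: (h.distance, str(h.donor), str(h.acceptor)))
    return bonds


def interface_residues(model: StructureModel, chain_a: str, chain_b: str,
                       cutoff: float = 4.0,
                       flag_residues: list[int] | None = None) -> InterfaceReport:
    """Residue pairs across the interface with any-atom distance <= cutoff.

    Each pair is classified main-main / main-side / side-side by the atom
    pair achieving the minimum distance. ``flag_residues`` marks contacts
    involving listed residue numbers (on either chain), e.g. catalytic or
    specificity-pocket residues.
    """
    a = model.chain(chain_a)
    b = model.chain(chain_b)
    d = np.linalg.norm(a.coord[:, None, :] - b.coord[None, :, :], axis=-1)
    flag = set(flag_residues or [])
    pairs = {}
    for i, j in zip(*np.where(d <= cutoff)):
        key = (int(a.res_id[i]), int(b.res_id[j]))
        if key not in pairs or d[i, j] < pairs[key][0]:
            pairs[key] = (float(d[i, j]), int(i), int(j))
    contacts = []
    for (ra, rb), (dist, i, j) in sorted(pairs.items()):
        cls_a = "main" if a.atom_name[i] in MAIN_CHAIN_ATOMS else "side"
        cls_b = "main" if b.atom_name[j] in MAIN_CHAIN_ATOMS else "side"
        contacts.append(InterfaceContact(
            residue_a=(str(a.res_name[i]), ra),
            residue_b=(str(b.res_name[j]), rb),
            min_distance=dist,
            contact_class=f"{cls_a}-{cls_b}",
            flagged=bool(flag and (ra in flag or rb in flag))))
    return InterfaceReport(chain_a=chain_a, chain_b=chain_b, cutoff=cutoff,
                           contacts=tuple(contacts))


def reactive_loop_candidates(seq: ProteinSequence, ss: str | None = None,
                             framework: CysFramework | None = None
                             ) -> list[CandidateLoop]:
    """Candidate reactive-site loops: basic-residue-bearing loop segments.

    With a secondary-structure string (H/E/C per residue), candidate
    segments are contiguous coil stretches; without one, the segments
    between consecutive cysteines serve as a proxy for loops. Segments
    containing at least one Lys or Arg are returned, labelled A, B, ...
    by position.
    """
    n = len(seq)
    if ss is not None and len(ss) != n:
        raise ValidationError("ss: length must match the sequence")
    segments = []
    if ss is not None:
        ss = ss.upper()
        i = 0
        while i < n:
            if ss[i] in "C-L":
                j = i
                while j < n and ss[j] in "C-L":
                    j += 1
                segments.append((i + 1, j))
                i = j
            else:
                i += 1
    else:
        fw = framework or extract_framework(seq)
        cys = [0, *fw.positions, n + 1]
        for a, b in zip(cys, cys[1:]):
            if b - a > 1:
                segments.append((a + 1, b - 1))
    loops = []
    for start, end in segments:
        basics = {p: seq.residues[p - 1] for p in range(start, end + 1)
                  if seq.residues[p - 1] in "KR"}
        if basics:
            loops.append(CandidateLoop(label=chr(ord("A") + len(loops)),
                                       positions=tuple(range(start, end + 1)),
                                       basic_residues=basics))
    return loops
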