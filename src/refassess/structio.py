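"""PDB structure I/O, residue correspondence and submission validity.

Structures are held in a deliberately small in-memory representation: an
ordered list of residues, each carrying its heavy atoms.  Reading goes
through :mod:`gemmi`; writing emits minimal ``ATOM``/``TER``/``END`` records
(wwPDB v3.3 columns).  Hydrogens, HETATM records and waters are dropped on
input, and alternate locations are resolved to the highest-occupancy
conformer (first listed on ties).

Residue correspondence between a model and its target is established by
author numbering — chain id, residue number and insertion code — which is
the convention refinement submissions follow (they inherit the target
numbering), so no sequence alignment is needed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Literal

import gemmi
import numpy as np

MAINCHAIN_ATOMS = frozenset({"N", "CA", "C", "O"})

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: residue key: (chain id, author residue number, insertion code)
ResidueKey = tuple[str, int, str]

Source = Literal["native", "starting", "prediction"]


@dataclass
class AtomRecord:
    """One heavy atom: name, element, Cartesian coordinate in Å."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def is_mainchain(self) -> bool:
        return self.name in MAINCHAIN_ATOMS


@dataclass
class ResidueRecord:
    chain: str
    seqnum: int
    icode: str
    resname: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain, self.seqnum, self.icode)

    @property
    def is_standard(self) -> bool:
        return self.resname in STANDARD_AA

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    """An ordered list of residues with chain/residue/atom identity.

    Multi-chain files are concatenated in file order; refinement targets are
    single-domain so this loses nothing.
    """

    id: str
    residues: list[ResidueRecord]
    source: Source = "prediction"

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError(f"{self.id}: duplicate residue keys")

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, key: ResidueKey) -> ResidueRecord | None:
        return self._index().get(key)

    def _index(self) -> dict[ResidueKey, ResidueRecord]:
        idx = getattr(self, "_key_index", None)
        if idx is None or len(idx) != len(self.residues):
            idx = {r.key: r for r in self.residues}
            self._key_index = idx
        return idx

    def heavy_atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def ca_coords(self, keys: Iterable[ResidueKey] | None = None) -> np.ndarray:
        """Cα coordinates, in residue order or in the order of ``keys``."""
        if keys is None:
            residues = self.residues
        else:
            residues = [self._index()[k] for k in keys]
        coords = []
        for r in residues:
            ca = r.atom("CA")
            if ca is None:
                raise ValueError(f"residue {r.key} has no CA atom")
            coords.append(ca.coord)
        return np.asarray(coords, dtype=float)


@dataclass
class ResidueCorrespondence:
    """Sequence-dependent pairing of model and target residues.

    ``pairs`` holds ``(model_key, target_key)`` in target order; with shared
    author numbering the two keys of a pair are identical.  A residue-name
    mismatch at a paired position is recorded in ``mismatched`` but does not
    break the pair.
    """

    pairs: list[tuple[ResidueKey, ResidueKey]]
    mismatched: list[ResidueKey] = field(default_factory=list)

    @property
    def n_common(self) -> int:
        return len(self.pairs)

    @property
    def model_keys(self) -> list[ResidueKey]:
        return [p[0] for p in self.pairs]

    @property
    def target_keys(self) -> list[ResidueKey]:
        return [p[1] for p in self.pairs]

    def restricted(self, exclude: set[ResidueKey]) -> "ResidueCorrespondence":
        """Correspondence with target-keyed residues in ``exclude`` removed."""
        kept = [(m, t) for m, t in self.pairs if t not in exclude]
        return ResidueCorrespondence(
            pairs=kept, mismatched=[k for k in self.mismatched if k not in exclude]
        )


class PDBParseError(ValueError):
    pass


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    # group by atom name; keep highest occupancy, first listed on ties
    by_name: dict[str, AtomRecord] = {}
    order: list[str] = []
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None:
            by_name[a.name] = a
            order.append(a.name)
        elif a.occupancy > prev.occupancy:
            by_name[a.name] = a
    return [by_name[n] for n in order]


def read_pdb(path: str | os.PathLike, source: Source = "prediction", id: str | None = None) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    HETATM records, waters and hydrogens are dropped; alternate locations are
    resolved to the highest-occupancy atom.  Raises :class:`PDBParseError` if
    the file contains no usable ATOM record.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise PDBParseError(f"{path}: no such file")
    try:
        st = gemmi.read_pdb(path)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc

    residues: list[ResidueRecord] = []
    if len(st) > 0:
        for chain in st[0]:
            for res in chain:
                if res.het_flag != "A":  # HETATM (incl. waters) dropped
                    continue
                atoms = []
                for at in res:
                    if at.is_hydrogen():
                        continue
                    atoms.append(
                        AtomRecord(
                            name=at.name,
                            element=at.element.name,
                            coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            occupancy=at.occ,
                            altloc=at.altloc if at.altloc else "",
                        )
                    )
                if not atoms:
                    continue
                residues.append(
                    ResidueRecord(
                        chain=chain.name,
                        seqnum=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        resname=res.name,
                        atoms=_resolve_altlocs(atoms),
                    )
                )
    if not residues:
        raise PDBParseError(f"{path}: no ATOM records (first line: {_first_line(path)!r})")
    return Structure(id=id or os.path.splitext(os.path.basename(path))[0], residues=residues, source=source)


def _first_line(path: str) -> str:
    try:
        with open(path, errors="replace") as fh:
            return fh.readline().rstrip("\n")
    except OSError:
        return ""


def write_pdb(structure: Structure, path: str | os.PathLike) -> None:
    """Write minimal ATOM/TER/END records (wwPDB v3.3 columns)."""
    serial = 0
    lines: list[str] = []
    prev_chain: str | None = None
    for res in structure.residues:
        if prev_chain is not None and res.chain != prev_chain:
            lines.append("TER")
        prev_chain = res.chain
        for a in res.atoms:
            serial += 1
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            x, y, z = a.coord
            lines.append(
                f"ATOM  {serial:5d} {name}{a.altloc or ' '}{res.resname:>3s} "
                f"{res.chain[:1]}{res.seqnum:4d}{res.icode or ' '}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}"
            )
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def map_common_residues(model: Structure, target: Structure) -> ResidueCorrespondence:
    """Pair residues present in both structures by (chain, seqnum, icode).

    Order follows the target.  Residues missing on either side are excluded;
    a residue-name mismatch at a shared key is flagged, not fatal.  Raises
    ``ValueError`` if the structures share no residue.
    """
    if len(model) == 0 or len(target) == 0:
        raise ValueError("empty structure")
    model_idx = {r.key: r for r in model.residues}
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    mismatched: list[ResidueKey] = []
    for tres in target.residues:
        mres = model_idx.get(tres.key)
        if mres is None:
            continue
        pairs.append((mres.key, tres.key))
        if mres.resname != tres.resname:
            mismatched.append(tres.key)
    if not pairs:
        raise ValueError(
            f"no common residues between {model.id} and {target.id}"
        )
    return ResidueCorrespondence(pairs=pairs, mismatched=mismatched)


@dataclass
class SubmissionVerdict:
    accepted: bool
    reason: str
    model_atoms: int
    starting_atoms: int

    def __bool__(self) -> bool:
        return self.accepted


def validate_submission(model: Structure, starting: Structure) -> SubmissionVerdict:
    """Accept a submission only if it carries at least as many heavy atoms as
    the starting model it was meant to refine.

    A lower count means missing residues or a non-all-atom model, which
    the assessment discards outright.
    """
    m, s = model.heavy_atom_count(), starting.heavy_atom_count()
    if m < s:
        return SubmissionVerdict(
            False,
            f"fewer atoms than starting model ({m} < {s})",
            m,
            s,
        )
    return SubmissionVerdict(True, "ok", m, s)
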