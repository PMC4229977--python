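"""Parsed protein structures and residue/atom selection helpers.

A :class:`Structure` is a flat, ordered list of amino-acid residues from the
first model of a PDB file: heavy atoms only, one conformer per atom, waters
and ligands dropped (selenomethionine is kept and normalized to MET).  This
is the minimal coordinate model a distance-constraint site search needs;
chains, residues and atoms keep their author identifiers so that motif
definitions written in author numbering resolve directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "atom_subset",
    "one_letter",
    "STANDARD_RESIDUES",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: IUPAC three- to one-letter codes for the 20 standard amino acids,
#: plus selenomethionine which is normalized to methionine on input.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

STANDARD_RESIDUES = frozenset(k for k in THREE_TO_ONE if k != "MSE")


class PDBParseError(ValueError):
    """Raised when PDB-format text cannot be parsed into a Structure."""


@dataclass(frozen=True)
class Atom:
    """A heavy atom: PDB atom name, element symbol, Å coordinates."""

    name: str
    element: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise ValueError("atom name must be non-empty")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass
class Residue:
    """An amino-acid residue identified by author (chain, number, icode)."""

    res_name: str
    seq_id: int
    chain: str
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        """Unique identity of the residue within its structure."""
        return (self.chain, self.seq_id, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def centroid(self) -> np.ndarray:
        return np.mean([a.xyz for a in self.atoms], axis=0)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Residue({self.res_name} {self.chain}:{self.seq_id}{self.icode})"


@dataclass
class Structure:
    """One model's amino-acid residues, in file order."""

    struct_id: str
    residues: list[Residue] = field(default_factory=list)
    model_index: int = 1

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def find_residue(self, chain: str, seq_id: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.key == (chain, seq_id, icode):
                return r
        return None


def _precheck_atom_lines(text: str, name: str) -> None:
    # gemmi zero-fills unparseable numeric fields instead of failing, so
    # malformed coordinates are caught here with their line number.
    n_atoms = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        n_atoms += 1
        if len(line) < 54:
            raise PDBParseError(f"{name}: line {lineno}: truncated coordinate record")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fieldtxt = line[lo:hi]
            try:
                float(fieldtxt)
            except ValueError:
                raise PDBParseError(
                    f"{name}: line {lineno}: malformed {what} coordinate {fieldtxt!r}"
                ) from None
    if n_atoms == 0:
        raise PDBParseError(f"{name}: no ATOM/HETATM records found")


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc."""
    out: dict[str, Atom] = {}
    for a in atoms:
        prev = out.get(a.name)
        if prev is None:
            out[a.name] = a
        elif (a.occupancy, _neg_ord(a.altloc)) > (prev.occupancy, _neg_ord(prev.altloc)):
            out[a.name] = a
    return list(out.values())


def _neg_ord(altloc: str) -> int:
    # higher key wins; earlier altloc character should win ties
    return -ord(altloc) if altloc else 0


def read_pdb(source: str | Path) -> Structure:
    """Parse PDB-format text (path or literal text) into a Structure.

    Keeps the first model only; drops hydrogens, waters and non-amino-acid
    HETATM residues (MSE is kept as MET); resolves alternate locations to
    the highest-occupancy conformer.

    Raises
    ------
    PDBParseError
        If the input has no ATOM/HETATM records or a malformed
        coordinate field (reported with its line number).
    """
    path: Path | None = None
    if isinstance(source, Path):
        path = source
    elif isinstance(source, str) and "\n" not in source and Path(source).exists():
        path = Path(source)

    if path is not None:
        text = path.read_text()
        name = path.name
        struct_id = path.stem.split(".")[0]
    else:
        text = str(source)
        name = "<text>"
        struct_id = "query"

    _precheck_atom_lines(text, name)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{name}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{name}: no coordinate models found")

    model = st[0]
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            res_name = res.name.upper()
            if res_name == "HOH" or res_name not in THREE_TO_ONE:
                continue
            atoms = []
            for a in res:
                if a.element.is_hydrogen:
                    continue
                atoms.append(
                    Atom(
                        name=a.name.strip(),
                        element=a.element.name,
                        coords=(a.pos.x, a.pos.y, a.pos.z),
                        occupancy=a.occ,
                        altloc=a.altloc if a.altloc != "\0" else "",
                    )
                )
            atoms = _resolve_altlocs(atoms)
            if not atoms:
                continue
            norm_name = "MET" if res_name == "MSE" else res_name
            icode = res.seqid.icode.strip()
            residues.append(
                Residue(res_name=norm_name, seq_id=res.seqid.num,
                        chain=chain.name, icode=icode, atoms=atoms)
            )
    if not residues:
        raise PDBParseError(f"{name}: no amino-acid residues after filtering")
    return Structure(struct_id=struct_id, residues=residues, model_index=1)


def write_pdb(structure: Structure) -> str:
    """Serialize a Structure as minimal fixed-width PDB text."""
    lines = []
    serial = 0
    for res in structure.residues:
        for a in res.atoms:
            serial += 1
            name = a.name
            # column convention: 1-3 char names start in column 14
            padded = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {padded}{a.altloc or ' '}"
                f"{res.res_name:>3s} {res.chain[:1]}{res.seq_id:4d}{res.icode or ' '}   "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


_SUBSET_MODES = ("sidechain", "backbone", "all", "ca", "ca_cb")


def atom_subset(residue: Residue, mode: str) -> list[Atom]:
    """Select atoms of a residue by mode, preserving file order.

    ``sidechain`` is everything outside the N/CA/C/O backbone (so CB is a
    sidechain atom); ``ca_cb`` degrades to CA alone for glycine.
    """
    if mode not in _SUBSET_MODES:
        raise ValueError(f"unknown atom-subset mode {mode!r}; expected one of {_SUBSET_MODES}")
    if mode == "all":
        return list(residue.atoms)
    if mode == "backbone":
        return [a for a in residue.atoms if a.name in BACKBONE_ATOMS]
    if mode == "sidechain":
        return [a for a in residue.atoms if a.name not in BACKBONE_ATOMS]
    if mode == "ca":
        return [a for a in residue.atoms if a.name == "CA"]
    return [a for a in residue.atoms if a.name in ("CA", "CB")]


def one_letter(res_name: str) -> str:
    """Map a three-letter residue code to its one-letter code (MSE → M)."""
    try:
        return THREE_TO_ONE[res_name.upper()]
    except KeyError:
        raise KeyError(f"unknown residue code {res_name!r}") from None


def residue_string(res_names: Iterable[str]) -> str:
    """One-letter string for a sequence of three-letter codes."""
    return "".join(one_letter(n) for n in res_names)
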