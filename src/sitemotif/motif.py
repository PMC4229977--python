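"""Motif-template data model and its on-disk serialization.

A motif template is an orientation-independent description of an active
site: an ordered set of residue *slots* (residue type, source identity,
atom names and template coordinates) plus pairwise inter-atom distance
constraints and a tolerance in Å.  Motifs are stored as declarative YAML
documents — data, not code — one motif per file; the template coordinates
are included so that superposition RMSD can be computed without access to
the source structure.

Schema (YAML mapping)::

    motif_id: str          # unique identifier
    source_pdb: str        # 4-character origin structure id
    ec_number: str         # dotted EC classification, 1-4 levels
    set_label: P|U|J|N     # template set (developer / user / ...)
    tolerance: float       # Å, default 2.00
    slots:                 # >=3 entries, ordered
      - res_name: SER
        seq_id: 195
        chain: A
        atoms: [CB, OG]
        coords: [[x, y, z], ...]   # one per atom, Å
    constraints:           # every slot pair covered
      - [slot_i, atom_i, slot_j, atom_j, distance]
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .structure import STANDARD_RESIDUES

__all__ = [
    "MotifSlot",
    "DistanceConstraint",
    "Motif",
    "MotifError",
    "DEFAULT_TOLERANCE",
    "serialize_motif",
    "parse_motif",
    "validate_motif",
    "load_motif",
    "save_motif",
]

#: Default matching tolerance added to template distances, Å.
DEFAULT_TOLERANCE = 2.00

SET_LABELS = ("P", "U", "J", "N")


class MotifError(ValueError):
    """Raised for unparseable or invalid motif files."""


@dataclass(frozen=True)
class MotifSlot:
    index: int
    res_name: str
    source_seq_id: int
    source_chain: str
    atom_names: tuple[str, ...]
    template_coords: tuple[tuple[float, float, float], ...]

    def coords_array(self) -> np.ndarray:
        return np.asarray(self.template_coords, dtype=float)

    def coord_of(self, atom_name: str) -> np.ndarray:
        return self.coords_array()[self.atom_names.index(atom_name)]


@dataclass(frozen=True)
class DistanceConstraint:
    slot_i: int
    atom_i: str
    slot_j: int
    atom_j: str
    distance: float


@dataclass
class Motif:
    motif_id: str
    source_pdb: str
    ec_number: str
    set_label: str
    slots: list[MotifSlot]
    constraints: list[DistanceConstraint]
    tolerance: float = DEFAULT_TOLERANCE

    def residue_string(self) -> str:
        from .structure import one_letter

        return "".join(one_letter(s.res_name) for s in self.slots)

    def constraints_between(self, i: int, j: int) -> list[DistanceConstraint]:
        lo, hi = min(i, j), max(i, j)
        return [c for c in self.constraints if (c.slot_i, c.slot_j) == (lo, hi)]


def validate_motif(motif: Motif) -> list[str]:
    """Check all motif invariants; returns violations (empty list = valid)."""
    v: list[str] = []
    if not motif.motif_id:
        v.append("motif_id is empty")
    if motif.set_label not in SET_LABELS:
        v.append(f"set_label {motif.set_label!r} not one of {SET_LABELS}")
    if motif.tolerance < 0:
        v.append(f"tolerance {motif.tolerance} is negative")
    if len(motif.slots) < 3:
        v.append(f"motif has {len(motif.slots)} slots; at least 3 residues required")
    for pos, slot in enumerate(motif.slots):
        if slot.index != pos:
            v.append(f"slot at position {pos} has index {slot.index}")
        if slot.res_name not in STANDARD_RESIDUES:
            v.append(f"slot {pos}: res_name {slot.res_name!r} is not a standard amino acid")
        if not slot.atom_names:
            v.append(f"slot {pos}: empty atom list")
        if len(slot.atom_names) != len(slot.template_coords):
            v.append(f"slot {pos}: {len(slot.atom_names)} atom names but "
                     f"{len(slot.template_coords)} coordinate triples")
        if len(set(slot.atom_names)) != len(slot.atom_names):
            v.append(f"slot {pos}: duplicate atom names")
    n = len(motif.slots)
    covered = set()
    for k, c in enumerate(motif.constraints):
        if not (0 <= c.slot_i < n and 0 <= c.slot_j < n):
            v.append(f"constraint {k}: slot index out of range")
            continue
        if c.slot_i >= c.slot_j:
            v.append(f"constraint {k}: slot_i must be < slot_j")
        if c.distance <= 0:
            v.append(f"constraint {k}: non-positive distance {c.distance}")
        for slot_idx, atom in ((c.slot_i, c.atom_i), (c.slot_j, c.atom_j)):
            if atom not in motif.slots[slot_idx].atom_names:
                v.append(f"constraint {k}: atom {atom!r} not in slot {slot_idx} atom list")
        covered.add((c.slot_i, c.slot_j))
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) not in covered:
                v.append(f"slot pair ({i}, {j}) has no distance constraint")
    return v


def serialize_motif(motif: Motif) -> str:
    """Render a valid motif as deterministic YAML text."""
    violations = validate_motif(motif)
    if violations:
        raise MotifError("invalid motif:\n  " + "\n  ".join(violations))
    doc = {
        "motif_id": motif.motif_id,
        "source_pdb": motif.source_pdb,
        "ec_number": motif.ec_number,
        "set_label": motif.set_label,
        "tolerance": float(motif.tolerance),
        "slots": [
            {
                "res_name": s.res_name,
                "seq_id": s.source_seq_id,
                "chain": s.source_chain,
                "atoms": list(s.atom_names),
                "coords": [[float(x) for x in c] for c in s.template_coords],
            }
            for s in motif.slots
        ],
        "constraints": [
            [c.slot_i, c.atom_i, c.slot_j, c.atom_j, float(c.distance)]
            for c in motif.constraints
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=None)


def parse_motif(text: str) -> Motif:
    """Parse YAML motif text, applying the documented tolerance default."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise MotifError(f"motif file is not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise MotifError("motif file must contain a YAML mapping")

    def need(key: str):
        if key not in doc:
            raise MotifError(f"missing required field {key!r}")
        return doc[key]

    slots = []
    for pos, s in enumerate(need("slots") or []):
        try:
            slots.append(
                MotifSlot(
                    index=pos,
                    res_name=str(s["res_name"]).upper(),
                    source_seq_id=int(s["seq_id"]),
                    source_chain=str(s["chain"]),
                    atom_names=tuple(str(a) for a in s["atoms"]),
                    template_coords=tuple(tuple(float(x) for x in c) for c in s["coords"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise MotifError(f"slots[{pos}]: {exc!r}") from exc
    constraints = []
    for k, c in enumerate(need("constraints") or []):
        try:
            si, ai, sj, aj, d = c
            constraints.append(DistanceConstraint(int(si), str(ai), int(sj), str(aj), float(d)))
        except (TypeError, ValueError) as exc:
            raise MotifError(f"constraints[{k}]: {exc!r}") from exc
    motif = Motif(
        motif_id=str(need("motif_id")),
        source_pdb=str(doc.get("source_pdb", "")),
        ec_number=str(doc.get("ec_number", "")),
        set_label=str(doc.get("set_label", "U")),
        slots=slots,
        constraints=constraints,
        tolerance=float(doc.get("tolerance", DEFAULT_TOLERANCE)),
    )
    violations = validate_motif(motif)
    if violations:
        raise MotifError("invalid motif:\n  " + "\n  ".join(violations))
    return motif


def save_motif(motif: Motif, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(serialize_motif(motif))
    return path


def load_motif(path: str | Path) -> Motif:
    return parse_motif(Path(path).read_text())
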