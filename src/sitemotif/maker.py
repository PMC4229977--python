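"""Build motif templates from a structure plus catalytic-residue specs.

The template records, for every pair of catalytic residues, the distance
between every pair of their listed heavy atoms.  Distances are Euclidean
and orientation-independent, so the resulting motif matches the same site
in any rigid placement of the structure.  Slot atom lists default to the
sidechain (CB and beyond); backbone N/CA/C/O can be added per residue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motif import DistanceConstraint, Motif, MotifError, MotifSlot, DEFAULT_TOLERANCE
from .structure import STANDARD_RESIDUES, Structure, atom_subset

__all__ = ["ResidueSpec", "build_motif", "self_test", "SelfTestReport"]


@dataclass(frozen=True)
class ResidueSpec:
    """One catalytic residue: name, author number, chain, backbone flag."""

    res_name: str
    seq_id: int
    chain: str
    include_backbone: bool = False
    icode: str = ""

    @classmethod
    def parse(cls, text: str) -> "ResidueSpec":
        """Parse ``NAME:SEQID:CHAIN[:backbone]``, e.g. ``SER:195:A``."""
        parts = text.split(":")
        if len(parts) not in (3, 4):
            raise ValueError(f"residue spec {text!r} is not NAME:SEQID:CHAIN[:backbone]")
        backbone = len(parts) == 4 and parts[3].lower() in ("backbone", "bb", "1", "true")
        return cls(res_name=parts[0].upper(), seq_id=int(parts[1]),
                   chain=parts[2], include_backbone=backbone)


def build_motif(
    structure: Structure,
    specs: list[ResidueSpec],
    *,
    tolerance: float = DEFAULT_TOLERANCE,
    ec_number: str = "",
    motif_id: str | None = None,
    set_label: str = "U",
) -> Motif:
    """Create a Motif from catalytic-residue specs against a structure.

    Each spec becomes one slot in spec order; constraints record the
    template distance for every atom pair across every slot pair.

    Raises
    ------
    MotifError
        If fewer than three specs are given, a spec does not resolve to a
        residue in the structure, or the residue found has a different
        residue type than the spec claims.
    """
    if len(specs) < 3:
        raise MotifError(f"an active site needs at least 3 residues, got {len(specs)}")
    slots: list[MotifSlot] = []
    seen: set[tuple[str, int, str]] = set()
    for idx, spec in enumerate(specs):
        if spec.res_name not in STANDARD_RESIDUES:
            raise MotifError(f"spec {idx}: {spec.res_name!r} is not a standard amino acid")
        res = structure.find_residue(spec.chain, spec.seq_id, spec.icode)
        if res is None:
            raise MotifError(
                f"spec {idx}: no residue ({spec.chain}, {spec.seq_id}{spec.icode}) "
                f"in structure {structure.struct_id!r}"
            )
        if res.res_name != spec.res_name:
            raise MotifError(
                f"spec {idx}: residue {spec.chain}:{spec.seq_id} is {res.res_name}, "
                f"spec says {spec.res_name}"
            )
        if res.key in seen:
            raise MotifError(f"spec {idx}: residue {res.key} listed twice")
        seen.add(res.key)
        atoms = atom_subset(res, "sidechain")
        if spec.include_backbone:
            atoms = atom_subset(res, "backbone") + atoms
        if not atoms:
            raise MotifError(f"spec {idx}: residue {res.key} has no usable atoms")
        slots.append(
            MotifSlot(
                index=idx,
                res_name=spec.res_name,
                source_seq_id=spec.seq_id,
                source_chain=spec.chain,
                atom_names=tuple(a.name for a in atoms),
                template_coords=tuple(a.coords for a in atoms),
            )
        )

    constraints: list[DistanceConstraint] = []
    for i in range(len(slots)):
        ci = slots[i].coords_array()
        for j in range(i + 1, len(slots)):
            cj = slots[j].coords_array()
            d = np.linalg.norm(ci[:, None, :] - cj[None, :, :], axis=-1)
            for ai, name_i in enumerate(slots[i].atom_names):
                for aj, name_j in enumerate(slots[j].atom_names):
                    constraints.append(
                        DistanceConstraint(i, name_i, j, name_j, float(d[ai, aj]))
                    )

    return Motif(
        motif_id=motif_id or f"{structure.struct_id}_{specs[0].seq_id}",
        source_pdb=structure.struct_id[:4],
        ec_number=ec_number,
        set_label=set_label,
        slots=slots,
        constraints=constraints,
        tolerance=float(tolerance),
    )


@dataclass(frozen=True)
class SelfTestReport:
    found: bool
    levenshtein: int | None
    rmsd_all: float | None

    @property
    def passed(self) -> bool:
        return (
            self.found
            and self.levenshtein == 0
            and self.rmsd_all is not None
            and self.rmsd_all <= 1e-6
        )


def self_test(motif: Motif, source: Structure) -> SelfTestReport:
    """Search the motif's own source structure for the motif.

    A freshly built motif must find the exact residues it was built from,
    with Levenshtein distance 0 and an all-atom RMSD of (numerically) zero
    — including when the source has been rigidly moved, since both the
    constraints and the superposition RMSD are rigid-motion invariant.
    A failing report is returned, never raised.
    """
    from .finder import SearchOptions, find_matches
    from .scoring import score_match

    original = {(s.source_chain, s.source_seq_id) for s in motif.slots}
    matches = find_matches(motif, source, SearchOptions(precision=1.0))
    for m in matches:
        assigned = {(r.chain, r.seq_id) for r in m.assigned_residues() if r is not None}
        if assigned == original:
            scored = score_match(motif, m, source)
            return SelfTestReport(found=True, levenshtein=scored.levenshtein,
                                  rmsd_all=scored.rmsd_all)
    return SelfTestReport(found=False, levenshtein=None, rmsd_all=None)
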