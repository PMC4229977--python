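"""Synthetic PDB-format structures with planted active sites and decoys.

The generator emulates the one thing a distance-constraint site search
actually reads: heavy-atom inter-residue geometry.  Residues are built
from idealized internal coordinates (standard bond lengths and angles,
fixed rotamers) and assembled into

* *planted sites* — e.g. a Ser–His–Asp catalytic triad with
  hydrogen-bond-range heavy-atom contacts (Oγ···Nε2 ≈ 3.0 Å,
  Nδ1···Oδ1 ≈ 2.8 Å) placed under a seeded random rigid motion, optionally
  perturbed by i.i.d. Gaussian coordinate noise; and
* *decoy residues* — idealized single residues scattered in a box at
  roughly protein-interior packing density, kept apart by a minimum
  centroid separation.

Every structure ships with a ground-truth manifest: the planted residue
identities and the ideal (pre-noise) inter-atom distances of each site,
so tests never need an external structure.  No attempt is made at
chemically plausible chain connectivity, sterics, or torsional statistics
— decoys are independent residues, which is exactly what a pairwise
distance filter sees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure import Atom, Residue, Structure, write_pdb

__all__ = [
    "FixtureSpec",
    "SynthResult",
    "synth_structure",
    "perturb_structure",
    "rigid_transform",
    "random_rigid_transform",
    "residue_template",
    "SITE_TEMPLATES",
    "DEFAULT_DECOY_TYPES",
]

# ---------------------------------------------------------------------------
# idealized residue geometry (NeRF internal-coordinate construction)

_ELEMENT = {"N": "N", "O": "O", "S": "S"}


def _element_of(atom_name: str) -> str:
    return _ELEMENT.get(atom_name[0], "C")


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Position atom d bonded to c with angle(d,c,b) and dihedral(d,c,b,a)."""
    ang = math.radians(angle)
    dih = math.radians(dihedral)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(dih),
        bond * math.sin(ang) * math.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# Side-chain z-matrix rows: atom, (ref_a, ref_b, ref_c), bond Å, angle °, dihedral °.
# Bond lengths and angles follow standard amino-acid stereochemistry;
# rotamers are fixed (one conformer per type).  Ring closure for HIS/PHE/TYR
# is by construction only — self-consistent, not refined.
_SIDECHAINS: dict[str, list[tuple[str, tuple[str, str, str], float, float, float]]] = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.417, 110.8, -65.0)],
    "CYS": [("SG", ("N", "CA", "CB"), 1.808, 114.4, -65.0)],
    "THR": [("OG1", ("N", "CA", "CB"), 1.433, 109.6, -60.0),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, 60.0)],
    "VAL": [("CG1", ("N", "CA", "CB"), 1.527, 110.5, 175.0),
            ("CG2", ("N", "CA", "CB"), 1.527, 110.5, -65.0)],
    "LEU": [("CG", ("N", "CA", "CB"), 1.530, 116.3, -65.0),
            ("CD1", ("CA", "CB", "CG"), 1.524, 110.7, 175.0),
            ("CD2", ("CA", "CB", "CG"), 1.524, 110.7, -65.0)],
    "ILE": [("CG1", ("N", "CA", "CB"), 1.530, 110.4, -60.0),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, 175.0),
            ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, 170.0)],
    "ASP": [("CG", ("N", "CA", "CB"), 1.516, 112.6, -65.0),
            ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, -20.0),
            ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, 160.0)],
    "GLU": [("CG", ("N", "CA", "CB"), 1.530, 114.1, -65.0),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
            ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, -20.0),
            ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, 160.0)],
    "ASN": [("CG", ("N", "CA", "CB"), 1.516, 112.6, -65.0),
            ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, -30.0),
            ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, 150.0)],
    "GLN": [("CG", ("N", "CA", "CB"), 1.530, 114.1, -65.0),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
            ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, -30.0),
            ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, 150.0)],
    "HIS": [("CG", ("N", "CA", "CB"), 1.500, 113.8, -65.0),
            ("ND1", ("CA", "CB", "CG"), 1.378, 122.7, -75.0),
            ("CD2", ("CA", "CB", "CG"), 1.354, 131.1, 105.0),
            ("CE1", ("CB", "CG", "ND1"), 1.320, 109.0, 180.0),
            ("NE2", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0)],
    "PHE": [("CG", ("N", "CA", "CB"), 1.500, 113.8, -65.0),
            ("CD1", ("CA", "CB", "CG"), 1.390, 120.7, 50.0),
            ("CD2", ("CA", "CB", "CG"), 1.390, 120.7, -130.0),
            ("CE1", ("CB", "CG", "CD1"), 1.390, 120.0, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.390, 120.0, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.390, 120.0, 0.0)],
    "TYR": [("CG", ("N", "CA", "CB"), 1.500, 113.8, -65.0),
            ("CD1", ("CA", "CB", "CG"), 1.390, 120.7, 50.0),
            ("CD2", ("CA", "CB", "CG"), 1.390, 120.7, -130.0),
            ("CE1", ("CB", "CG", "CD1"), 1.390, 120.0, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.390, 120.0, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.390, 120.0, 0.0),
            ("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0)],
    "LYS": [("CG", ("N", "CA", "CB"), 1.520, 114.0, 180.0),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.0, 180.0),
            ("CE", ("CB", "CG", "CD"), 1.520, 111.0, 180.0),
            ("NZ", ("CG", "CD", "CE"), 1.490, 112.0, 180.0)],
    "ARG": [("CG", ("N", "CA", "CB"), 1.520, 114.0, 180.0),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.0, 180.0),
            ("NE", ("CB", "CG", "CD"), 1.460, 112.0, 180.0),
            ("CZ", ("CG", "CD", "NE"), 1.330, 124.0, 180.0),
            ("NH1", ("CD", "NE", "CZ"), 1.330, 120.0, 0.0),
            ("NH2", ("CD", "NE", "CZ"), 1.330, 120.0, 180.0)],
    "MET": [("CG", ("N", "CA", "CB"), 1.520, 114.0, 180.0),
            ("SD", ("CA", "CB", "CG"), 1.803, 112.7, 180.0),
            ("CE", ("CB", "CG", "SD"), 1.791, 100.9, 180.0)],
}

#: Residue types the generator can build.
SUPPORTED_TYPES = tuple(sorted(_SIDECHAINS))

#: Default decoy composition: common types that do not overlap the built-in
#: planted-site residue types (SER/CYS/HIS/ASP), so a default fixture is
#: clean by construction.
DEFAULT_DECOY_TYPES = ("ALA", "GLY", "VAL", "LEU", "PHE", "LYS", "ASN", "MET")


def residue_template(res_name: str) -> dict[str, np.ndarray]:
    """Idealized heavy-atom coordinates for one residue type, local frame."""
    res_name = res_name.upper()
    if res_name not in _SIDECHAINS:
        raise ValueError(
            f"no idealized template for {res_name!r}; supported: {SUPPORTED_TYPES}"
        )
    coords: dict[str, np.ndarray] = {
        "N": np.array([0.0, 0.0, 0.0]),
        "CA": np.array([1.458, 0.0, 0.0]),
    }
    ang = math.radians(180.0 - 111.0)
    coords["C"] = coords["CA"] + 1.525 * np.array([math.cos(ang), math.sin(ang), 0.0])
    coords["O"] = _place(coords["N"], coords["CA"], coords["C"], 1.231, 120.5, -45.0)
    if res_name != "GLY":
        coords["CB"] = _place(coords["C"], coords["N"], coords["CA"], 1.530, 110.5, -122.0)
    for name, (ra, rb, rc), bond, angle, dihedral in _SIDECHAINS[res_name]:
        coords[name] = _place(coords[ra], coords[rb], coords[rc], bond, angle, dihedral)
    return coords


# ---------------------------------------------------------------------------
# planted-site assembly

def _rotation_between(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Proper rotation sending unit vector v to unit vector w (Rodrigues)."""
    v = v / np.linalg.norm(v)
    w = w / np.linalg.norm(w)
    axis = np.cross(v, w)
    s = np.linalg.norm(axis)
    c = float(np.dot(v, w))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any perpendicular axis
        perp = np.cross(v, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(v, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    axis = axis / s
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def _centroid(coords: dict[str, np.ndarray]) -> np.ndarray:
    return np.mean(list(coords.values()), axis=0)


def _attach(template: dict[str, np.ndarray], anchor_atom: str,
            target: np.ndarray, outward: np.ndarray) -> dict[str, np.ndarray]:
    """Rigidly place a residue so anchor_atom sits at target with the rest
    of the residue extending along the outward direction."""
    cen = _centroid(template)
    v = cen - template[anchor_atom]
    rot = _rotation_between(v, outward)
    return {
        name: rot @ (xyz - template[anchor_atom]) + target
        for name, xyz in template.items()
    }


def _build_site(res_names: tuple[str, str, str],
                contacts: tuple[tuple[str, str, float], tuple[str, str, float]],
                ) -> list[tuple[str, dict[str, np.ndarray]]]:
    """Assemble a three-residue site from pairwise anchor-atom contacts.

    ``contacts[0] = (atom_of_res0, atom_of_res1, distance)`` and
    ``contacts[1] = (atom_of_res1, atom_of_res2, distance)``.
    """
    r0 = residue_template(res_names[0])
    a01, a10, d01 = contacts[0]
    u = r0[a01] - _centroid(r0)
    u = u / np.linalg.norm(u)
    r1 = _attach(residue_template(res_names[1]), a10, r0[a01] + d01 * u, u)
    a12, a21, d12 = contacts[1]
    w = r1[a12] - _centroid(r1)
    w = w / np.linalg.norm(w)
    r2 = _attach(residue_template(res_names[2]), a21, r1[a12] + d12 * w, w)
    return [(res_names[0], r0), (res_names[1], r1), (res_names[2], r2)]


#: Built-in planted-site geometries.  The classic serine-protease triad
#: (nucleophile–base–acid) and its cysteine-nucleophile variant.
SITE_TEMPLATES: dict[str, dict] = {
    "triad": {
        "residues": ("SER", "HIS", "ASP"),
        "contacts": (("OG", "NE2", 3.0), ("ND1", "OD1", 2.8)),
    },
    "thiol-triad": {
        "residues": ("CYS", "HIS", "ASP"),
        "contacts": (("SG", "NE2", 3.5), ("ND1", "OD1", 2.8)),
    },
}


def _site_coords(site_name: str) -> list[tuple[str, dict[str, np.ndarray]]]:
    try:
        tpl = SITE_TEMPLATES[site_name]
    except KeyError:
        raise ValueError(
            f"unknown site template {site_name!r}; available: {sorted(SITE_TEMPLATES)}"
        ) from None
    return _build_site(tpl["residues"], tpl["contacts"])


# ---------------------------------------------------------------------------
# structure synthesis

@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic structure.

    ``sites`` names the planted active-site geometries; ``n_decoys``
    idealized single residues (types drawn from ``decoy_types``) are packed
    around them in a box sized for ~0.008 residues/Å³.  ``noise_sd`` is the
    per-coordinate Gaussian noise applied to planted atoms.
    """

    sites: tuple[str, ...] = ("triad",)
    n_decoys: int = 40
    decoy_types: tuple[str, ...] = DEFAULT_DECOY_TYPES
    noise_sd: float = 0.0
    min_separation: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")


@dataclass
class SynthResult:
    pdb_text: str
    manifest: dict
    structure: Structure


class PlacementError(RuntimeError):
    """Decoy placement failed; the box is too crowded."""


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix, sign-fixed: Haar-uniform proper rotation
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _to_residue(res_name: str, seq_id: int, coords: dict[str, np.ndarray]) -> Residue:
    atoms = [
        Atom(name=name, element=_element_of(name), coords=tuple(float(x) for x in xyz))
        for name, xyz in coords.items()
    ]
    return Residue(res_name=res_name, seq_id=seq_id, chain="A", atoms=atoms)


def synth_structure(spec: FixtureSpec) -> SynthResult:
    """Generate PDB text plus a ground-truth manifest for a fixture spec.

    Deterministic for a fixed spec (the seed drives every random choice).
    The manifest records, per planted site, the residue identities
    (chain A, sequential author numbering starting at 1) and the ideal
    inter-atom side-chain distances before noise; those distances are what
    a motif built from the noise-free structure will contain.
    """
    rng = np.random.default_rng(spec.seed)
    n_planted = 3 * len(spec.sites)
    total = n_planted + spec.n_decoys
    box = (total / 0.008) ** (1.0 / 3.0) if total else 10.0

    site_centers = [
        box * np.full(3, (k + 1) / (len(spec.sites) + 1.0))
        for k in range(len(spec.sites))
    ]

    residues: list[Residue] = []
    manifest_res: list[dict] = []
    manifest_dist: list[list] = []
    centroids: list[np.ndarray] = []
    seq = 0
    for site_name, center in zip(spec.sites, site_centers):
        placed = _site_coords(site_name)
        # ideal distances between side-chain heavy atoms, recorded pre-noise
        site_seq_ids = list(range(seq + 1, seq + 1 + len(placed)))
        for (i, (name_i, ci)), (j, (name_j, cj)) in (
            ((a, placed[a]), (b, placed[b]))
            for a in range(len(placed)) for b in range(a + 1, len(placed))
        ):
            for an, axyz in ci.items():
                if an in ("N", "CA", "C", "O"):
                    continue
                for bn, bxyz in cj.items():
                    if bn in ("N", "CA", "C", "O"):
                        continue
                    manifest_dist.append([
                        site_seq_ids[i], an, site_seq_ids[j], bn,
                        float(np.linalg.norm(axyz - bxyz)),
                    ])
        rot = _random_rotation(rng)
        all_xyz = np.concatenate([list(c.values()) for _, c in placed])
        site_cen = all_xyz.mean(axis=0)
        for res_name, coords in placed:
            seq += 1
            moved = {
                n: rot @ (xyz - site_cen) + center for n, xyz in coords.items()
            }
            if spec.noise_sd > 0:
                moved = {
                    n: xyz + rng.normal(scale=spec.noise_sd, size=3)
                    for n, xyz in moved.items()
                }
            res = _to_residue(res_name, seq, moved)
            residues.append(res)
            centroids.append(res.centroid())
            manifest_res.append({
                "chain": "A", "seq_id": seq, "res_name": res_name, "site": site_name,
            })

    for _ in range(spec.n_decoys):
        res_name = str(rng.choice(spec.decoy_types))
        template = residue_template(res_name)
        cen = _centroid(template)
        local = {n: xyz - cen for n, xyz in template.items()}
        for _attempt in range(500):
            pos = rng.uniform(0.0, box, size=3)
            if all(np.linalg.norm(pos - c) >= spec.min_separation for c in centroids):
                break
        else:
            raise PlacementError(
                f"could not place decoy {len(residues) + 1} of {total} at "
                f"min_separation {spec.min_separation} Å in a {box:.1f} Å box; "
                "lower the density or separation"
            )
        rot = _random_rotation(rng)
        coords = {n: rot @ xyz + pos for n, xyz in local.items()}
        seq += 1
        res = _to_residue(res_name, seq, coords)
        residues.append(res)
        centroids.append(res.centroid())

    structure = Structure(struct_id=f"synth{spec.seed}", residues=residues)
    manifest = {
        "struct_id": structure.struct_id,
        "seed": spec.seed,
        "n_residues": len(residues),
        "sites": list(spec.sites),
        "noise_sd": spec.noise_sd,
        "planted_residues": manifest_res,
        "planted_distances": manifest_dist,
    }
    return SynthResult(pdb_text=write_pdb(structure), manifest=manifest,
                       structure=structure)


def rigid_transform(structure: Structure, rotation: np.ndarray,
                    translation: np.ndarray) -> Structure:
    """Copy of a structure under the rigid motion ``x -> R x + t``."""
    out: list[Residue] = []
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float)
    for res in structure.residues:
        atoms = [
            Atom(name=a.name, element=a.element,
                 coords=tuple(float(x) for x in rotation @ a.xyz + translation),
                 occupancy=a.occupancy, altloc=a.altloc)
            for a in res.atoms
        ]
        out.append(Residue(res_name=res.res_name, seq_id=res.seq_id,
                           chain=res.chain, icode=res.icode, atoms=atoms))
    return Structure(struct_id=structure.struct_id, residues=out,
                     model_index=structure.model_index)


def random_rigid_transform(structure: Structure, seed: int) -> Structure:
    """Copy of a structure under a seeded Haar-random rotation plus a
    uniform translation in [-50, 50] Å per axis."""
    rng = np.random.default_rng(seed)
    return rigid_transform(structure, _random_rotation(rng),
                           rng.uniform(-50.0, 50.0, size=3))


def perturb_structure(structure: Structure, noise_sd: float, seed: int) -> Structure:
    """Copy of a structure with i.i.d. Gaussian noise on every coordinate."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[Residue] = []
    for res in structure.residues:
        atoms = []
        for a in res.atoms:
            shift = rng.normal(scale=noise_sd, size=3) if noise_sd > 0 else np.zeros(3)
            atoms.append(Atom(name=a.name, element=a.element,
                              coords=tuple(float(x) for x in a.xyz + shift),
                              occupancy=a.occupancy, altloc=a.altloc))
        out.append(Residue(res_name=res.res_name, seq_id=res.seq_id,
                           chain=res.chain, icode=res.icode, atoms=atoms))
    return Structure(struct_id=structure.struct_id, residues=out,
                     model_index=structure.model_index)
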