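"""Match scoring: Levenshtein distance and superposition RMSD.

Levenshtein distance between the motif's residue string and the match's
residue string gives a coarse, composition-level score (0 = identical
residue types slot for slot; each substitution or missing residue adds 1).
RMSD after least-squares rigid superposition (Kabsch) gives the geometric
score, reported for three atom selections: all matched atoms, Cα only,
and Cα+Cβ.  Superposition precedes RMSD because the motif template and
the query live in unrelated coordinate frames.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .finder import Match
from .motif import Motif
from .structure import Structure, one_letter

__all__ = [
    "ScoredMatch",
    "levenshtein",
    "match_string",
    "superpose",
    "match_rmsd",
    "score_match",
    "rank_matches",
]

#: Chemically equivalent side-chain atom pairs whose PDB labels are
#: arbitrary; both labelings are tried and the lower RMSD kept.
SYMMETRIC_ATOM_SWAPS: dict[str, tuple[tuple[str, str], ...]] = {
    "ASP": (("OD1", "OD2"),),
    "GLU": (("OE1", "OE2"),),
    "PHE": (("CD1", "CD2"), ("CE1", "CE2")),
    "TYR": (("CD1", "CD2"), ("CE1", "CE2")),
    "ARG": (("NH1", "NH2"),),
}


@dataclass
class ScoredMatch:
    match: Match
    levenshtein: int
    rmsd_all: float
    rmsd_ca: float
    rmsd_ca_cb: float


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insert/delete/substitute) between strings.

    Classic dynamic programme over a single rolling row.
    """
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        curr = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            curr[j] = min(
                prev[j] + 1,          # delete from a
                curr[j - 1] + 1,      # insert into a
                prev[j - 1] + (ca != cb),  # substitute
            )
        prev = curr
    return prev[-1]


def match_string(motif: Motif, match: Match) -> str:
    """One-letter residue string of the match in motif slot order.

    UNMATCHED slots are simply omitted, so they surface as deletions in
    the edit distance against the motif's own residue string.
    """
    return "".join(
        one_letter(res.res_name) for res in match.assignment if res is not None
    )


def superpose(ref_coords, mov_coords) -> dict:
    """Optimal rigid superposition of mov onto ref (Kabsch, proper rotation).

    Returns ``{"rotation": R, "translation": t, "rmsd": float}`` with
    ``mov @ R.T + t`` least-squares aligned onto ref.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != 3 or mov.shape != ref.shape:
        raise ValueError(f"need matching (N, 3) arrays, got {ref.shape} and {mov.shape}")
    if ref.shape[0] == 0:
        raise ValueError("cannot superpose empty coordinate sets")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    h = (mov - mov_c).T @ (ref - ref_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ref_c - rot @ mov_c
    moved = mov @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((ref - moved) ** 2, axis=1))))
    return {"rotation": rot, "translation": trans, "rmsd": rmsd}


def _mode_pairs(motif: Motif, match: Match, query: Structure, mode: str):
    """Per-slot (template xyz, query xyz, swap-group) correspondences.

    ``all``: atoms sharing a name within each matched slot (substituted
    residues contribute shared names only); ``ca``: Cα per slot; ``ca_cb``:
    Cα and Cβ where present on both sides.  Returns per-slot lists so that
    symmetric-atom relabeling can be applied slot-locally.
    """
    per_slot = []
    for slot, res in zip(motif.slots, match.assignment):
        if res is None:
            continue
        if mode == "all":
            names = [n for n in slot.atom_names if res.atom(n) is not None]
        elif mode == "ca":
            names = [n for n in ("CA",) if n in slot.atom_names and res.atom(n)]
        elif mode == "ca_cb":
            names = [n for n in ("CA", "CB") if n in slot.atom_names and res.atom(n)]
        else:
            raise ValueError(f"unknown RMSD mode {mode!r}")
        if names:
            per_slot.append((slot, res, names))
    return per_slot


def _swap_variants(slot, res, names: list[str]):
    """Query-side name relabelings for chemically symmetric atoms."""
    swaps = [
        (a, b) for a, b in SYMMETRIC_ATOM_SWAPS.get(res.res_name, ())
        if a in names and b in names
    ]
    variants = []
    for flips in itertools.product((False, True), repeat=len(swaps)):
        relabel = {}
        for (a, b), flip in zip(swaps, flips):
            if flip:
                relabel[a], relabel[b] = b, a
        variants.append([relabel.get(n, n) for n in names])
    return variants


def match_rmsd(motif: Motif, match: Match, query: Structure, mode: str = "all") -> float:
    """RMSD between template and query atoms after optimal superposition.

    Symmetric side-chain labelings (ASP/GLU/PHE/TYR/ARG) are resolved by
    trying every relabeling combination and keeping the lowest RMSD.
    Returns NaN when the mode yields no atom correspondence (e.g. Cα mode
    for a motif that stored no backbone atoms).
    """
    per_slot = _mode_pairs(motif, match, query, mode)
    if not per_slot:
        return float("nan")
    slot_variants = []
    for slot, res, names in per_slot:
        if mode == "all":
            slot_variants.append([(slot, res, names, qnames)
                                  for qnames in _swap_variants(slot, res, names)])
        else:
            slot_variants.append([(slot, res, names, names)])
    best = math.inf
    for combo in itertools.product(*slot_variants):
        ref, mov = [], []
        for slot, res, names, qnames in combo:
            for tname, qname in zip(names, qnames):
                ref.append(res.atom(qname).xyz)
                mov.append(slot.coord_of(tname))
        rmsd = superpose(ref, mov)["rmsd"]
        best = min(best, rmsd)
    return best


def score_match(motif: Motif, match: Match, query: Structure,
                compute_rmsd: bool = True) -> ScoredMatch:
    """Attach Levenshtein and the three RMSD modes to a match."""
    lev = levenshtein(motif.residue_string(), match_string(motif, match))
    if compute_rmsd:
        r_all = match_rmsd(motif, match, query, "all")
        r_ca = match_rmsd(motif, match, query, "ca")
        r_cacb = match_rmsd(motif, match, query, "ca_cb")
    else:
        r_all = r_ca = r_cacb = float("nan")
    return ScoredMatch(match=match, levenshtein=lev,
                       rmsd_all=r_all, rmsd_ca=r_ca, rmsd_ca_cb=r_cacb)


def _rank_key(s: ScoredMatch):
    rmsd = s.rmsd_all if not math.isnan(s.rmsd_all) else math.inf
    return (s.levenshtein, rmsd, s.match.sort_key())


def rank_matches(scored: list[ScoredMatch]) -> list[ScoredMatch]:
    """Best first: ascending Levenshtein, then all-atom RMSD, then residue
    identity for a deterministic total order."""
    return sorted(scored, key=_rank_key)
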