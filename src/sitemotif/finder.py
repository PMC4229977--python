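"""Distance-constraint search for motif matches in query structures.

A match assigns one query residue to each motif slot such that every
active pairwise atom-distance constraint is satisfied under the effective
cutoff ``(template_distance + tolerance) * precision``.  The search mirrors
the classic cascade for, e.g., a serine protease: start from every residue
of the rarest slot type, then extend one slot at a time, keeping only
candidates within the constrained distances of everything already placed.
Because constraints are pure inter-atom distances, matching is invariant
under rigid motion of the query.

A brute-force enumerator over all residue tuples is provided as an
independent oracle for verifying the progressive search on small inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .motif import Motif
from .structure import Atom, Residue, Structure

__all__ = [
    "SearchOptions",
    "Match",
    "DEFAULT_SUBSTITUTION_GROUPS",
    "effective_cutoff",
    "find_matches",
    "brute_force_matches",
]

#: Residue types treated as interchangeable when substitutions are enabled.
#: Chemically conservative side-chain swaps (hydroxyl/thiol nucleophiles,
#: carboxylates, amides, branched aliphatics, basic and aromatic pairs).
DEFAULT_SUBSTITUTION_GROUPS: tuple[frozenset[str], ...] = (
    frozenset({"SER", "CYS", "THR"}),
    frozenset({"ASP", "GLU"}),
    frozenset({"ASN", "GLN"}),
    frozenset({"VAL", "ILE", "LEU"}),
    frozenset({"LYS", "ARG"}),
    frozenset({"PHE", "TYR"}),
)


@dataclass(frozen=True)
class SearchOptions:
    """Search-time knobs: precision multiplier, imperfect-match allowance,
    and opt-in residue substitution groups."""

    precision: float = 1.0
    max_unmatched: int = 0
    substitution_groups: tuple[frozenset[str], ...] = ()

    def __post_init__(self) -> None:
        if self.precision <= 0:
            raise ValueError(f"precision must be positive, got {self.precision}")
        if self.max_unmatched < 0:
            raise ValueError("max_unmatched must be >= 0")

    def allowed_types(self, res_name: str) -> frozenset[str]:
        allowed = {res_name}
        for group in self.substitution_groups:
            if res_name in group:
                allowed |= group
        return frozenset(allowed)


def effective_cutoff(distance: float, tolerance: float, precision: float) -> float:
    """Cutoff for one constraint: tolerance widens the template distance,
    precision then scales the widened cutoff (p=1 keeps the tolerance-only
    rule)."""
    if precision <= 0:
        raise ValueError(f"precision must be positive, got {precision}")
    if distance <= 0:
        raise ValueError(f"template distance must be positive, got {distance}")
    if tolerance < 0:
        raise ValueError(f"tolerance must be non-negative, got {tolerance}")
    return (distance + tolerance) * precision


@dataclass
class Match:
    """One residue constellation satisfying a motif's active constraints."""

    motif_id: str
    query_id: str
    assignment: tuple[Residue | None, ...]
    atom_pairs: tuple[tuple[int, str, Atom], ...]
    n_substitutions: int
    n_unmatched: int

    def assigned_residues(self) -> tuple[Residue | None, ...]:
        return self.assignment

    def residue_key_set(self) -> frozenset[tuple[str, int, str]]:
        return frozenset(r.key for r in self.assignment if r is not None)

    def sort_key(self):
        sentinel = ("￿", 2**31, "￿")
        return (
            self.n_unmatched,
            self.n_substitutions,
            tuple(r.key if r is not None else sentinel for r in self.assignment),
        )


# ---------------------------------------------------------------------------
# shared semantics: slot candidacy and pairwise constraint checks

def _candidate_map(slot_atoms: tuple[str, ...], residue: Residue) -> dict[str, Atom] | None:
    """Correspondence from slot atom names to query atoms with the same name.

    Substituting residue types share only part of the atom nomenclature
    (always CB and often more); a candidate with no shared atom at all is
    unusable, since no constraint on the slot could ever be evaluated.
    """
    mapping = {name: a for name in slot_atoms if (a := residue.atom(name)) is not None}
    return mapping or None


def _pair_ok(
    motif: Motif,
    i: int,
    j: int,
    map_i: dict[str, Atom],
    map_j: dict[str, Atom],
    precision: float,
) -> bool:
    """All evaluable constraints between slots i<j hold, and at least one
    is evaluable (otherwise the pair geometry would be unconstrained)."""
    any_active = False
    for c in motif.constraints_between(i, j):
        a = map_i.get(c.atom_i) if c.slot_i == i else map_j.get(c.atom_i)
        b = map_j.get(c.atom_j) if c.slot_j == j else map_i.get(c.atom_j)
        if a is None or b is None:
            continue
        any_active = True
        cutoff = effective_cutoff(c.distance, motif.tolerance, precision)
        if float(np.linalg.norm(a.xyz - b.xyz)) > cutoff:
            return False
    return any_active


def _make_match(
    motif: Motif,
    query: Structure,
    assignment: dict[int, tuple[Residue, dict[str, Atom]]],
    n_slots: int,
) -> Match:
    full: list[Residue | None] = [None] * n_slots
    pairs: list[tuple[int, str, Atom]] = []
    n_subs = 0
    for idx, (res, mapping) in assignment.items():
        full[idx] = res
        if res.res_name != motif.slots[idx].res_name:
            n_subs += 1
        for name in motif.slots[idx].atom_names:
            if name in mapping:
                pairs.append((idx, name, mapping[name]))
    return Match(
        motif_id=motif.motif_id,
        query_id=query.struct_id,
        assignment=tuple(full),
        atom_pairs=tuple(pairs),
        n_substitutions=n_subs,
        n_unmatched=n_slots - len(assignment),
    )


def _dedupe(matches: list[Match]) -> list[Match]:
    """One match per unordered residue set: fewest unmatched slots, then
    fewest substitutions, then lexicographically smallest assignment."""
    best: dict[frozenset, Match] = {}
    for m in matches:
        key = m.residue_key_set()
        prev = best.get(key)
        if prev is None or m.sort_key() < prev.sort_key():
            best[key] = m
    return sorted(best.values(), key=Match.sort_key)


def _maximal_only(matches: list[Match]) -> list[Match]:
    """Drop partial matches whose residues are contained in a match with
    fewer unmatched slots (they are fragments of the better match)."""
    kept: list[Match] = []
    for m in matches:
        key = m.residue_key_set()
        absorbed = any(
            other.n_unmatched < m.n_unmatched and key <= other.residue_key_set()
            for other in matches
        )
        if not absorbed:
            kept.append(m)
    return kept


# ---------------------------------------------------------------------------
# progressive search

def _search_slots(
    motif: Motif,
    query: Structure,
    slot_ids: tuple[int, ...],
    options: SearchOptions,
) -> list[Match]:
    """Backtracking search assigning residues to the given slots only."""
    candidates: dict[int, list[tuple[Residue, dict[str, Atom]]]] = {}
    for idx in slot_ids:
        slot = motif.slots[idx]
        allowed = options.allowed_types(slot.res_name)
        cands = []
        for res in query.residues:
            if res.res_name not in allowed:
                continue
            mapping = _candidate_map(slot.atom_names, res)
            if mapping is not None:
                cands.append((res, mapping))
        if not cands:
            return []
        candidates[idx] = cands

    # rarest residue type first keeps the branching factor low
    order = sorted(slot_ids, key=lambda idx: (len(candidates[idx]), idx))
    results: list[Match] = []
    assignment: dict[int, tuple[Residue, dict[str, Atom]]] = {}
    used: set[tuple[str, int, str]] = set()

    def extend(depth: int) -> None:
        if depth == len(order):
            results.append(_make_match(motif, query, assignment, len(motif.slots)))
            return
        idx = order[depth]
        for res, mapping in candidates[idx]:
            if res.key in used:
                continue
            ok = all(
                _pair_ok(motif, *sorted((idx, prev)),
                         *( (mapping, assignment[prev][1]) if idx < prev
                            else (assignment[prev][1], mapping) ),
                         options.precision)
                for prev in assignment
            )
            if not ok:
                continue
            assignment[idx] = (res, mapping)
            used.add(res.key)
            extend(depth + 1)
            del assignment[idx]
            used.discard(res.key)

    extend(0)
    return results


def find_matches(motif: Motif, query: Structure, options: SearchOptions | None = None) -> list[Match]:
    """All maximal, deduplicated residue constellations satisfying the motif.

    Matches may span chains.  With ``max_unmatched > 0`` the search retries
    with slots marked UNMATCHED, reporting partial matches only where they
    are not fragments of a more complete match.  Results are in a
    deterministic order; rank them with :func:`sitemotif.scoring.rank_matches`.
    """
    options = options or SearchOptions()
    n = len(motif.slots)
    all_slots = tuple(range(n))
    matches = _search_slots(motif, query, all_slots, options)
    max_drop = min(options.max_unmatched, max(0, n - 2))
    for n_drop in range(1, max_drop + 1):
        for dropped in itertools.combinations(all_slots, n_drop):
            kept = tuple(i for i in all_slots if i not in dropped)
            matches.extend(_search_slots(motif, query, kept, options))
    return _maximal_only(_dedupe(matches))


# ---------------------------------------------------------------------------
# brute-force oracle

def brute_force_matches(
    motif: Motif, query: Structure, options: SearchOptions | None = None, *,
    size_guard: int = 80,
) -> list[Match]:
    """Exhaustive enumeration of residue tuples; definitional oracle.

    Checks every ordered tuple of distinct, type-compatible residues against
    every constraint directly from the motif record, without any of the
    progressive search's candidate filtering or cutoff helpers.
    Combinatorial — refuses structures larger than ``size_guard`` residues.
    """
    options = options or SearchOptions()
    if len(query.residues) > size_guard:
        raise ValueError(
            f"brute force is combinatorial; structure has {len(query.residues)} "
            f"residues (> {size_guard})"
        )
    n = len(motif.slots)
    matches: list[Match] = []
    max_drop = min(options.max_unmatched, max(0, n - 2))
    for n_drop in range(0, max_drop + 1):
        for dropped in itertools.combinations(range(n), n_drop):
            kept = [i for i in range(n) if i not in dropped]
            pools = []
            for idx in kept:
                slot = motif.slots[idx]
                allowed = options.allowed_types(slot.res_name)
                pool = []
                for res in query.residues:
                    if res.res_name not in allowed:
                        continue
                    mapping = {name: a for name in slot.atom_names
                               if (a := res.atom(name)) is not None}
                    if mapping:
                        pool.append((res, mapping))
                pools.append(pool)
            needed_pairs = {(kept[a], kept[b])
                            for a in range(len(kept)) for b in range(a + 1, len(kept))}
            for combo in itertools.product(*pools):
                keys = [res.key for res, _ in combo]
                if len(set(keys)) != len(keys):
                    continue
                map_by_slot = {idx: mapping for idx, (_, mapping) in zip(kept, combo)}
                ok = True
                active_pairs = set()
                for c in motif.constraints:
                    if c.slot_i not in map_by_slot or c.slot_j not in map_by_slot:
                        continue
                    a = map_by_slot[c.slot_i].get(c.atom_i)
                    b = map_by_slot[c.slot_j].get(c.atom_j)
                    if a is None or b is None:
                        continue
                    active_pairs.add((c.slot_i, c.slot_j))
                    observed = float(np.linalg.norm(a.xyz - b.xyz))
                    if observed > (c.distance + motif.tolerance) * options.precision:
                        ok = False
                        break
                if ok and active_pairs == needed_pairs:
                    assignment = {idx: pair for idx, pair in zip(kept, combo)}
                    matches.append(_make_match(motif, query, assignment, n))
    return _maximal_only(_dedupe(matches))
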