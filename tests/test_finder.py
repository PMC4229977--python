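import numpy as np
import pytest

from conftest import motif_from_result
from sitemotif.finder import (
    DEFAULT_SUBSTITUTION_GROUPS,
    SearchOptions,
    brute_force_matches,
    effective_cutoff,
    find_matches,
)
from sitemotif.fixtures import (
    FixtureSpec,
    random_rigid_transform,
    synth_structure,
)
from sitemotif.motif import DistanceConstraint, Motif, MotifSlot
from sitemotif.structure import Structure, read_pdb

# decoy pool that includes the triad's own residue types, so the search
# actually has to discriminate on geometry, not composition
HARD_DECOYS = ("SER", "HIS", "ASP", "CYS", "GLU", "ALA", "GLY", "LYS")


def hard_fixture(seed: int, noise_sd: float = 0.3):
    spec = FixtureSpec(seed=seed, n_decoys=30, decoy_types=HARD_DECOYS,
                       noise_sd=noise_sd)
    return read_pdb(synth_structure(spec).pdb_text)


@pytest.mark.parametrize(
    "distance,tolerance,precision,expected",
    [(5.0, 2.0, 1.0, 7.0), (5.0, 0.0, 1.0, 5.0), (5.0, 2.0, 0.5, 3.5)],
)
def test_effective_cutoff(distance, tolerance, precision, expected):
    assert effective_cutoff(distance, tolerance, precision) == pytest.approx(expected)


def test_effective_cutoff_rejects_bad_precision():
    with pytest.raises(ValueError, match="precision"):
        effective_cutoff(5.0, 2.0, 0.0)
    with pytest.raises(ValueError, match="precision"):
        SearchOptions(precision=-1.0)


class TestFindMatches:
    def test_single_planted_triad_is_found_exactly_once(self, triad_motif, triad_structure):
        matches = find_matches(triad_motif, triad_structure)
        assert len(matches) == 1
        (m,) = matches
        assert m.n_substitutions == 0 and m.n_unmatched == 0
        assert m.residue_key_set() == {("A", 1, ""), ("A", 2, ""), ("A", 3, "")}
        oracle = brute_force_matches(triad_motif, triad_structure)
        assert {x.residue_key_set() for x in oracle} == {m.residue_key_set()}

    def test_displaced_acid_breaks_the_match(self, triad_result):
        motif, structure = motif_from_result(triad_result)
        shift = 3.0 * motif.tolerance  # far beyond every cutoff
        displaced = []
        for res in structure.residues:
            if res.seq_id == 3:  # the planted ASP
                from sitemotif.structure import Atom, Residue

                atoms = [Atom(a.name, a.element,
                              (a.coords[0] + shift, a.coords[1] + shift,
                               a.coords[2] + shift)) for a in res.atoms]
                res = Residue(res.res_name, res.seq_id, res.chain, res.icode, atoms)
            displaced.append(res)
        q = Structure(structure.struct_id, displaced)
        assert find_matches(motif, q) == []
        assert brute_force_matches(motif, q) == []

    def test_two_identical_sites_give_two_matches(self, triad_motif):
        q = read_pdb(synth_structure(
            FixtureSpec(sites=("triad", "triad"), n_decoys=30, seed=11)).pdb_text)
        matches = find_matches(triad_motif, q)
        assert len(matches) == 2
        assert len({m.residue_key_set() for m in matches}) == 2

    def test_cysteine_substitutes_for_serine_only_when_enabled(self, triad_motif):
        q = read_pdb(synth_structure(
            FixtureSpec(sites=("thiol-triad",), n_decoys=20, seed=5)).pdb_text)
        assert find_matches(triad_motif, q) == []
        opts = SearchOptions(substitution_groups=DEFAULT_SUBSTITUTION_GROUPS)
        matches = find_matches(triad_motif, q, opts)
        assert len(matches) == 1 and matches[0].n_substitutions == 1
        assert matches[0].assignment[0].res_name == "CYS"

    def test_one_unmatched_slot_recovers_partial_site(self, triad_motif, triad_structure):
        pruned = Structure(
            triad_structure.struct_id,
            [r for r in triad_structure.residues if r.seq_id != 1],  # drop SER
        )
        assert find_matches(triad_motif, pruned) == []
        matches = find_matches(triad_motif, pruned, SearchOptions(max_unmatched=1))
        assert len(matches) == 1
        (m,) = matches
        assert m.n_unmatched == 1 and m.assignment[0] is None
        assert m.residue_key_set() == {("A", 2, ""), ("A", 3, "")}

    def test_partials_absorbed_by_full_matches(self, triad_motif, triad_structure):
        full = find_matches(triad_motif, triad_structure)
        with_partials = find_matches(triad_motif, triad_structure,
                                     SearchOptions(max_unmatched=1))
        # intact site: the fragments of the full match must not be reported
        assert {m.residue_key_set() for m in with_partials} == \
            {m.residue_key_set() for m in full}

    def test_empty_structure_brute_force(self, triad_motif):
        assert brute_force_matches(triad_motif, Structure("empty", [])) == []

    def test_brute_force_size_guard(self, triad_motif):
        big = read_pdb(synth_structure(FixtureSpec(seed=1, n_decoys=90)).pdb_text)
        with pytest.raises(ValueError, match="combinatorial"):
            brute_force_matches(triad_motif, big)


class TestOracleEquivalence:
    @pytest.mark.parametrize("precision", [0.8, 1.0, 1.2])
    @pytest.mark.parametrize("max_unmatched", [0, 1])
    def test_matches_equal_brute_force_on_random_fixtures(
        self, triad_motif, precision, max_unmatched
    ):
        for seed in range(40):
            q = hard_fixture(seed)
            opts = SearchOptions(precision=precision, max_unmatched=max_unmatched)
            fast = {m.residue_key_set() for m in find_matches(triad_motif, q, opts)}
            slow = {m.residue_key_set() for m in brute_force_matches(triad_motif, q, opts)}
            assert fast == slow, f"seed {seed}"

    def test_equivalence_with_substitutions(self, triad_motif):
        opts = SearchOptions(substitution_groups=DEFAULT_SUBSTITUTION_GROUPS)
        for seed in range(15):
            q = hard_fixture(seed, noise_sd=0.5)
            fast = {m.residue_key_set() for m in find_matches(triad_motif, q, opts)}
            slow = {m.residue_key_set() for m in brute_force_matches(triad_motif, q, opts)}
            assert fast == slow, f"seed {seed}"


class TestInvariances:
    def test_precision_monotonicity(self, triad_motif):
        for seed in range(20):
            q = hard_fixture(seed)
            prev: set = set()
            for p in (0.6, 0.8, 1.0, 1.2, 1.5):
                curr = {m.residue_key_set()
                        for m in find_matches(triad_motif, q, SearchOptions(precision=p))}
                assert prev <= curr
                prev = curr

    def test_tolerance_monotonicity(self, triad_motif, triad_structure):
        import dataclasses

        prev: set = set()
        for tol in (0.0, 0.5, 1.0, 2.0, 4.0):
            motif = dataclasses.replace(triad_motif, tolerance=tol)
            curr = {m.residue_key_set() for m in find_matches(motif, triad_structure)}
            assert prev <= curr
            prev = curr

    def test_rigid_motion_invariance(self, triad_motif):
        for seed in range(5):
            q = hard_fixture(seed)
            moved = random_rigid_transform(q, seed + 1000)
            a = {m.residue_key_set() for m in find_matches(triad_motif, q)}
            b = {m.residue_key_set() for m in find_matches(triad_motif, moved)}
            assert a == b

    def test_slot_order_invariance(self, triad_motif, triad_structure):
        perm = [2, 0, 1]
        inv = {old: new for new, old in enumerate(perm)}
        slots = []
        for new_idx, old_idx in enumerate(perm):
            s = triad_motif.slots[old_idx]
            slots.append(MotifSlot(new_idx, s.res_name, s.source_seq_id,
                                   s.source_chain, s.atom_names, s.template_coords))
        constraints = []
        for c in triad_motif.constraints:
            i, ai, j, aj = inv[c.slot_i], c.atom_i, inv[c.slot_j], c.atom_j
            if i > j:
                i, ai, j, aj = j, aj, i, ai
            constraints.append(DistanceConstraint(i, ai, j, aj, c.distance))
        permuted = Motif(
            "permuted", triad_motif.source_pdb, triad_motif.ec_number,
            triad_motif.set_label, slots, constraints, triad_motif.tolerance,
        )
        a = {m.residue_key_set() for m in find_matches(triad_motif, triad_structure)}
        b = {m.residue_key_set() for m in find_matches(permuted, triad_structure)}
        assert a == b and a
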