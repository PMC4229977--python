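import math

import edlib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import horn_rmsd, levenshtein_recursive
from conftest import motif_from_result
from sitemotif.finder import (
    DEFAULT_SUBSTITUTION_GROUPS,
    SearchOptions,
    find_matches,
)
from sitemotif.fixtures import (
    FixtureSpec,
    perturb_structure,
    random_rigid_transform,
    synth_structure,
)
from sitemotif.scoring import (
    ScoredMatch,
    levenshtein,
    match_rmsd,
    match_string,
    rank_matches,
    score_match,
    superpose,
)
from sitemotif.structure import read_pdb

short_strings = st.text(alphabet="ACDEFGHS", max_size=7)


class TestLevenshtein:
    @pytest.mark.parametrize("a,b,expected", [
        ("HSE", "HSE", 0),   # identical catalytic strings
        ("HSE", "HCE", 1),   # His-Ser-Glu motif vs His-Cys-Glu match
        ("", "HSE", 3),
        ("HSD", "", 3),
        ("kitten", "sitting", 3),
    ])
    def test_known_distances(self, a, b, expected):
        assert levenshtein(a, b) == expected

    @given(a=short_strings, b=short_strings)
    @settings(max_examples=150, deadline=None)
    def test_agrees_with_recursive_oracle(self, a, b):
        assert levenshtein(a, b) == levenshtein_recursive(a, b)

    @given(a=short_strings, b=short_strings, c=short_strings)
    @settings(max_examples=100, deadline=None)
    def test_is_a_metric(self, a, b, c):
        assert levenshtein(a, b) == levenshtein(b, a)
        assert (levenshtein(a, b) == 0) == (a == b)
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)

    def test_agrees_with_edlib_on_longer_strings(self):
        rng = np.random.default_rng(0)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(20):
            a = "".join(rng.choice(letters, size=rng.integers(0, 30)))
            b = "".join(rng.choice(letters, size=rng.integers(0, 30)))
            want = edlib.align(a, b, task="distance")["editDistance"]
            assert levenshtein(a, b) == want


class TestMatchString:
    def test_perfect_triad_transcription(self, triad_motif, triad_structure):
        (m,) = find_matches(triad_motif, triad_structure)
        assert triad_motif.residue_string() == "SHD"
        assert match_string(triad_motif, m) == "SHD"
        assert levenshtein("SHD", match_string(triad_motif, m)) == 0

    def test_substituted_position_changes_letter(self, triad_motif):
        q = read_pdb(synth_structure(
            FixtureSpec(sites=("thiol-triad",), n_decoys=10, seed=5)).pdb_text)
        opts = SearchOptions(substitution_groups=DEFAULT_SUBSTITUTION_GROUPS)
        (m,) = find_matches(triad_motif, q, opts)
        assert match_string(triad_motif, m) == "CHD"
        assert levenshtein(triad_motif.residue_string(), "CHD") == 1

    def test_unmatched_slot_is_a_deletion(self, triad_motif, triad_structure):
        from sitemotif.structure import Structure

        pruned = Structure(triad_structure.struct_id,
                           [r for r in triad_structure.residues if r.seq_id != 1])
        (m,) = find_matches(triad_motif, pruned, SearchOptions(max_unmatched=1))
        s = match_string(triad_motif, m)
        assert len(s) == 2
        assert levenshtein(triad_motif.residue_string(), s) == 1


class TestSuperpose:
    def test_identical_sets_zero_rmsd(self):
        pts = np.arange(15.0).reshape(5, 3)
        assert superpose(pts, pts)["rmsd"] == pytest.approx(0.0, abs=1e-12)

    def test_recovers_rigid_motion(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0],
                        [0, 0, 1.0]])
        moved = pts @ rot.T + [3.0, -2.0, 7.0]
        out = superpose(pts, moved)
        assert out["rmsd"] <= 1e-8
        np.testing.assert_allclose(out["rotation"] @ rot, np.eye(3), atol=1e-8)

    def test_agrees_with_quaternion_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ref = rng.normal(scale=3.0, size=(5, 3))
            mov = rng.normal(scale=3.0, size=(5, 3))
            assert superpose(ref, mov)["rmsd"] == pytest.approx(
                horn_rmsd(ref, mov), abs=1e-6)

    def test_proper_rotation_even_for_reflected_input(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 3))
        mirrored = pts * [-1.0, 1.0, 1.0]
        out = superpose(pts, mirrored)
        assert np.linalg.det(out["rotation"]) == pytest.approx(1.0)

    def test_shape_errors(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((3, 3)), np.zeros((4, 3)))
        with pytest.raises(ValueError):
            superpose(np.zeros((0, 3)), np.zeros((0, 3)))


class TestMatchRmsd:
    def test_self_match_zero_in_all_modes(self, triad_motif, triad_structure):
        (m,) = find_matches(triad_motif, triad_structure)
        s = score_match(triad_motif, m, triad_structure)
        assert s.levenshtein == 0
        assert s.rmsd_all == pytest.approx(0.0, abs=1e-6)
        assert s.rmsd_ca_cb == pytest.approx(0.0, abs=1e-6)
        # sidechain-only motif stores no CA atoms: Cα mode undefined
        assert math.isnan(s.rmsd_ca)

    def test_ca_mode_defined_with_backbone_motif(self, triad_result):
        from sitemotif.maker import ResidueSpec, build_motif

        motif, structure = motif_from_result(triad_result)
        specs = [ResidueSpec(r["res_name"], r["seq_id"], r["chain"], include_backbone=True)
                 for r in triad_result.manifest["planted_residues"]]
        bb_motif = build_motif(structure, specs, motif_id="bb")
        (m,) = find_matches(bb_motif, structure)
        s = score_match(bb_motif, m, structure)
        assert s.rmsd_ca == pytest.approx(0.0, abs=1e-6)

    def test_invariant_under_rigid_motion_of_query(self, triad_motif, triad_structure):
        (m0,) = find_matches(triad_motif, triad_structure)
        base = match_rmsd(triad_motif, m0, triad_structure, "all")
        moved = random_rigid_transform(triad_structure, seed=4)
        (m1,) = find_matches(triad_motif, moved)
        assert match_rmsd(triad_motif, m1, moved, "all") == pytest.approx(base, abs=1e-6)

    def test_noise_raises_rmsd_into_expected_band(self, triad_motif, triad_structure):
        values = []
        for seed in range(100):
            q = perturb_structure(triad_structure, 0.1, seed)
            matches = find_matches(triad_motif, q)
            if not matches:
                continue
            values.append(min(match_rmsd(triad_motif, m, q, "all") for m in matches))
        # i.i.d. sigma=0.1 Å per coordinate: all-atom RMSD concentrates
        # well inside this bracket once superposition removes 6 d.o.f.
        assert len(values) > 90
        mean = float(np.mean(values))
        assert 0.05 <= mean <= 0.35
        assert all(0.02 <= v <= 0.6 for v in values)

    def test_symmetric_sidechain_relabeling_not_penalized(self, triad_motif, triad_structure):
        # swap the chemically equivalent ASP carboxylate oxygens in the query
        from sitemotif.structure import Atom, Residue, Structure

        swapped = []
        for res in triad_structure.residues:
            if res.seq_id == 3 and res.res_name == "ASP":
                rename = {"OD1": "OD2", "OD2": "OD1"}
                atoms = [Atom(rename.get(a.name, a.name), a.element, a.coords)
                         for a in res.atoms]
                res = Residue(res.res_name, res.seq_id, res.chain, res.icode, atoms)
            swapped.append(res)
        q = Structure(triad_structure.struct_id, swapped)
        (m,) = find_matches(triad_motif, q)
        assert match_rmsd(triad_motif, m, q, "all") == pytest.approx(0.0, abs=1e-6)


class TestRanking:
    def _scored(self, lev, rmsd, match):
        return ScoredMatch(match=match, levenshtein=lev, rmsd_all=rmsd,
                           rmsd_ca=float("nan"), rmsd_ca_cb=float("nan"))

    def test_levenshtein_then_rmsd(self, triad_motif, triad_structure):
        (m,) = find_matches(triad_motif, triad_structure)
        ranked = rank_matches([
            self._scored(1, 0.1, m),
            self._scored(0, 1.5, m),
            self._scored(0, 0.9, m),
        ])
        assert [(s.levenshtein, s.rmsd_all) for s in ranked] == \
            [(0, 0.9), (0, 1.5), (1, 0.1)]

    def test_empty_input(self):
        assert rank_matches([]) == []
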