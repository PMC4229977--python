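# Methods

## The matching model

A motif template is an orientation-independent summary of an active site:
an ordered list of residue slots, each carrying a residue type, the source
residue's author identity, an atom list (side-chain heavy atoms, i.e.
everything outside the N/CA/C/O backbone, optionally plus that backbone),
and the template coordinates of those atoms; plus one distance constraint
per atom pair across every slot pair, and a tolerance *t* in Å.

Recording *every* cross-slot atom pair is the strictest distance-only
reading of a site's "relative geometry". It over-determines the rigid
arrangement (3 residues × a few atoms each give tens of constraints for
what is at most a 6-degree-of-freedom relationship), which is deliberate:
redundancy makes the filter sharp without any coordinate frame, and a
genuine site satisfies all of the constraints at once while decoys that
happen to satisfy a few do not survive.

A query assignment matches when every *active* constraint satisfies

    observed_distance ≤ (template_distance + t) · p

with precision factor *p* applied at search time. Two semantics choices
are worth stating explicitly:

* **Upper bound only.** A constraint caps the observed distance; there is
  no floor. This mirrors within-distance selection semantics; a site
  compressed below its template distances still matches. In practice the
  many cross-constraints make "too close overall" geometrically difficult.
* **Precision scales the widened cutoff**, not the raw template distance,
  so *p* = 1 is exactly the tolerance-only rule and the default behaviour
  does not change when the precision knob is introduced.

**Substitutions and partial correspondence.** Substitution groups
({Ser,Cys,Thr}, {Asp,Glu}, {Asn,Gln}, {Val,Ile,Leu}, {Lys,Arg}, {Phe,Tyr})
are opt-in. A substituting residue shares only part of the motif's atom
nomenclature, so correspondence is by identical atom name and a constraint
whose atom has no counterpart is inactive for that candidate. Every
matched slot pair must retain at least one active constraint; otherwise
the candidate is rejected rather than matched vacuously. For the shipped
groups the shared atoms always include Cβ (and usually Cγ or ring atoms),
so substituted slots remain geometrically constrained.

**Imperfect matches.** `max_unmatched = k` allows up to *k* slots to stay
unassigned (at least two slots must remain). Partial matches whose residue
set is contained in a more complete match are suppressed as fragments.
The converse imperfection — an *extra* residue beyond the motif's slots —
is not representable in a slot-assignment model and is out of scope.

**Deduplication and determinism.** Matches are deduplicated by the
unordered set of assigned query residues; among duplicates the engine
keeps the fewest-unmatched, then fewest-substitution, then
lexicographically smallest assignment. All orderings are total, so search
output and batch CSV are byte-reproducible.

## Search algorithm and its oracle

`find_matches` orders slots by ascending candidate count (rarest residue
type first) and extends partial assignments one slot at a time, pruning
any candidate violating a constraint against an already-assigned slot.
`brute_force_matches` enumerates every type-compatible residue tuple and
evaluates every constraint directly from the motif record; it shares
no traversal or cutoff code with the progressive search and serves as the
definitional oracle in the tests (equivalence over 200 randomized
structures × 3 precisions × 2 unmatched limits, decoy pools deliberately
containing the motif's own residue types).

## Scoring

* **Levenshtein distance** — standard unit-cost dynamic programme,
  computed between the motif's one-letter string (slot order) and the
  match's string (assigned residues in slot order, unmatched slots
  omitted so they surface as deletions). Cross-checked in tests against a
  memoised recursive definition and against edlib.
* **RMSD** — computed *after* optimal superposition (Kabsch via SVD with
  the proper-rotation determinant correction). The template and the query
  live in unrelated frames, so superposition is the only frame-independent
  definition consistent with a native self-match scoring ≈ 0. Three atom
  selections: all name-matched atoms per slot, Cα only, Cα+Cβ (glycine
  contributes Cα alone). A sidechain-only motif stores no Cα, so Cα-mode
  RMSD is *undefined* and reported as NaN / an empty CSV field rather
  than an error. Chemically equivalent atom labelings (Asp Oδ1/Oδ2,
  Glu Oε1/Oε2, Phe/Tyr ring, Arg Nη1/Nη2) are tried both ways per residue
  and the lower RMSD kept, avoiding spurious ~1 Å inflation on symmetric
  side chains. The Kabsch implementation is verified against Horn's
  quaternion closed form. No ordering between the three RMSD modes is
  assumed or asserted; they are not monotone in general.
* **Ranking** — ascending (Levenshtein, all-atom RMSD, residue identity);
  NaN RMSD sorts last.

## Structure input

PDB parsing is delegated to gemmi and normalized to a flat residue list:
first model only (templates are built from crystal structures; multi-model
NMR input is reduced, not averaged), hydrogens and waters dropped,
non-amino-acid HETATM dropped except selenomethionine (kept as MET),
alternate locations resolved to the highest-occupancy conformer with ties
broken by altloc character. Residue identity is author numbering plus
insertion code, because catalytic-residue definitions are published in
author numbering. gemmi silently zero-fills malformed numeric fields, so
ATOM/HETATM coordinate columns are pre-validated to report a parse error
with its line number.

## The synthetic-structure generator

The generator emulates the only features a distance-constraint engine
reads: residue types and heavy-atom geometry.

* **Residue geometry** comes from an internal-coordinate (NeRF) builder
  over a 16-type template table with standard bond lengths and angles and
  one fixed rotamer per type. Rings are built without closure refinement —
  self-consistent, and frozen into both structure and manifest, which is
  all that matters for distance constraints.
* **Planted sites**: the Ser–His–Asp triad (Oγ···Nε2 = 3.0 Å,
  Nδ1···Oδ1 = 2.8 Å, hydrogen-bond-range heavy-atom contacts) and a
  Cys–His–Asp variant (Sγ···Nε2 = 3.5 Å). Sites are placed under a seeded
  Haar-random rotation; optional i.i.d. Gaussian noise (σ in Å per
  coordinate) perturbs planted atoms. The manifest records the planted
  identities and the ideal pre-noise inter-atom distances.
* **Decoys**: independent idealized residues packed uniformly in a box at
  0.008 residues/Å³ with a 4 Å minimum centroid separation (sequential
  rejection sampling with bounded retries; the density is kept below the
  random-packing jamming regime so placement is reliable at every seed).
  The default decoy composition excludes the planted site types, giving a
  clean true-negative background; tests that stress the search instead
  draw decoys from the triad's own types.

What the generator does **not** emulate: chain connectivity, backbone
torsional statistics, sterics between residues, side-chain rotamer
diversity, crystallographic disorder. Passing tests therefore demonstrate
the engine's correctness (search completeness, scoring, invariances) on
geometry like real sites', not annotation accuracy on real proteomes —
measuring true/false-positive rates requires a curated motif library and
a structure corpus, which are outside this package.

## Problem sizes and numerical choices

The standard fixture is one planted triad plus ~25–41 decoys (≤ 60
residues), small enough that brute-force enumeration stays exact and the
full test suite runs in well under a minute. Key numbers: tolerance
default 2.00 Å; self-test threshold 1e-6 Å all-atom RMSD (double-precision
superposition of byte-identical coordinates is exact to ~1e-14); PDB
round-trip comparisons at 1e-3 Å (fixed-width format); Kabsch vs
quaternion agreement at 1e-6 Å; the noise-sweep recovery curve uses 100
replicates per level with a two-standard-error Monte-Carlo slack on the
monotonicity assertion; brute force refuses structures over 80 residues.
The recovery curve's endpoints are structural, not statistical: at σ = 0
the planted site satisfies its own constraints identically, and at
σ = 3 Å typical atom displacements (≈ 4.8 Å, χ₃ mean) exceed every
tolerance-widened cutoff difference, so recovery is 0 across seeds.

## Motif files

Motifs are declarative YAML (one per file), not executable code: slots
with template coordinates, explicit constraint list, tolerance. Template
coordinates live in the motif so RMSD is computable without the source
structure. Set labels follow the P/U developer/user convention (J and N
reserved); a library directory is filtered by label at load, unreadable
files are skipped with a warning, duplicate motif ids are fatal.

## Known limitations

* Metal ions, prosthetic groups and any non-amino-acid site components
  cannot be part of a motif.
* No statistical calibration of RMSD or match significance is provided.
* The "extra residue" class of imperfect match is not representable.
* mmCIF input, symmetry/assembly expansion and nucleic-acid chains are
  out of scope; the distance floor question (should a match also be
  rejected for being *too close*?) is resolved as "no floor" by design.
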