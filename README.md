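# sitemotif

Template-based annotation of enzyme active sites from protein structure.

Structural genomics deposits far more structures than wet-lab work can
characterize, so function must often be inferred *in silico*. Sequence
similarity misses cases where catalysis is determined locally: a handful of
catalytic residues can be conserved in spatial arrangement even when global
sequence and fold have diverged. `sitemotif` is a small library and CLI for
exactly that local, geometry-first comparison: it builds
orientation-independent **motif templates** of catalytic sites from
structures of known function, searches query structures for residue
constellations that satisfy the template, and scores each hit. It is aimed
at structural bioinformaticians who want a transparent, scriptable
distance-constraint engine — for annotating structures of unknown function
against a motif library, or for building and curating such a library from
catalytic-residue definitions (e.g. Catalytic Site Atlas entries).

## The method

A motif template over catalytic residues *1…n* (each with side-chain heavy
atoms, optionally plus backbone N/CA/C/O) records every inter-residue
atom-pair distance

&nbsp;&nbsp;&nbsp;&nbsp;*d*(*i·a*, *j·b*) = ‖**x**<sub>ia</sub> − **x**<sub>jb</sub>‖

together with a tolerance *t* (default **2.00 Å**). At search time a
precision factor *p* (default 1.0) rescales the constraints: a query
residue assignment is a **match** iff for every constrained atom pair

&nbsp;&nbsp;&nbsp;&nbsp;‖**y**<sub>ia</sub> − **y**<sub>jb</sub>‖ ≤ (*d* + *t*) · *p*.

Because only pairwise distances enter, matching is invariant under any
rigid motion of the query. The search proceeds progressively — seed with
all residues of the rarest slot type (for a serine protease: all serines),
then keep only histidines within the constrained distances of a serine,
then aspartates within range of both — which is equivalent to, and tested
against, brute-force enumeration. Matches are scored two ways:

* **Levenshtein distance** between the motif's one-letter residue string
  and the match's (0 = same residue types slot for slot; e.g. His‑Ser‑Glu
  vs His‑Cys‑Glu scores 1);
* **RMSD** after optimal least-squares rigid superposition (Kabsch) of the
  template atoms onto the matched query atoms, reported for all atoms,
  Cα only, and Cα+Cβ.

Matches are ranked by Levenshtein distance, then all-atom RMSD.

Nothing here needs a network or a structure database: a fixture generator
synthesizes PDB-format structures with planted catalytic-triad geometry
plus decoy residues, with ground truth recorded alongside.

## Worked example

Make a synthetic serine-protease-like structure, build a motif from its
catalytic triad, then search a noisy copy of the site:

```sh
sitemotif synth --sites triad --decoys 20 --seed 7 --out fix.pdb
sitemotif make-motif --pdb fix.pdb \
    --residue SER:1:A --residue HIS:2:A --residue ASP:3:A \
    --ec 3.4.21.4 --out triad.yaml
sitemotif synth --sites triad --decoys 40 --noise 0.2 --seed 11 --out query.pdb
sitemotif find --pdb query.pdb --motif triad.yaml
```

which prints:

```
query_id,motif_id,motif_ec,levenshtein,rmsd_all,rmsd_ca,rmsd_ca_cb,n_substitutions,n_unmatched,assignment
query,fix_1,3.4.21.4,0,0.316,,0.105,0,0,A:1:SER;A:2:HIS;A:3:ASP
```

One constellation — residues Ser1, His2, Asp3 of chain A — satisfies all
44 distance constraints. Levenshtein 0 means the residue types match the
motif exactly (no substitutions, no unmatched slots); the all-atom RMSD of
0.316 Å is what 0.2 Å of per-coordinate noise looks like after optimal
superposition of the twelve side-chain atoms. The Cα column is empty
because this motif stores side-chain atoms only; rebuild with
`--residue SER:1:A:backbone …` to score Cα RMSD as well. Decoy residues
produce no rows: composition alone never satisfies the geometry.

`make-motif` self-tests every new template against its source structure
(the template must re-find its own site with Levenshtein 0 and RMSD ≈ 0)
before writing it. `batch` runs directories of structures against motif
libraries and writes one CSV row per scored match; `validate` checks motif
files; substitutions (e.g. Cys matching a Ser slot) are opt-in via
`--substitutions on`, and near-misses with one missing residue via
`--max-unmatched 1`.

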