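# Methods

## Model and assumptions

The unit of analysis is the imaginary transition structure (ITS): the
topological superposition of the reactant and product graphs of one
balanced, atom-mapped reaction. Nodes are keyed by atom-map number and
carry per-side formal charge, hybridization label, radical count and
aromatic flag; edges carry per-side bond orders (0, 1, 1.5, 2, 3), with
1.5 reserved for aromatic bonds. The ITS is a bookkeeping device for
which atoms and bonds change; it makes no mechanistic claim. An atom is
*changed* when any per-side scalar attribute differs; a bond when its two
orders differ. Molecules contributing no changed atom (true spectators)
are omitted. The reaction center is the subgraph of changed atoms,
changed bonds, and unchanged bonds between changed atoms.

The central assumption of the template model is that substructures
conserved across all reactions of one enzyme mark atoms that matter —
for binding in the active pocket or for the mechanism — while
non-conserved periphery is tolerated variation. Template growth therefore
adds atoms shell-wise only where every known ITS agrees, and the depth at
which the tree first branches defines the most specific rule supported by
the data, with no user-chosen radius.

## Template expansion in detail

* One template atom is *expandable* when, under at least one embedding
  into at least one ITS, it has a neighbor outside the template.
* An expansion step adds the **entire** neighborhood of the chosen atoms
  (all neighbors plus all bonds among covered atoms). Partial
  neighborhoods are never added; this is what makes the greedy search
  well-defined and is mirrored exactly by the exhaustive oracle.
* Among subsets of expandable atoms, the largest one whose enlarged
  template is isomorphic across every ITS wins; ties are broken by fewer
  hydrogen atoms in the result, then by canonical hash for determinism.
  Subsets are enumerated exhaustively up to 12 shortlisted atoms; beyond
  that a greedy fallback (jointly expanding all individually-common
  atoms) takes over.
* Template identity and branch grouping use a Weisfeiler–Lehman hash
  over element, per-side charges and aromatic flags (nodes) and per-side
  orders (edges); groups formed by hash share one child. Template
  matching itself uses exact subgraph monomorphism with the same
  attribute semantics, so hybridization labels influence *change*
  detection but not matching.
* An atom added inside a ring pulls in its whole ring (minimum cycle
  basis membership, closed transitively) within the same step.
* Kekulization artifacts are suppressed: a 1/2-order flip between two
  atoms aromatic on both sides is recorded as an unchanged 1.5 bond.
* Duplicate inputs are removed by canonical ITS hash before building;
  stereochemistry is not part of the ITS, so inputs differing only in
  stereo descriptors collapse to one leaf (stereo is handled at scoring
  time instead).
* Embeddings per (template, ITS) are capped (default 256) to bound the
  combinatorics of highly symmetric molecules; the cap is configurable.

Input reactions whose centers are not mutually isomorphic raise a
center-conflict error naming the minority reactions — in practice the
way faulty atom maps surface. Mutually exclusive centers can be admitted
explicitly, producing one root per center class (a forest).

In single-substrate mode the same machinery runs on plain molecule
graphs; the root is a user seed (e.g. `C([H])O[H]` for a secondary
alcohol) or the largest connected component of the maximum common
substructure of all inputs (RDKit FMCS over element and bond order).

## Scoring

    score = c_S·S_S + c_P·S_P + c_M·S_M + c_L·S_L,
    defaults (c_S, c_P, c_M, c_L) = (+1, −1, +1, −0.1)

Fingerprints are Morgan, radius 2, 2048 bits, no feature invariants;
similarity is Tanimoto. All parameters live in `SimilarityParams`.

* `S_P` (specificity) is the mean similarity over unordered distinct
  leaf pairs, capped at 0.8 so that single-substrate trees are treated
  as moderately specific rather than maximally specific; a tree with one
  leaf scores the cap exactly. Only reactant-side molecules enter
  (products are excluded by choice; the substrate side is what binding
  selectivity is about).
* `S_S`/`S_M` compare the query to leaf substrates within the matched
  branch / the whole tree. In reaction mode, each side is compared
  separately — each query molecule is paired with its most similar
  counterpart and the per-molecule maxima averaged — and the two sides'
  values averaged. With default coefficients the total score lies in
  [−1.2, 2.0]; the suggested activity threshold is 0.5.
* `S_L` is the number of tree edges from the matched template to its
  nearest descendant leaf, capped at 5, minus 1 (floored at 0 for the
  corner case of a node that is both template and leaf). Leaves are not
  match targets, so the ideal distance is 1 and the ideal `S_L` is 0.

Substrate queries embed the reactant-side fragments of the root template
in the query molecule(s); each distinct embedding site is one
regiochemical candidate. A candidate ITS is assembled by overlaying the
root's per-side orders and product-side attributes on the host molecule
graphs; its product-side projection yields the proposed products. Each
reactant fragment not covered by the query defines a cosubstrate role;
every distinct leaf substrate containing that fragment yields one
candidate (with cosubstrate search disabled, a missing fragment scores
0). Descent through the tree is anchored at the matched site, so
chemically different sites of one molecule can receive different scores.

Stereocenters are compared only at scoring time: a candidate is flagged
(never removed) when a CIP code at a root-matched query atom contradicts
the corresponding atom of *every* leaf that specifies one. Comparison is
restricted to root atoms — the atoms whose configuration the
transformation actually touches.

## Synthetic families

The generator emulates a per-enzyme reaction set: `n` dehydrogenations
of secondary alcohols `CH3–CH(OH)–(C(R,R'))_depth–H → ketone + H2`,
with substituent slots drawn from an alphabet of single-attachment
groups (H, F, Cl, Br, methyl, hydroxyl). Every pair of alphabet members
differs already at the attachment atom, so the conserved region of a
family is exactly the set of identically decorated positions — which
makes the expected most-specific-common template known by construction
and lets the exhaustive oracle serve as an exact check. Members are
deduplicated by canonical substrate structure; generation is
deterministic under a fixed seed. Defaults (3 reactions, depth 2,
alphabet H/F/Cl/methyl) keep members at ≤ 15 heavy atoms.

What the generator does **not** emulate: cofactor chemistry, charged and
tautomeric substrates, rings and aromatic systems, stereochemistry, and
mapping noise. Passing property batteries on these families therefore
demonstrates algorithmic correctness (containment, monotonicity,
determinism, greedy-equals-exhaustive, score bounds and ordering), not
predictive accuracy on real screening data.

## Problem sizes and numerical choices

The property batteries use 200 families (1–4 reactions, depth 1–2) for
tree invariants, 50 families of 2–3 reactions for oracle equivalence,
and 15 families for scoring properties — sizes at which the exhaustive
oracle and the full batteries run in well under a minute while covering
all branching regimes the builder has. Scores are plain floating point;
the only tolerances used in tests are 1e-12 comparisons for quantities
that are algebraically equal. Determinism is achieved by sorting every
iteration order (node keys, children, hash keys) rather than by seeding.

## Known limitations

* Balanced, fully atom-mapped input is required; hydrogens that migrate
  between heavy atoms must be mapped explicitly (auto-numbering pairs
  hydrogens by parent heavy atom and refuses ambiguous cases).
* Greedy subset expansion is not guaranteed optimal in general; the
  oracle battery verifies optimality only on generator-style families
  where variation begins at the attachment atom.
* The Weisfeiler–Lehman hash can in principle collide for non-isomorphic
  graphs; branch groups therefore share a child on hash equality, and a
  collision would merge two branches rather than corrupt containment.
* Scoring is structure-based: enzymes whose activity does not track
  substrate similarity will not be predicted well, and extrapolation far
  from the known substrates is unreliable by construction.
* Inconsistent input representations (e.g. open- vs closed-form sugars,
  inconsistent protonation of the same group) cause spurious early
  branching, exactly as faulty maps do.
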