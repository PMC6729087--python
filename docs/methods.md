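# Methods

## Protocols

All three protocols orchestrate the same inner engine contract
(`dock(receptor, fragment, config) -> PosePool`) and differ only in how
engine calls are arranged and how their binding-mode pools are combined.

* **single** — one engine call on the whole ligand.  The engine's
  `exhaustiveness` parameter scales the number of independent internal
  runs (`runs_per_exhaustiveness × exhaustiveness`, default 4 runs per
  unit), so "running longer" is expressed as a larger exhaustiveness.
* **multi** — `instances` independent engine calls with seeds
  `master_seed + 0 … n−1`, pools merged.  Executed sequentially; results
  are by construction identical to any concurrent execution, because each
  call is a pure function of its seed.
* **incremental** — fragment-based meta-docking.  With `N` rotatable
  bonds, `rounds = r` and `new_bonds = b`, the fragment size is
  `k = N − (r−1)·b`; if that would drop below 1, `r` is clamped to the
  largest feasible value (logged).  Round 1 docks the initial fragment
  (torsion-tree root plus the `k` branches nearest the root) with
  `threads` engine calls.  Each later round selects up to
  `expansion_size` poses (default: `threads`) — best scores first,
  greedily kept only if at least `diversity_rmsd` (default 1 Å,
  heavy-atom, no superposition) from every already-kept pose, backfilled
  by score — grows each by the next `b` branches, and docks each grown
  fragment with `⌈threads/m⌉` calls.  Only full-ligand poses from the
  final round are returned.

Budget accounting: one thread = one engine call per round, so an
incremental run with `T` threads and `r` rounds costs `r·T` engine calls.
Budget-matched comparisons give the multi protocol `r·T` instances and the
single protocol an exhaustiveness of `r·T·E`.

### Fragment growth

A grown rigid group is placed by rigid transplantation: the three-atom
local frame of the branch's anchor group is matched between the reference
geometry and the current pose (Kabsch), and the new group's reference
coordinates are mapped through that transform.  Anchor-frame atoms are
taken from the anchor's *own rigid group*, whose internal geometry is
torsion-invariant — this makes the transfer exact whenever that group has
three non-collinear atoms, and only approximately correct otherwise
(the search then widens across explored bonds).  Growing with
reference-geometry poses through a whole schedule reproduces the reference
coordinates to < 1e−6 Å (tested).

Frozen bonds keep the torsion values of the pose they were docked with,
not the reference values: the point of the incremental paradigm is that
earlier rounds' conformational decisions are inherited.  Consequently any
error in a frozen torsion is locked in for the rest of the run; lineage
diversity (several expanded poses per round) is the only hedge, which is
why `expansion_size` and `diversity_rmsd` matter on rugged landscapes.

Expansion-round engine calls seed one extra run from the grown pose itself
(the fragment continues from where its parent sat in the site) in addition
to the randomized runs.  This implements growth *in the binding site*;
without it the engine would have to re-discover the placement from scratch
every round, which penalizes exactly the protocol whose premise is
inherited placement.

## Built-in engine

The built-in engine is a test harness for the meta-protocols, not a
reproduction of any published scoring function.  It is charge-free and
purely geometric:

* **Score** (lower = better): for every receptor–ligand heavy-atom pair
  within 8 Å, with surface gap `s = d − (rᵢ + rⱼ)` (element radii C 1.9,
  N 1.8, O 1.7, S 2.0, P 2.1, default 1.8 Å):
  `−0.05·exp(−(s/0.5)²)` plus `0.8·s²` when `s < 0`; plus `0.8·s²` for
  intra-ligand nonbonded heavy pairs (graph distance ≥ 3 bonds) with
  `s < −0.5`.  The score is invariant under joint rigid transforms of
  receptor and ligand (tested to 1e−9).
* **Randomization**: active torsions uniform in [−180°, 180°), uniform
  random orientation (normalized Gaussian quaternion), centroid uniform in
  the box with all atoms kept inside; placements with any receptor contact
  gap below −1 Å are rejected and resampled (≤ 100 tries, then a placement
  error).
* **Search**: each run is randomize → cyclic coordinate descent (rigid
  translation/rotation plus active torsions, step halving from 2 Å / 30°
  to 0.01 Å / 0.25°, per-level convergence 1e−4, ≤ 12 cycles per level)
  → a short basin-hopping chain (`mc_hops` = 8 proposals of σ = 1.5 Å
  translation, σ = 25° rotation/torsion, re-refined at half steps,
  Metropolis-accepted at temperature 0.05 score units; the best pose along
  the chain is kept).  Translations that would push the centroid outside
  the box are rejected, so no returned pose leaves the box by more than
  the fragment radius.
* **Pooling**: poses from all runs are clustered greedily at 1 Å
  heavy-atom RMSD (best-scoring representative kept) and filtered to at
  most `num_modes` (default 25) within `energy_range` (default 10) of the
  best score.

Per-run search strength is a deliberate compromise: strong enough that a
low-dimensional problem (a fragment, or a single-atom probe) is solved
reliably — the engine lands within 0.5 Å of a brute-force 0.25 Å grid
optimum on the shell fixture — yet weak enough that whole-ligand
redocking of multi-DoF ligands usually fails in a single call, which is
the premise of the meta-protocols under study.  Determinism: every run's
RNG derives from `(seed, run_index)`; identical configs give bitwise
identical pools.  The scoring/refinement kernels are Numba-compiled, with
a NumPy reference implementation tested for equality.

An external Vina-compatible binary can replace the built-in engine
(`dock_external`): inputs are written as PDBQT, the standard
receptor/ligand/box/exhaustiveness/num_modes/energy_range/seed flags are
passed, and multi-MODEL PDBQT output is parsed back into a pool.

## Structure preparation

`prepare_complex` applies the standard redocking recipe: drop waters
(HOH/WAT/H2O/DOD), keep the first model and the first matching ligand
instance (ambiguous selectors matching several species are an error, and
other copies of the ligand are discarded entirely), drop lone single-atom
het residues (stray ions), strip hydrogens whose nearest heavy atom is
carbon while keeping polar hydrogens (on N/O/S), and build the docking box
as the ligand bounding box padded by 5 Å per side (overridable).  Partial
charges are computed with RDKit's Gasteiger implementation when the ligand
sanitizes; otherwise they default to 0.0 with a warning — the built-in
score is charge-free, so this affects only the external-engine path.
"Removing lone atoms" is interpreted as dropping single-atom het residues;
the preparation convention this mirrors does not define the term exactly.

Rotatable bonds follow the AutoDockTools-style convention: single,
acyclic (bridge) bonds, both ends heavy with at least one further heavy
neighbor, excluding amide C–N bonds (detected as a C–N bond whose carbon
carries a terminal oxygen).  The torsion-tree root defaults to the rigid
group with the most heavy atoms (ties: lowest minimum atom serial);
branches are ordered breadth-first from the root.

## Synthetic study conditions

The fixtures are abstract heavy-atom constructs, not chemically valid
molecules; the engine score and all meta-algorithms operate on geometry
plus the bond graph only, so nothing more is required.

* **Ligands**: rigid groups are 3-atom triangles (their internal bonds are
  cyclic, hence never rotatable); every inter-group bond is rotatable by
  construction, so the requested DoF count is exact (a generation-time
  gate re-runs the detector).  Growth is peptide-like — mostly chain
  extension with occasional short branches — with 1.5 Å bonds and
  self-avoidance chosen so the reference conformation carries no internal
  clash penalty.  Atom count is 3·(N+1).
* **Pockets**: receptor pseudo-atoms are molded at the exact contact
  distance (3.8 Å, C–C) around the planted pose, graded by burial — atoms
  near the torsion-tree root get up to 4 contacts, peripheral atoms 1 —
  with all contact directions kept out of an approach corridor (default
  half-angle 70°) oriented from the anchor toward the periphery.  This
  yields a buried, anchor-driven groove that is concave but enterable,
  the regime in which incremental docking is claimed to help.  After
  molding, the pose is settled by a fine-step refinement and verified to
  be a local score minimum under ±0.25 Å translations and ±2°
  rotations/torsions (regenerated with a derived seed otherwise).
* **Box**: planted-complex boxes pad the ligand bounding box by 5 Å.

What passing tests on these fixtures do *not* show: chemistry (no
electrostatics, protonation, solvent, or real torsion potentials), receptor
flexibility, crystallographic symmetry, or the absolute RMSD levels
reachable on real complexes with a production engine.  The fixtures test
the *meta*-algorithms — scheduling, growth, freezing, pooling, seeding,
evaluation — under a score whose global minimum is known by construction.

## Experiment sizes

The protocol comparison uses the incremental protocol's published-default
thread count (24) with 3 rounds and 2 new bonds per round (engine
exhaustiveness 1, i.e. 4 runs per call), giving a 72-call budget matched
by a 72-instance multi protocol and a single call at exhaustiveness 72.
The reproduction script runs 3 planted complexes (6–10 DoFs) × 4 master
seeds and reports per-protocol median top-RMSD and success rates; the
acceptance test uses the same grid at a fixed seed base.  These sizes keep a full run
in the ten-minute range on one CPU while the medians remain stable enough
to express the protocol ordering; larger grids sharpen the estimates but
do not change the machinery being exercised.

## Numerical choices

* Sample (n−1) standard deviation for replicate statistics; 0 for n = 1.
* Ties in `top_rmsd` break by better score then pose index; in
  `top_scoring` by lower reference RMSD (when a reference is given) then
  pose index — deterministic either way.
* RMSD is plain heavy-atom, fixed-correspondence: no symmetry correction
  for chemically equivalent atoms (a conservative choice; symmetric
  ligands would score slightly pessimistically).  A mask argument allows
  backbone-only variants, unused by default.
* PDB/PDBQT coordinates are written at 1e−3 Å precision; round-trip tests
  use that tolerance.
* Seeds: multi instances use `master_seed + i`; expansion lineages use a
  stable hash of (master seed, round, lineage, call), all below 2³¹.

## Known limitations

* The incremental advantage depends on lineage quality: a frozen torsion
  error cannot be repaired later, so on landscapes where fragment poses
  score degenerately the incremental protocol only ties the pooled one.
* `expansion_size`/`diversity_rmsd` are exposed but uncalibrated beyond
  the defaults; no claim is made that they are optimal.
* The external-engine adapter is smoke-tested against a scripted stand-in
  binary; it has not been validated here against a real installation.
* `prepare_complex` does not predict protonation states or expand
  crystallographic symmetry, and bond perception is distance-based.
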