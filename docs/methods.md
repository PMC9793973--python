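# Methods

## Model and scope

`pocketdesign` treats binding-pocket design as a discrete combinatorial
optimisation over a fixed backbone.  The system is partitioned into a
**fixed scaffold** (all backbone atoms plus the complete side chains of
non-design residues) and **variable groups**: at each design position the
side chain beyond Cα (CB and outward), and for the ligand a set of rigid
poses.  Only the bound state is evaluated; there is no unbound-state
ensemble, no entropy model, and no solvation term.  Backbone flexibility,
loop remodelling and ligand conformer generation are out of scope —
conformers are inputs.

Assumptions worth stating explicitly:

* side chains occupy discrete library conformations (no continuous
  minimisation — deliberately, since post-hoc rotamer minimisation biases
  designs toward bulky residues by letting clashes relax);
* the ligand is rigid within a pose; flexibility enters only through the
  input conformer ensemble and the pose grid;
* all energies are strictly pairwise-decomposable, which holds exactly
  for the non-bonded forms used here.

## Energy model

**Packing track** (protein–protein, kcal/mol): 12-6 Lennard-Jones,
`E = ε[(r_min/r)¹² − 2(r_min/r)⁶]` with Lorentz–Berthelot-style
combination (`r_min = r_i + r_j` from per-atom half-minima,
`ε = √(ε_i ε_j)`), plus Coulomb `E = k q_i q_j / r` with
`k = 332.0636 kcal·Å/(mol·e²)`.  Atom pairs separated by one or two
bonds are excluded and three-bond pairs are scaled (LJ × 0.5, Coulomb
× 1/1.2, the AMBER convention); with rigid backbones these rules bind
only across the Cα/Cβ cut of a rotamer's own residue, and the exclusion
map is derived in closed form from the side chain's bond distance to Cβ.
No distance cutoff is applied to packing terms: exactness of the
decomposition is worth more than speed at the system sizes this package
targets (an optional cutoff could be added for large pockets).

**Binding track** (protein–ligand, score units): an empirical
Vina-style interaction score over heavy-atom pairs within 8 Å, using the
surface distance `d = r − (R_i + R_j)` (per-atom van der Waals radii):
`gauss1 = exp(−(d/0.5)²)`, `gauss2 = exp(−((d−3)/2)²)`, `repulsion = d²`
for `d < 0`, a hydrophobic ramp (1 below 0.5 Å, 0 above 1.5 Å) for
hydrophobic–hydrophobic pairs, and an H-bond ramp (1 below −0.7 Å, 0
above 0 Å) for donor–acceptor pairs.  Default weights are the published
Vina values (−0.035579, −0.005156, 0.840245, −0.035069, −0.587439); they
live in configuration, not code, so alternative weight sets (e.g.
Vinardo-style) are a config change.  This is an interaction *rescore*:
no rotatable-bond/entropy normalisation is applied.  Atom classes
(hydrophobic / H-bond donor / acceptor) come from the parameter table
rather than cheminformatic perception, keeping the scoring core free of
chemistry heuristics.

**Objective.** Binding entries are multiplied by `binding_scale`
(default 50) when assembled into the solver objective:
`total = packing + 50 × binding_raw`.  Reports always carry both the raw
and the scaled binding energy, so rankings can be read on either scale.

## Sampling

* **Flexible shell** — a residue is flexible when any side-chain heavy
  atom lies within `flex_radius` (default 4 Å) of a ligand heavy atom or
  a mutation position's Cα.  The candidate residue's *side-chain* atoms
  define the distance (the shell is about side-chain contact); this is a
  package choice where conventions differ, and it is configurable.
  Residues at segment termini (chain ends or peptide-bond breaks > 2 Å)
  and cysteines in disulfide bridges (S–S ≤ 2.3 Å) are kept static.
  Prolines and glycines are never selected by distance.
* **Rotamers** — side chains are rebuilt from ideal-geometry templates
  (generic sp³/sp²/aromatic bond lengths and angles) attached at the
  N/Cα/C backbone frame; every chi torsion is set exactly during NeRF
  placement, so chi values are reproduced to machine precision.  Rebuilt
  rotamers are heavy-atom only; in the bundled parameterisations,
  hydrogen contributions are folded into heavy-atom parameters
  (united-atom style).  The library format is backbone-dependent
  (phi/psi bins, nearest-bin-centre lookup, ties toward −180°, default
  bin width 10°) with `*` wildcard bins for backbone-independent
  libraries.
* **Poses** — each conformer is rotated intrinsically about its
  heavy-atom centroid in fixed axis order x→y→z and then translated, on
  the Cartesian product of per-axis value lists `{−max, …, 0, …, +max}`.
  Defaults: ±20° and ±0.5 Å with one step per side (3 values/axis,
  729 poses per conformer); step sizes are configurable, including finer
  grids.  Output order is lexicographic in (conformer, rotation,
  translation), so ensembles are reproducible.
* **Pruning** — rotamers and poses with Lennard-Jones energy ≥ 100
  kcal/mol against the fixed scaffold are removed before tables are
  computed.  The pruning energy is LJ-only ("vdW"), not
  LJ+electrostatics; a pure threshold filter, verified against
  brute-force pair loops in the tests.  A position (or the pose set)
  emptying out is a hard error rather than a silent degradation.

## Solver

The GMEC ILP uses binary node variables `x[p,r]` and binary edge
variables `y[p,r,q,s]` with the flow constraints
`Σ_s y[p,r,q,s] = x[p,r]` per partner; the ligand is one extra position
whose candidates are poses and whose self energies are the scaled
pose–scaffold scores, mirroring the symmetric treatment of rotamers and
poses everywhere else.  The backend is HiGHS via `scipy.optimize.milp`,
which proves optimality.  Determinism under degenerate optima is
enforced by a secondary pass: after the optimal value is known,
positions are fixed in order, trying candidate indices ascending and
keeping the first that preserves the optimum (tolerance
`1e-7·(1+|V*|)`), which yields the lexicographically smallest optimal
index vector — the same tie-break the brute-force oracle applies by
scanning assignments in C order.  N-best enumeration re-solves with
exclusion cuts (`Σ_p x[p, chosen_p] ≤ n_positions − 1` per previous
solution); requesting more solutions than exist returns all of them with
a warning.  Instances up to 10⁶ assignments can be brute-forced, which
the test-suite uses as an independent oracle throughout.

## Synthetic systems

The toy generator builds chemically naive but geometrically valid
pockets: 5+ residues on ideal backbone geometry (α-helix −57/−47,
β-strand −120/+120, or a gently curved "ring pocket"), two interior
design positions (one mutable), a 2–5 atom rigid ligand placed outward
along the first design residue's Cα→Cβ vector, per-atom parameter tables
with element-level LJ radii and small seeded charge jitter (backbone
charges shared across amino acids so mutations never alter fixed-scaffold
parameters), and a small chi library.  Two properties are guaranteed by
construction and checked at generation time: at least one library
rotamer clashes with the scaffold (a decoy found by scanning chi space
for maximal scaffold LJ — generation fails loudly if nothing reaches the
pruning threshold), and at least one rotamer makes a favourable
(negative) empirical-score contact with the ligand.  Everything is
byte-deterministic given the seed.

What the toys do *not* emulate: real protonation states, realistic
charge distributions, solvent, crystallographic side-chain diversity, or
ligand chemistry.  Passing tests therefore demonstrate the correctness
of the machinery — decomposition, pruning, optimisation, evaluation
operators — not predictive accuracy on real proteins, which depends on
the supplied force-field parameters, rotamer library and scoring
weights.

## Numerical choices

* Units: Å, kcal/mol, degrees, elementary charges — package-wide.
* PDB parsing: `ATOM`/`HETATM` only; alternate locations resolved to
  highest occupancy (ties: first encountered); insertion codes and
  multi-model files rejected.  Written coordinates carry the format's
  1e-3 Å precision; round-trip energy agreement is limited accordingly
  (steep contacts amplify coordinate rounding).
* Rotamer-library bin lookup: nearest bin centre on the wrapped angle
  wheel; exact midpoints round toward −180°.
* Energy tables are written as plain CSV (17 significant digits —
  lossless for doubles) with a JSON manifest.
* Pair-energy blocks are embarrassingly parallel; results are assembled
  in block order, so tables are bit-identical for any worker count.
* Stage caching: each pipeline stage hashes its relevant configuration
  slice, its input files and its upstream stage hashes; a stage is
  skipped iff the stored manifest hash matches, so changing a threshold
  invalidates exactly the stages downstream of it.
* Test problem sizes: exhaustive-enumeration checks (decomposition
  conservation over every assignment of 50 seeded systems) run on
  translation-only pose grids (27 poses/conformer) — the identities
  being verified are grid-independent, and the default 729-pose grid is
  exercised separately where grid combinatorics are the point.

## Limitations

* Heavy-atom rotamer rebuilding: explicit polar hydrogens (and thus
  orientation-dependent H-bond geometry) are not modelled; the H-bond
  term depends on donor/acceptor class and heavy-atom distance only.
* Proline is never sampled (ring closure), and design positions need
  both backbone neighbours unless the library is backbone-independent.
* The shipped ideal-geometry templates cover 14 amino acids (GLY, ALA,
  SER, CYS, THR, VAL, LEU, ILE, ASP, ASN, MET, GLU, LYS, PHE); extending
  to the rest is a data addition, not a code change.
* Binding affinities are relative scores for ranking variants, not
  physical free energies.
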