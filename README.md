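# pocketdesign

Computational design of small-molecule binding pockets in proteins.
Given a prepared (protonated, parameterised) protein scaffold, a ligand
conformer ensemble placed in the pocket, and a set of design positions
with allowed mutations, `pocketdesign` samples discrete side-chain
rotamers and rigid ligand poses, decomposes the pocket energy into self
and pairwise interaction terms, and finds the **global minimum energy
conformation (GMEC)** — one rotamer per position plus one ligand pose —
by integer linear programming, with proven optimality.  It is aimed at
protein engineers who want exact, inspectable answers on discrete design
search spaces rather than stochastic sampling.

## Method

The variable system is a set of positions `p` with candidate sets
(rotamers; the ligand is one extra position whose candidates are poses).
Energies are decomposed into

* `E_self(p, r)` — candidate `r` at position `p` against the fixed
  scaffold,
* `E_pair(p, r, q, s)` — between candidates at two positions,

on two tracks: protein–protein terms use a 12-6 Lennard-Jones plus
Coulomb force field (parameters supplied per atom), and protein–ligand
terms use an empirical AutoDock-Vina-style scoring function (two
Gaussians, quadratic repulsion, hydrophobic and H-bond ramps on the
atom-surface distance).  Binding-track entries are multiplied by a
configurable scale (default 50) in the objective so that the empirical
score competes with force-field packing energies.  Because every term is
strictly pairwise, the decomposition is exact: the table sum for any
assignment equals the directly evaluated energy of the assembled
structure.

The GMEC is found with the classic side-chain-positioning ILP: binary
node variables `x[p,r]`, binary edge variables `y[p,r,q,s]`, constraints
`Σ_r x[p,r] = 1` and `Σ_s y[p,r,q,s] = x[p,r]`, objective
`min Σ self·x + Σ pair·y` (HiGHS backend via SciPy).  Ties are broken
deterministically (lexicographically smallest index vector), N-best
solutions are enumerated with exclusion cuts, and an exhaustive
brute-force oracle cross-checks the solver on every desk-scale instance.

Before table computation, rotamers and poses whose Lennard-Jones energy
against the fixed scaffold is ≥ 100 kcal/mol are pruned.  Flexible
positions are selected within 4 Å of the ligand or of a mutation
position's Cα; segment termini and disulfide-bridged cysteines stay
static.  Poses are generated on a systematic grid, by default ±20° about
each axis and ±0.5 Å along each direction (3 values per axis, 729 poses
per conformer).

## Worked example

Every input a design needs — scaffold PDB, ligand SDF, per-atom
parameter TSVs, rotamer library TSV, config — can be generated as a
deterministic toy system, so the whole pipeline runs without external
data:

```python
from pocketdesign import ToySystemSpec, make_toy_system, DesignProject

paths = make_toy_system(ToySystemSpec(seed=7), "toy_project")
project = DesignProject(paths["config"])
solutions = project.run_all()
kept = project._rotamer_set.kept_rotamers()
for rank, sol in enumerate(solutions, start=1):
    aas = [kept[p][r].aa for p, r in enumerate(sol.rotamer_choice)]
    print(f"solution {rank}: residues {'-'.join(aas)} pose {sol.pose_choice} "
          f"total {sol.total_energy:.4f} packing {sol.packing_energy:.4f} "
          f"binding {sol.binding_energy_raw:.4f}")
```

prints

```
solution 1: residues SER-SER pose 107 total 62.6542 packing 82.6523 binding -0.4000
solution 2: residues SER-SER pose 188 total 62.8489 packing 82.6523 binding -0.3961
solution 3: residues SER-SER pose 26 total 63.9019 packing 82.6523 binding -0.3750
```

The two design positions both choose serine (position 1 was allowed to
mutate LEU→SER); `total = packing + 50 × binding`, so the three ranked
solutions differ only in ligand pose, trading a slightly different
empirical binding score (in Vina-style score units; more negative is
better) against the same packing energy (kcal/mol).  Outputs land in
`toy_project/output/`: per-stage manifests (stages are skipped on re-run
when their input hashes match), energy tables as CSV, ranked solutions
as JSON, designed structures as PDB, and text/HTML reports with
per-term energy breakdowns.

The same pipeline is available from the shell:

```bash
pocketdesign fixtures make-system --seed 7 --out toy_project
pocketdesign solve toy_project/config.yaml
pocketdesign report toy_project/config.yaml
```

with subcommands `prepare-pocket`, `sample-rotamers`, `sample-poses`,
`compute-energies`, `solve`, `report`, `evaluate-pair` (mutant-pair
affinity ranking) and `rmsd` (backbone-superposed side-chain heavy-atom
RMSD), plus `--workers` for parallel energy blocks and `--force` to
ignore cached stages.

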