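"""Global minimum energy conformation (GMEC) search.

The decomposed design problem — pick one rotamer per position and one
ligand pose minimising the sum of self and pairwise table entries — is
solved exactly with the classic side-chain-positioning integer linear
program: binary node variables x[p,r] select candidates, binary edge
variables y[p,r,q,s] select interacting pairs, and flow constraints tie
edges to their endpoints.  The ligand is encoded as one extra "position"
whose candidates are the poses and whose self energies are the (scaled)
pose-scaffold binding scores, which mirrors how poses and rotamers are
treated symmetrically throughout.

The backend is HiGHS via :func:`scipy.optimize.milp`, which proves
optimality.  Because MILP backends are otherwise free to return any
optimum, ties are broken deterministically: among all optimal
assignments, the lexicographically smallest index vector
(rotamer indices in position order, then the pose index) is returned,
enforced by a secondary pass that fixes candidates position by position.

:func:`brute_force_gmec` enumerates every assignment and serves as the
independent oracle; it applies the same tie-break by construction
(first minimum in C scan order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .energy import EnergyTables

__all__ = [
    "Solution",
    "ILPModel",
    "build_ilp",
    "solve_gmec",
    "brute_force_gmec",
    "brute_force_best",
    "enumerate_best",
]

MAX_BRUTE_FORCE = 1_000_000


@dataclass
class Solution:
    """One design solution: per-position rotamer indices plus a pose index.

    Indices refer to the kept (post-pruning) candidate lists.  Energies
    satisfy total = packing + binding_scale * binding_raw.
    """

    rotamer_choice: tuple[int, ...]
    pose_choice: int
    total_energy: float
    packing_energy: float
    binding_energy_raw: float
    binding_energy_scaled: float

    @property
    def index_vector(self) -> tuple[int, ...]:
        return (*self.rotamer_choice, self.pose_choice)

    @classmethod
    def from_assignment(
        cls, tables: EnergyTables, rotamer_choice: tuple[int, ...], pose_choice: int
    ) -> "Solution":
        total, packing, binding = tables.assignment_energy(rotamer_choice, pose_choice)
        return cls(
            rotamer_choice=tuple(int(r) for r in rotamer_choice),
            pose_choice=int(pose_choice),
            total_energy=total,
            packing_energy=packing,
            binding_energy_raw=binding,
            binding_energy_scaled=binding * tables.binding_scale,
        )


def _extended_tables(tables: EnergyTables):
    """Candidate counts, self costs and pair costs with the ligand as the
    last position (binding entries pre-scaled)."""
    counts = [*tables.n_rotamers, tables.n_poses]
    lig = len(counts) - 1
    selfs = [np.asarray(v, float) for v in tables.self_packing]
    selfs.append(tables.binding_scale * np.asarray(tables.lig_self_binding, float))
    pairs: dict[tuple[int, int], np.ndarray] = {
        k: np.asarray(m, float) for k, m in tables.pair_packing.items()
    }
    for p, m in enumerate(tables.lig_pair_binding):
        pairs[(p, lig)] = tables.binding_scale * np.asarray(m, float).T  # (n_rot, n_pose)
    return counts, selfs, pairs


@dataclass
class ILPModel:
    """Assembled node/edge ILP instance."""

    counts: list[int]
    c: np.ndarray
    a_eq: sparse.csr_matrix
    b_eq: np.ndarray
    x_offset: list[int]  # variable index of x[p,0]
    n_node_vars: int
    n_vars: int
    edge_index: dict[tuple[int, int], int]  # (p,q) -> first y var of that pair

    def x_index(self, p: int, i: int) -> int:
        return self.x_offset[p] + i

    def export_lp(self, path) -> None:
        """Write the instance in CPLEX LP format (debugging aid)."""
        names = [None] * self.n_vars
        for p, off in enumerate(self.x_offset):
            for i in range(self.counts[p]):
                names[off + i] = f"x_{p}_{i}"
        for (p, q), base in self.edge_index.items():
            k = 0
            for i in range(self.counts[p]):
                for j in range(self.counts[q]):
                    names[base + k] = f"y_{p}_{i}_{q}_{j}"
                    k += 1
        lines = ["Minimize", " obj: " + " + ".join(
            f"{self.c[v]:.17g} {names[v]}" for v in range(self.n_vars) if self.c[v] != 0
        ), "Subject To"]
        a = self.a_eq.tocoo()
        rows: dict[int, list[str]] = {}
        for r, cix, val in zip(a.row, a.col, a.data):
            rows.setdefault(r, []).append(f"{val:+.17g} {names[cix]}")
        for r in range(self.a_eq.shape[0]):
            lines.append(f" c{r}: " + " ".join(rows.get(r, [])) + f" = {self.b_eq[r]:.17g}")
        lines.append("Binary")
        lines.append(" " + " ".join(names))
        lines.append("End")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def build_ilp(tables: EnergyTables) -> ILPModel:
    """Assemble node variables, edge variables and flow constraints."""
    counts, selfs, pairs = _extended_tables(tables)
    n_pos = len(counts)
    x_offset = []
    n = 0
    for p in range(n_pos):
        if counts[p] < 1:
            raise ValueError(f"position {p} has no candidates")
        x_offset.append(n)
        n += counts[p]
    n_node = n
    edge_index: dict[tuple[int, int], int] = {}
    for (p, q) in sorted(pairs):
        edge_index[(p, q)] = n
        n += counts[p] * counts[q]

    c = np.zeros(n)
    for p in range(n_pos):
        c[x_offset[p] : x_offset[p] + counts[p]] = selfs[p]
    for (p, q), base in edge_index.items():
        c[base : base + counts[p] * counts[q]] = pairs[(p, q)].ravel()

    rows, cols, data, b = [], [], [], []
    r = 0
    for p in range(n_pos):  # one candidate per position
        for i in range(counts[p]):
            rows.append(r)
            cols.append(x_offset[p] + i)
            data.append(1.0)
        b.append(1.0)
        r += 1
    for (p, q), base in edge_index.items():
        nq = counts[q]
        for i in range(counts[p]):  # sum_j y[p,i,q,j] = x[p,i]
            for j in range(nq):
                rows.append(r)
                cols.append(base + i * nq + j)
                data.append(1.0)
            rows.append(r)
            cols.append(x_offset[p] + i)
            data.append(-1.0)
            b.append(0.0)
            r += 1
        for j in range(nq):  # sum_i y[p,i,q,j] = x[q,j]
            for i in range(counts[p]):
                rows.append(r)
                cols.append(base + i * nq + j)
                data.append(1.0)
            rows.append(r)
            cols.append(x_offset[q] + j)
            data.append(-1.0)
            b.append(0.0)
            r += 1
    a_eq = sparse.csr_matrix((data, (rows, cols)), shape=(r, n))
    return ILPModel(
        counts=counts,
        c=c,
        a_eq=a_eq,
        b_eq=np.array(b),
        x_offset=x_offset,
        n_node_vars=n_node,
        n_vars=n,
        edge_index=edge_index,
    )


def _milp_solve(model: ILPModel, lb: np.ndarray, ub: np.ndarray, cuts: list):
    constraints = [LinearConstraint(model.a_eq, model.b_eq, model.b_eq)]
    n_pos = len(model.counts)
    for cut_vars in cuts:
        row = sparse.csr_matrix(
            (np.ones(len(cut_vars)), (np.zeros(len(cut_vars), int), cut_vars)),
            shape=(1, model.n_vars),
        )
        constraints.append(LinearConstraint(row, -np.inf, n_pos - 1))
    res = milp(
        c=model.c,
        constraints=constraints,
        integrality=np.ones(model.n_vars),
        bounds=Bounds(lb, ub),
    )
    if res.status == 2:  # infeasible
        return None
    if not res.success:
        raise RuntimeError(f"MILP backend failed: status {res.status} ({res.message})")
    assignment = []
    for p, off in enumerate(model.x_offset):
        xs = res.x[off : off + model.counts[p]]
        assignment.append(int(np.argmax(xs)))
    return float(res.fun), tuple(assignment)


def _solve_lexicographic(model: ILPModel, cuts: list):
    """Optimal value with deterministic lexicographic tie-break.

    After the initial solve establishes the optimal value, positions are
    fixed one by one: for each position, candidate indices below the
    incumbent are tried in ascending order and accepted if the optimum is
    still attainable, yielding the lexicographically smallest optimal
    index vector.
    """
    lb = np.zeros(model.n_vars)
    ub = np.ones(model.n_vars)
    first = _milp_solve(model, lb, ub, cuts)
    if first is None:
        return None
    best_val, assignment = first
    tol = 1e-7 * (1.0 + abs(best_val))
    assignment = list(assignment)
    for p in range(len(model.counts)):
        if model.counts[p] == 1:
            continue
        chosen = assignment[p]
        for cand in range(chosen):
            trial_lb, trial_ub = lb.copy(), ub.copy()
            off = model.x_offset[p]
            trial_ub[off : off + model.counts[p]] = 0.0
            trial_lb[off + cand] = 1.0
            trial_ub[off + cand] = 1.0
            res = _milp_solve(model, trial_lb, trial_ub, cuts)
            if res is not None and res[0] <= best_val + tol:
                chosen = cand
                assignment = list(res[1])
                break
        off = model.x_offset[p]
        ub[off : off + model.counts[p]] = 0.0
        lb[off + chosen] = 1.0
        ub[off + chosen] = 1.0
        assignment[p] = chosen
    return best_val, tuple(assignment)


def solve_gmec(tables: EnergyTables) -> Solution:
    """Provably optimal assignment, deterministic under ties."""
    model = build_ilp(tables)
    res = _solve_lexicographic(model, cuts=[])
    if res is None:
        raise RuntimeError("ILP reported infeasible on a well-formed instance")
    _, assignment = res
    return Solution.from_assignment(tables, assignment[:-1], assignment[-1])


def _energy_tensor(tables: EnergyTables) -> np.ndarray:
    counts, selfs, pairs = _extended_tables(tables)
    n_pos = len(counts)
    shape = tuple(counts)
    e = np.zeros(shape)
    for p in range(n_pos):
        sh = [1] * n_pos
        sh[p] = counts[p]
        e = e + selfs[p].reshape(sh)
    for (p, q), m in pairs.items():
        sh = [1] * n_pos
        sh[p] = counts[p]
        sh[q] = counts[q]
        e = e + m.reshape(sh)
    return e


def brute_force_gmec(tables: EnergyTables) -> Solution:
    """Exhaustive-enumeration oracle with the same tie-break as the ILP."""
    counts = [*tables.n_rotamers, tables.n_poses]
    size = int(np.prod(counts))
    if size > MAX_BRUTE_FORCE:
        raise ValueError(f"instance too large for brute force ({size} assignments)")
    e = _energy_tensor(tables)
    flat = int(np.argmin(e))  # first occurrence in C order = lexicographic min
    assignment = np.unravel_index(flat, e.shape)
    return Solution.from_assignment(tables, tuple(int(i) for i in assignment[:-1]), int(assignment[-1]))


def brute_force_best(tables: EnergyTables, n: int) -> list[Solution]:
    """The n lowest-energy assignments by exhaustive sorted enumeration."""
    counts = [*tables.n_rotamers, tables.n_poses]
    size = int(np.prod(counts))
    if size > MAX_BRUTE_FORCE:
        raise ValueError(f"instance too large for brute force ({size} assignments)")
    e = _energy_tensor(tables)
    order = np.argsort(e.ravel(), kind="stable")[: min(n, size)]
    out = []
    for flat in order:
        assignment = np.unravel_index(int(flat), e.shape)
        out.append(
            Solution.from_assignment(
                tables, tuple(int(i) for i in assignment[:-1]), int(assignment[-1])
            )
        )
    return out


def enumerate_best(tables: EnergyTables, n: int) -> list[Solution]:
    """The n best distinct assignments in non-decreasing energy order.

    Each found assignment is forbidden with an exclusion cut (the sum of
    its matched node variables must drop by at least one) and the ILP is
    re-solved; ties within equal-energy groups follow the lexicographic
    order.  If fewer than n assignments exist, all are returned with a
    warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    model = build_ilp(tables)
    cuts: list[list[int]] = []
    solutions: list[Solution] = []
    for _ in range(n):
        res = _solve_lexicographic(model, cuts)
        if res is None:
            warnings.warn(
                f"only {len(solutions)} assignments exist; requested {n}"
            )
            break
        _, assignment = res
        solutions.append(Solution.from_assignment(tables, assignment[:-1], assignment[-1]))
        cuts.append([model.x_index(p, i) for p, i in enumerate(assignment)])
    return solutions
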