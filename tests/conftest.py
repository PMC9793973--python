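"""Shared fixtures: toy systems, parameter helpers, independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
import yaml

from pocketdesign.fixtures import ToySystemSpec, make_toy_system
from pocketdesign.pipeline import DesignProject


def make_atom(
    name="C1",
    element="C",
    coords=(0.0, 0.0, 0.0),
    charge=0.0,
    rmin_half=1.9,
    epsilon=0.1,
    vdw_radius=1.9,
    atom_class="none",
):
    from pocketdesign.model import Atom

    a = Atom(name=name, element=element, coords=np.asarray(coords, float), vdw_radius=1.0)
    a.charge = charge
    a.lj_rmin_half = rmin_half
    a.lj_epsilon = epsilon
    a.vdw_radius = vdw_radius
    a.atom_class = atom_class
    return a


@pytest.fixture(scope="session")
def toy_paths(tmp_path_factory):
    """A default toy design project on disk (seed 7)."""
    out = tmp_path_factory.mktemp("toy7")
    return make_toy_system(ToySystemSpec(seed=7), out)


@pytest.fixture(scope="session")
def solved_project(toy_paths):
    """The toy project run through the full pipeline."""
    project = DesignProject(toy_paths["config"])
    project.run_all()
    return project


def reduced_grid_project(tmp_path, seed: int, **config_overrides) -> DesignProject:
    """Toy project with a translation-only pose grid (27 poses/conformer).

    Used where exhaustive enumeration over all assignments is required;
    the decomposition/solver properties under test are grid-size
    independent.
    """
    out = tmp_path / f"toy{seed}"
    paths = make_toy_system(ToySystemSpec(seed=seed), out)
    cfg = yaml.safe_load(paths["config"].read_text())
    cfg["rot_max"] = 0.0
    cfg.update(config_overrides)
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return DesignProject(paths["config"])


# ---------------------------------------------------------------------------
# independent whole-system energy oracle
# ---------------------------------------------------------------------------

def direct_system_energy(pocket, chosen_rotamers, pose, params, weights, binding_scale):
    """Direct inter-group energy of the assembled system.

    Independent of the table machinery: concatenates all atoms with group
    labels and evaluates the force-field sum over protein group pairs and
    the empirical score of the pose against all protein atoms in one
    masked pass over the full pair matrix.
    """
    from pocketdesign.energy import rotamer_scaffold_exclusions, _scaffold_label_index

    groups = [pocket.fixed_scaffold.atoms] + [r.atoms for r in chosen_rotamers]
    labels = np.concatenate(
        [np.full(len(g), gi) for gi, g in enumerate(groups)]
    )
    atoms = [a for g in groups for a in g]
    n = len(atoms)
    coords = np.array([a.coords for a in atoms])
    charge = np.array([a.charge for a in atoms])
    rmin_h = np.array([a.lj_rmin_half for a in atoms])
    eps = np.array([a.lj_epsilon for a in atoms])

    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    inter = labels[:, None] != labels[None, :]

    lj_scale = np.ones((n, n))
    coul_scale = np.ones((n, n))
    offset = len(groups[0])
    for gi, rot in enumerate(chosen_rotamers):
        if not rot.atoms:
            offset += 0
            continue
        lbl = _scaffold_label_index(pocket, pocket.position_indices[gi])
        excl = rotamer_scaffold_exclusions(rot.aa, [a.name for a in rot.atoms], lbl)
        for (i, j), kind in excl.items():
            gi_i = offset + i
            if kind == "excluded":
                lj_scale[gi_i, j] = lj_scale[j, gi_i] = 0.0
                coul_scale[gi_i, j] = coul_scale[j, gi_i] = 0.0
            else:
                lj_scale[gi_i, j] = lj_scale[j, gi_i] = params.lj_14_scale
                coul_scale[gi_i, j] = coul_scale[j, gi_i] = params.coulomb_14_scale
        offset += len(rot.atoms)

    r_min = rmin_h[:, None] + rmin_h[None, :]
    e_mat = np.sqrt(eps[:, None] * eps[None, :])
    q6 = (r_min / d) ** 6
    lj = e_mat * (q6 * q6 - 2.0 * q6) * lj_scale
    coul = params.coulomb_constant * charge[:, None] * charge[None, :] / d * coul_scale
    packing = float(((lj + coul) * inter).sum() / 2.0)

    # empirical score: pose vs every protein heavy atom (vectorised
    # straight from the term definitions, one flat pass over pairs)
    prot_heavy = [a for a in atoms if not a.is_hydrogen]
    lig_heavy = [a for a in pose.atoms if not a.is_hydrogen]
    pc = np.array([a.coords for a in prot_heavy])
    lc = np.array([a.coords for a in lig_heavy])
    pr_v = np.array([a.vdw_radius for a in prot_heavy])
    lr_v = np.array([a.vdw_radius for a in lig_heavy])
    p_cls = np.array([a.atom_class for a in prot_heavy])
    l_cls = np.array([a.atom_class for a in lig_heavy])
    r = np.sqrt(((lc[:, None, :] - pc[None, :, :]) ** 2).sum(-1))
    s = r - (lr_v[:, None] + pr_v[None, :])
    term = weights.w_gauss1 * np.exp(-((s / 0.5) ** 2))
    term = term + weights.w_gauss2 * np.exp(-(((s - 3.0) / 2.0) ** 2))
    term = term + weights.w_repulsion * np.where(s < 0, s * s, 0.0)
    phob = (l_cls[:, None] == "hydrophobic") & (p_cls[None, :] == "hydrophobic")
    term = term + weights.w_hydrophobic * np.clip((1.5 - s) / 1.0, 0.0, 1.0) * phob
    dapair = ((l_cls[:, None] == "hbond_donor") & (p_cls[None, :] == "hbond_acceptor")) | (
        (l_cls[:, None] == "hbond_acceptor") & (p_cls[None, :] == "hbond_donor")
    )
    term = term + weights.w_hbond * np.clip((0.0 - s) / 0.7, 0.0, 1.0) * dapair
    binding = float(term[r <= weights.cutoff].sum())

    return packing + binding_scale * binding, packing, binding
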