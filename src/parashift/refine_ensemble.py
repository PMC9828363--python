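"""PCS-restrained structure refinement and ensemble analytics.

The refinement engine here deliberately replaces a molecular-dynamics force
field with a harmonic geometry template (distance restraints extracted from
a reference conformer).  That is sufficient to verify the paramagnetic
restraint machinery — the flat-bottom PCS pseudo-energy, its analytic
gradients with respect to both nuclear coordinates and the metal position,
and the alternating tensor-fit / structure-minimization protocol — without
any force-field dependency.  Ensemble analytics cover all-pairs Kabsch
superposition statistics and interhelical-angle measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import PCSDataset, Structure, StructureEnsemble
from .pcs_core import DeltaChiTensor, MetalSite, PCS_PREFACTOR
from .tensor_fit import FitResult, JointFitResult, fit_position_and_tensors, q_factor

logger = logging.getLogger(__name__)


class RestraintMappingError(KeyError):
    """Restrained atoms missing from the structure."""


class NonConvergenceError(RuntimeError):
    """Iterative tensor/structure protocol failed to converge."""


# ---------------------------------------------------------------------------
# restraint containers
# ---------------------------------------------------------------------------


@dataclass
class PCSRestraintSet:
    """Multi-dataset PCS restraints sharing one metal site.

    Energy per observation: E = k · max(0, |δ_calc − δ_obs| − tol)²  — a
    flat-bottom quadratic with half-width ``tolerance`` (ppm) and force
    constant ``force_constant`` (energy·ppm⁻²).
    """

    datasets: list[PCSDataset]
    tensors: list[DeltaChiTensor]
    site: MetalSite
    force_constant: float = 1.0
    tolerance: float = 0.05

    def __post_init__(self):
        if len(self.datasets) != len(self.tensors):
            raise ValueError("need one tensor per dataset")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass
class GeometryTemplate:
    """Harmonic distance terms standing in for covalent + base-pair geometry."""

    pairs: list[tuple[tuple[int, str], tuple[int, str]]]
    targets: np.ndarray  # Å
    force_constants: np.ndarray

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=float)
        self.force_constants = np.asarray(self.force_constants, dtype=float)
        if np.any(self.targets <= 0):
            raise ValueError("target distances must be positive")

    @classmethod
    def from_structure(
        cls,
        structure: Structure,
        cutoff: float = 6.0,
        force_constant: float = 10.0,
        blocks: list[set[int]] | None = None,
        inter_block_pairs: list | None = None,
    ) -> "GeometryTemplate":
        """Extract all intra-block atom pairs within ``cutoff`` of each other.

        ``blocks`` partitions residue numbers (e.g. one block per helix);
        pairs spanning blocks are excluded so that the template constrains
        local geometry but leaves inter-helix orientation free, unless given
        explicitly in ``inter_block_pairs``.
        """
        keys = structure.atom_keys()
        coords = structure.coords
        n = len(keys)
        block_of = {}
        if blocks is not None:
            for bi, block in enumerate(blocks):
                for rn in block:
                    block_of[rn] = bi
        pairs, targets, ks = [], [], []
        d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=2)
        cut2 = cutoff**2
        for i in range(n):
            for j in range(i + 1, n):
                if d2[i, j] > cut2:
                    continue
                if blocks is not None:
                    bi = block_of.get(keys[i][0])
                    bj = block_of.get(keys[j][0])
                    if bi is None or bj is None or bi != bj:
                        continue
                pairs.append((keys[i], keys[j]))
                targets.append(np.sqrt(d2[i, j]))
                ks.append(force_constant)
        if inter_block_pairs:
            for key_a, key_b, dist, k in inter_block_pairs:
                pairs.append((tuple(key_a), tuple(key_b)))
                targets.append(dist)
                ks.append(k)
        return cls(pairs, np.array(targets), np.array(ks))


def geometry_energy_grad(structure: Structure, template: GeometryTemplate):
    """Harmonic energy Σ k (d − d₀)² and its gradient per atom."""
    try:
        ia = np.array([structure.index_of(*a) for a, _ in template.pairs])
        ib = np.array([structure.index_of(*b) for _, b in template.pairs])
    except KeyError as exc:
        raise RestraintMappingError(f"template atom missing: {exc}") from exc
    grad = np.zeros_like(structure.coords)
    if len(template.pairs) == 0:
        return 0.0, grad
    delta = structure.coords[ia] - structure.coords[ib]
    dist = np.linalg.norm(delta, axis=1)
    diff = dist - template.targets
    energy = float(template.force_constants @ diff**2)
    coef = (2.0 * template.force_constants * diff / np.maximum(dist, 1e-12))[:, None]
    np.add.at(grad, ia, coef * delta)
    np.add.at(grad, ib, -coef * delta)
    return energy, grad


# ---------------------------------------------------------------------------
# PCS pseudo-energy
# ---------------------------------------------------------------------------


def pcs_energy_grad(structure: Structure, restraints: PCSRestraintSet):
    """Flat-bottom PCS energy with analytic gradients.

    Returns (energy, gradient w.r.t. atom coordinates (n,3), gradient
    w.r.t. the site coordinates (3,)).  The total is the sum over datasets
    of independent single-dataset energies (the multi-sample contract).
    """
    site = restraints.site.as_array()
    grad_atoms = np.zeros_like(structure.coords)
    grad_site = np.zeros(3)
    energy = 0.0
    k = restraints.force_constant
    tol = restraints.tolerance
    for dataset, tensor in zip(restraints.datasets, restraints.tensors):
        missing = [
            (rn, an) for rn, an in dataset.keys() if not structure.has_atom(rn, an)
        ]
        if missing:
            raise RestraintMappingError(f"restrained atoms absent: {missing[:5]}")
        idx = np.array([structure.index_of(rn, an) for rn, an in dataset.keys()])
        obs = dataset.entries["pcs"].to_numpy(float)
        chi = tensor.as_matrix()
        d = structure.coords[idx] - site
        r2 = np.einsum("ij,ij->i", d, d)
        r = np.sqrt(r2)
        chi_d = d @ chi
        quad = np.einsum("ij,ij->i", d, chi_d)
        calc = PCS_PREFACTOR * 3.0 * quad / r**5
        diff = calc - obs
        excess = np.abs(diff) - tol
        active = excess > 0
        energy += float(k * np.sum(excess[active] ** 2))
        if not np.any(active):
            continue
        # dE/dδ, then chain rule through δ = s·3 (dᵀχd)/r⁵
        de_ddelta = np.zeros_like(diff)
        de_ddelta[active] = 2.0 * k * np.sign(diff[active]) * excess[active]
        ddelta_dd = (
            PCS_PREFACTOR
            * 3.0
            * (2.0 * chi_d / r[:, None] ** 5 - 5.0 * quad[:, None] * d / r[:, None] ** 7)
        )
        contrib = de_ddelta[:, None] * ddelta_dd
        np.add.at(grad_atoms, idx, contrib)
        grad_site -= contrib.sum(axis=0)
    return energy, grad_atoms, grad_site


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------


def total_energy_grad(
    structure: Structure,
    geometry: GeometryTemplate | None,
    restraints: PCSRestraintSet | None,
):
    energy, grad = 0.0, np.zeros_like(structure.coords)
    grad_site = np.zeros(3)
    if geometry is not None:
        e_geo, g_geo = geometry_energy_grad(structure, geometry)
        energy += e_geo
        grad += g_geo
    if restraints is not None:
        e_pcs, g_pcs, g_site = pcs_energy_grad(structure, restraints)
        energy += e_pcs
        grad += g_pcs
        grad_site += g_site
    return energy, grad, grad_site


def refine_structure(
    start: Structure,
    geometry: GeometryTemplate | None,
    restraints: PCSRestraintSet | None,
    steps: int = 500,
    step_size: float = 1e-3,
    optimize_site: bool = False,
    gtol: float = 1e-8,
) -> tuple[Structure, list[float]]:
    """Gradient minimization of geometry + PCS energy.

    Adaptive steepest descent with backtracking: a trial step is accepted
    only if the energy does not increase, so the returned energy trace is
    monotone non-increasing.  With ``optimize_site`` the metal position is a
    free variable coupled only through the PCS terms.  Returns the minimized
    structure and the per-accepted-step energy trace.
    """
    coords = start.coords.copy()
    site = restraints.site.as_array().copy() if restraints is not None else np.zeros(3)
    current = start.with_coords(coords)
    if restraints is not None:
        restraints = PCSRestraintSet(
            restraints.datasets, restraints.tensors, MetalSite.from_array(site),
            restraints.force_constant, restraints.tolerance,
        )
    energy, grad, grad_site = total_energy_grad(current, geometry, restraints)
    if not np.isfinite(energy):
        raise FloatingPointError("non-finite energy at the starting structure")
    trace = [energy]
    h = step_size
    for _ in range(steps):
        gnorm = np.linalg.norm(grad) + (np.linalg.norm(grad_site) if optimize_site else 0.0)
        if gnorm < gtol:
            break
        accepted = False
        for _try in range(30):
            new_coords = coords - h * grad
            new_site = site - h * grad_site if optimize_site else site
            trial = current.with_coords(new_coords)
            trial_restr = restraints
            if restraints is not None and optimize_site:
                trial_restr = PCSRestraintSet(
                    restraints.datasets, restraints.tensors,
                    MetalSite.from_array(new_site),
                    restraints.force_constant, restraints.tolerance,
                )
            e_new, g_new, gs_new = total_energy_grad(trial, geometry, trial_restr)
            if not np.isfinite(e_new):
                raise FloatingPointError(
                    f"energy diverged (NaN/inf) at step size {h:.2e}"
                )
            if e_new <= energy:
                coords, site = new_coords, new_site
                current, restraints = trial, trial_restr
                energy, grad, grad_site = e_new, g_new, gs_new
                trace.append(energy)
                h *= 1.5
                accepted = True
                break
            h *= 0.5
        if not accepted:
            break
    return current, trace


def _axis_angle_matrix(p: np.ndarray) -> np.ndarray:
    """Rotation matrix from an axis-angle vector (radians·axis)."""
    angle = np.linalg.norm(p)
    if angle < 1e-12:
        return np.eye(3)
    x, y, z = p / angle
    c, s = np.cos(angle), np.sin(angle)
    cross = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * cross + (1 - c) * np.outer(p / angle, p / angle)


def refine_rigid_body(
    start: Structure,
    blocks: list[set[int]],
    geometry: GeometryTemplate | None,
    restraints: PCSRestraintSet | None,
    maxiter: int = 400,
) -> tuple[Structure, list[float]]:
    """Minimize geometry + PCS energy over rigid-body moves of residue blocks.

    Each block after the first gets 6 degrees of freedom (axis-angle
    rotation about its centroid plus translation); the first block anchors
    the frame.  This is the natural minimizer for interhelical geometry:
    helices are locally stiff, so the soft degrees of freedom of a junction
    are the relative helix placements, which Cartesian steepest descent
    moves only very slowly.  Returns (structure, [E_start, E_final]).
    """
    from scipy.optimize import minimize as _minimize

    masks = [
        np.array([int(rn) in block for rn in start.residue_numbers])
        for block in blocks[1:]
    ]
    centroids = [start.coords[m].mean(axis=0) for m in masks]
    base = start.coords

    def build(params: np.ndarray) -> Structure:
        coords = base.copy()
        for k, mask in enumerate(masks):
            rot_vec = params[6 * k : 6 * k + 3]
            trans = params[6 * k + 3 : 6 * k + 6]
            rot = _axis_angle_matrix(rot_vec)
            coords[mask] = (coords[mask] - centroids[k]) @ rot.T + centroids[k] + trans
        return start.with_coords(coords)

    def objective(params: np.ndarray) -> float:
        e, _, _ = total_energy_grad(build(params), geometry, restraints)
        return e

    x0 = np.zeros(6 * len(masks))
    e0 = objective(x0)
    res = _minimize(
        objective, x0, method="Nelder-Mead",
        options={"maxiter": maxiter * max(1, len(masks)), "xatol": 1e-5, "fatol": 1e-10},
    )
    best = res.x if res.fun <= e0 else x0
    final = build(best)
    return final, [e0, float(min(res.fun, e0))]


def refine_rigid_profile(
    start: Structure,
    datasets: list[PCSDataset],
    blocks: list[set[int]],
    site: MetalSite,
    maxiter: int = 600,
    refit_site: bool = True,
) -> tuple[Structure, MetalSite, float]:
    """Rigid-block refinement with the tensors profiled out (variable projection).

    At every trial placement of the mobile blocks the per-dataset tensors
    are re-solved exactly by linear least squares, so the outer objective is
    the fully minimized PCS misfit as a function of the rigid degrees of
    freedom (plus, with ``refit_site``, the three site coordinates) alone.
    This avoids the slow zigzag of alternating full tensor fits with
    fixed-tensor minimization: with self-consistent data the true block
    placement is the global minimum of the profiled objective.
    Returns (structure, refined site, final objective).
    """
    from scipy.optimize import minimize as _minimize

    from .tensor_fit import _objective_at_site

    masks = [
        np.array([int(rn) in block for rn in start.residue_numbers])
        for block in blocks[1:]
    ]
    centroids = [start.coords[m].mean(axis=0) for m in masks]
    base = start.coords
    site_xyz = site.as_array().copy()
    n_rigid = 6 * len(masks)

    obs_w = []
    atom_rows = []
    for ds in datasets:
        rows = np.array([start.index_of(rn, an) for rn, an in ds.keys()])
        obs = ds.entries["pcs"].to_numpy(float)
        obs_w.append((obs, np.ones_like(obs)))
        atom_rows.append(rows)

    def build_coords(params: np.ndarray) -> np.ndarray:
        coords = base.copy()
        for k, mask in enumerate(masks):
            rot = _axis_angle_matrix(params[6 * k : 6 * k + 3])
            trans = params[6 * k + 3 : 6 * k + 6]
            coords[mask] = (coords[mask] - centroids[k]) @ rot.T + centroids[k] + trans
        return coords

    def objective(params: np.ndarray) -> float:
        coords = build_coords(params[:n_rigid])
        s = params[n_rigid:] if refit_site else site_xyz
        data = [
            (coords[rows], obs, w) for rows, (obs, w) in zip(atom_rows, obs_w)
        ]
        val, _ = _objective_at_site(s, data)
        return val

    x0 = np.zeros(n_rigid + (3 if refit_site else 0))
    if refit_site:
        x0[n_rigid:] = site_xyz
    # initial simplex scaled to the physical step sizes of each DOF
    steps = np.concatenate(
        [np.tile([0.15, 0.15, 0.15, 1.0, 1.0, 1.0], len(masks))]
        + ([np.full(3, 0.5)] if refit_site else [])
    )
    simplex = np.vstack([x0] + [x0 + steps[i] * np.eye(len(x0))[i] for i in range(len(x0))])
    res = _minimize(
        objective, x0, method="Nelder-Mead",
        options={
            "maxiter": maxiter * max(1, len(masks)),
            "xatol": 1e-6, "fatol": 1e-14, "adaptive": True,
            "initial_simplex": simplex,
        },
    )
    best = res.x if res.fun <= objective(x0) else x0
    final = start.with_coords(build_coords(best[:n_rigid]))
    if refit_site:
        site_xyz = best[n_rigid:]
    return final, MetalSite.from_array(site_xyz), float(res.fun)


# ---------------------------------------------------------------------------
# iterative tensor <-> structure protocol
# ---------------------------------------------------------------------------


def _paf_rotation_deg(t1: DeltaChiTensor, t2: DeltaChiTensor) -> float:
    """Angle between the principal z-axes of two tensors (sign-insensitive).

    Near the maximum-rhombicity boundary |χzz| ≈ |χyy| the z-label is
    unstable and the nominal axis can hop 90° between near-identical
    tensors; in that regime the orientation criterion is meaningless and 0
    is returned (the component-change criterion still applies).
    """
    def z_info(t):
        evals, evecs = np.linalg.eigh(t.as_matrix())
        order = np.argsort(np.abs(evals))
        gap = abs(abs(evals[order[2]]) - abs(evals[order[1]]))
        return evecs[:, order[2]], gap / max(abs(evals[order[2]]), 1e-30)

    z1, gap1 = z_info(t1)
    z2, gap2 = z_info(t2)
    if min(gap1, gap2) < 0.05:
        return 0.0
    c = abs(float(z1 @ z2))
    return float(np.degrees(np.arccos(min(1.0, c))))


def iterate_tensor_structure(
    start: Structure,
    datasets: list[PCSDataset],
    geometry: GeometryTemplate | None,
    max_rounds: int = 10,
    refine_steps: int = 300,
    blocks: list[set[int]] | None = None,
    force_constant: float = 1.0,
    tolerance: float = 0.0,
    box: tuple | None = None,
    grid_spacing: float = 2.0,
    ax_rh_rel_tol: float = 0.01,
    paf_tol_deg: float = 2.0,
    site_tol: float = 0.1,
    rmsd_tol: float = 0.05,
) -> dict:
    """Alternate Δχ/site fitting and restrained minimization until convergence.

    Each round (a) refits the shared site and per-dataset tensors on the
    current coordinates, then (b) minimizes the structure with the tensors
    held fixed.  Convergence requires, between consecutive rounds: relative
    change of Δχ_ax and Δχ_rh below ``ax_rh_rel_tol``, principal-axis
    rotation below ``paf_tol_deg``, site displacement below ``site_tol`` Å
    and coordinate RMSD below ``rmsd_tol`` Å.  Three consecutive objective
    increases raise NonConvergenceError.
    """
    structure = start
    rounds, converged = [], False
    increases = 0
    fit = fit_position_and_tensors(
        datasets, structure, box=box, grid_spacing=grid_spacing,
        check_consistency=False,
    )
    prev_fit, prev_coords = fit, structure.coords.copy()
    if max_rounds == 0:
        return {
            "ensemble": StructureEnsemble([structure]),
            "fit": fit,
            "rounds": [],
            "converged": False,
        }
    for round_no in range(1, max_rounds + 1):
        local_box = (fit.site.as_array() - 4.0, fit.site.as_array() + 4.0)
        if blocks is not None:
            structure, new_site, _ = refine_rigid_profile(
                structure, datasets, blocks, fit.site
            )
            # tensors must be re-solved for the moved blocks before they are
            # frozen into Cartesian restraints
            fit = fit_position_and_tensors(
                datasets, structure, box=local_box, grid_spacing=grid_spacing,
                check_consistency=False,
            )
        restraints = PCSRestraintSet(
            datasets, [f.tensor for f in fit.fits], fit.site,
            force_constant=force_constant, tolerance=tolerance,
        )
        structure, trace = refine_structure(
            structure, geometry, restraints, steps=refine_steps
        )
        # after the first global search the site moves little per round
        new_fit = fit_position_and_tensors(
            datasets, structure, box=local_box, grid_spacing=grid_spacing,
            check_consistency=False,
        )
        entry = {
            "round": round_no,
            "objective": new_fit.objective,
            "q_factors": new_fit.q_factors,
            "energy_final": trace[-1],
        }
        if prev_fit is not None:
            entry["site_shift"] = float(
                np.linalg.norm(new_fit.site.as_array() - prev_fit.site.as_array())
            )
            rel, rot = [], []
            for f_new, f_old in zip(new_fit.fits, prev_fit.fits):
                # component-space change is label-stable even at the
                # maximum-rhombicity boundary where (Δχax, Δχrh) flip
                dc = np.abs(f_new.tensor.components - f_old.tensor.components).max()
                rel.append(dc / max(np.abs(f_old.tensor.components).max(), 1e-12))
                rot.append(_paf_rotation_deg(f_new.tensor, f_old.tensor))
            entry["tensor_rel_change"] = max(rel)
            entry["paf_rotation_deg"] = max(rot)
            entry["coord_rmsd"] = float(
                np.sqrt(np.mean(np.sum((structure.coords - prev_coords) ** 2, axis=1)))
            )
            if new_fit.objective > prev_fit.objective * (1 + 1e-9):
                increases += 1
                if increases >= 3:
                    raise NonConvergenceError(
                        "objective increased 3 consecutive rounds; trace: "
                        + ", ".join("%.3e" % r["objective"] for r in rounds)
                    )
            else:
                increases = 0
            if (
                entry["tensor_rel_change"] < ax_rh_rel_tol
                and entry["paf_rotation_deg"] < paf_tol_deg
                and entry["site_shift"] < site_tol
                and entry["coord_rmsd"] < rmsd_tol
            ):
                converged = True
        rounds.append(entry)
        logger.info("round %d: objective %.3e", round_no, new_fit.objective)
        prev_fit, prev_coords = new_fit, structure.coords.copy()
        fit = new_fit
        if converged:
            break
    return {
        "ensemble": StructureEnsemble([structure]),
        "fit": fit,
        "rounds": rounds,
        "converged": converged,
    }


# ---------------------------------------------------------------------------
# ensemble analytics
# ---------------------------------------------------------------------------


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal rotation/translation superposing mobile onto target.

    Returns (rotation (3,3), translation (3,), rmsd).
    """
    p = np.asarray(mobile, float)
    q = np.asarray(target, float)
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = qc - rot @ pc
    moved = (rot @ p.T).T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return rot, trans, rmsd


@dataclass
class BundleStats:
    pairwise_rmsd_mean: float
    metal_spread_rmsd: float | None
    pair_rmsd: np.ndarray
    selection: list[tuple[int, str]]


def bundle_stats(
    ensemble: StructureEnsemble,
    selection=None,
    metal_positions: np.ndarray | None = None,
) -> BundleStats:
    """All-pairs Kabsch superposition statistics for a structural bundle.

    ``selection`` is a predicate on (residue_number, atom_name) or a list of
    such keys; default all atoms.  ``metal_positions`` (n_models, 3), if
    given, yields the metal spread: rms distance of the superposed metal
    positions about their mean, with each model aligned onto the first on
    the selection.
    """
    if len(ensemble) < 2:
        raise ValueError("bundle statistics need at least 2 models")
    keys = ensemble[0].atom_keys()
    if selection is None:
        sel_keys = keys
    elif callable(selection):
        sel_keys = [k for k in keys if selection(*k)]
    else:
        sel_keys = [tuple(k) for k in selection]
    if len(sel_keys) < 3:
        raise ValueError("selection must contain at least 3 atoms")
    idx = [ensemble[0].index_of(*k) for k in sel_keys]
    n = len(ensemble)
    pair = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, rmsd = kabsch(ensemble[j].coords[idx], ensemble[i].coords[idx])
            pair[i, j] = pair[j, i] = rmsd
    mean_rmsd = float(pair[np.triu_indices(n, 1)].mean())

    metal_spread = None
    if metal_positions is not None:
        metal_positions = np.asarray(metal_positions, float)
        aligned = [metal_positions[0]]
        for j in range(1, n):
            rot, trans, _ = kabsch(ensemble[j].coords[idx], ensemble[0].coords[idx])
            aligned.append(rot @ metal_positions[j] + trans)
        aligned = np.asarray(aligned)
        centered = aligned - aligned.mean(axis=0)
        metal_spread = float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))
    return BundleStats(mean_rmsd, metal_spread, pair, sel_keys)


def helix_axis(structure: Structure, base_pairs: list[tuple[int, int]]) -> np.ndarray:
    """Unit axis of a duplex from the C1'-midpoints of consecutive base pairs.

    The axis is the principal direction of the midpoint series, oriented
    5'→3' along the first strand (increasing base-pair index).
    """
    if len(base_pairs) < 3:
        raise ValueError("need at least 3 base pairs to define a helix axis")
    mids = []
    for res_a, res_b in base_pairs:
        mids.append(
            0.5 * (structure.position(res_a, "C1'") + structure.position(res_b, "C1'"))
        )
    mids = np.asarray(mids)
    centered = mids - mids.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    if axis @ (mids[-1] - mids[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def interhelical_angle(
    structure: Structure,
    helix_a: list[tuple[int, int]],
    helix_b: list[tuple[int, int]],
) -> float:
    """Angle (degrees, [0, 180]) between two helix axes.

    Each helix is given as its list of (strand-1 residue, strand-2 residue)
    base pairs in 5'→3' order of the first strand.
    """
    axis_a = helix_axis(structure, helix_a)
    axis_b = helix_axis(structure, helix_b)
    c = float(np.clip(axis_a @ axis_b, -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def select_bundle(
    candidates: list[Structure],
    geometry: GeometryTemplate | None,
    restraints: PCSRestraintSet | None,
    n_keep: int,
) -> StructureEnsemble:
    """Keep the n_keep candidates with the lowest geometry + PCS energy."""
    scored = []
    for s in candidates:
        e, _, _ = total_energy_grad(s, geometry, restraints)
        scored.append((e, s))
    scored.sort(key=lambda t: t[0])
    kept = [s for _, s in scored[:n_keep]]
    models = [
        Structure(s.residue_numbers, s.residue_names, s.atom_names, s.coords, i + 1)
        for i, s in enumerate(kept)
    ]
    return StructureEnsemble(models)
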