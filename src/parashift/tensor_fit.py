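"""Δχ-tensor and metal-position fitting against PCS datasets.

At a fixed metal position the PCS forward model is linear in the five
independent components of the traceless susceptibility anisotropy tensor,
so each dataset reduces to a weighted linear least-squares problem.  The
metal position enters nonlinearly; a joint fit of several datasets sharing
one site uses a nested scheme: a coarse grid over a search box followed by
Nelder-Mead refinement of the three site coordinates, with an exact linear
solve per dataset at every candidate site.  Fit quality is reported as

    Q = sqrt( Σ (obs − calc)² / Σ obs² )

with no mean-centering, the convention used by FANTEN-style PCS software.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .io_formats import PCSDataset, Structure
from .pcs_core import DeltaChiTensor, MetalSite, pcs_design_matrix

logger = logging.getLogger(__name__)

#: Entries closer than this to a candidate site are down-weighted during
#: position search (unmodeled contact-shift / local-dynamics leverage guard).
NEAR_SITE_RADIUS = 5.0
NEAR_SITE_WEIGHT = 0.1


class DegenerateGeometryError(ValueError):
    """Observed atoms do not determine the five tensor components."""


class UndefinedQError(ValueError):
    """Q-factor undefined because all observed values are zero."""


class FoldSizeError(ValueError):
    """A cross-validation fold leaves too few training observations."""


@dataclass
class FitResult:
    tensor: DeltaChiTensor
    site: MetalSite
    residuals: np.ndarray
    q_factor: float
    n_obs: int
    metal_label: str = ""
    ambiguous_swaps: int = 0

    def calculated(self, observed: np.ndarray) -> np.ndarray:
        return np.asarray(observed) - self.residuals


@dataclass
class JointFitResult:
    site: MetalSite
    fits: list[FitResult]
    objective: float
    inconsistent: bool = False

    @property
    def q_factors(self) -> dict[str, float]:
        return {f.metal_label or str(i): f.q_factor for i, f in enumerate(self.fits)}


def q_factor(observed, calculated, weights=None) -> float:
    """Normalized rms deviation between observed and back-calculated PCS."""
    obs = np.asarray(observed, dtype=float)
    calc = np.asarray(calculated, dtype=float)
    if obs.shape != calc.shape or obs.size == 0:
        raise ValueError("observed and calculated must be equal-length, non-empty")
    w = np.ones_like(obs) if weights is None else np.asarray(weights, dtype=float)
    denom = float(w @ obs**2)
    if denom == 0.0:
        raise UndefinedQError("all observed values are zero")
    return float(np.sqrt(w @ (obs - calc) ** 2 / denom))


def _matched_arrays(dataset: PCSDataset, structure: Structure):
    """Positions / observations / sigmas for entries whose atoms exist."""
    keep, positions = [], []
    for i, (rn, an) in enumerate(dataset.keys()):
        if structure.has_atom(rn, an):
            keep.append(i)
            positions.append(structure.position(rn, an))
        else:
            logger.info("skipping %s%d %s: atom absent from structure", "", rn, an)
    if not keep:
        raise DegenerateGeometryError("no dataset entries match the structure")
    ent = dataset.entries.iloc[keep]
    return (
        np.asarray(positions, dtype=float),
        ent["pcs"].to_numpy(float),
        ent["sigma"].to_numpy(float),
        keep,
    )


def _solve_tensor(design: np.ndarray, obs: np.ndarray, weights: np.ndarray):
    """Weighted linear LS for the 5 tensor components; raises if rank < 5."""
    sw = np.sqrt(weights)
    a = design * sw[:, None]
    b = obs * sw
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 5:
        raise DegenerateGeometryError(
            f"design matrix rank {rank} < 5 (null space dimension {5 - rank}): "
            "observed atoms are in a degenerate arrangement"
        )
    return sol


def fit_tensor_fixed_position(
    dataset: PCSDataset,
    structure: Structure,
    site: MetalSite,
    weights: str = "uniform",
) -> FitResult:
    """Fit one Δχ tensor to one dataset with the metal position held fixed.

    Linear least squares over the 5 Cartesian tensor components; entries
    whose atoms are absent from the structure are skipped with a log line.
    """
    positions, obs, sigma, _ = _matched_arrays(dataset, structure)
    if len(obs) < 5:
        raise DegenerateGeometryError(
            f"{len(obs)} matched observations < 5 tensor unknowns"
        )
    if weights == "uniform":
        w = np.ones_like(obs)
    elif weights == "inverse_variance":
        w = 1.0 / sigma**2
    else:
        raise ValueError(f"unknown weighting {weights!r}")
    design = pcs_design_matrix(positions, site.as_array())
    comps = _solve_tensor(design, obs, w)
    calc = design @ comps
    return FitResult(
        tensor=DeltaChiTensor.from_components(comps),
        site=site,
        residuals=obs - calc,
        q_factor=q_factor(obs, calc),
        n_obs=len(obs),
        metal_label=dataset.metal_label,
    )


# ---------------------------------------------------------------------------
# joint position + tensors fit
# ---------------------------------------------------------------------------


def _objective_at_site(site_xyz, data, ambiguous_pairs=None):
    """Sum of weighted squared residuals over datasets; exact inner solve.

    data is a list of (positions, obs, weights) triples.  Entries within
    NEAR_SITE_RADIUS of the candidate site are down-weighted.  Returns
    (objective, per-dataset solutions).
    """
    total, sols = 0.0, []
    for positions, obs, w in data:
        d = positions - site_xyz
        near = np.einsum("ij,ij->i", d, d) < NEAR_SITE_RADIUS**2
        w_eff = np.where(near, w * NEAR_SITE_WEIGHT, w)
        try:
            design = pcs_design_matrix(positions, site_xyz)
            comps = _solve_tensor(design, obs, w_eff)
        except (DegenerateGeometryError, ValueError):
            return np.inf, None
        resid = obs - design @ comps
        total += float(w_eff @ resid**2)
        sols.append(comps)
    return total, sols


def _resolve_ambiguous(dataset_arrays, comps, site_xyz, pairs):
    """Swap observed values within diastereotopic pairs to minimize residuals.

    ``pairs`` maps dataset index -> list of (row_i, row_j) index pairs into
    the matched observation vector.  Returns the number of swaps applied.
    """
    swaps = 0
    for k, pair_list in pairs.items():
        positions, obs, w = dataset_arrays[k]
        design = pcs_design_matrix(positions, site_xyz)
        calc = design @ comps[k]
        for i, j in pair_list:
            keep = (obs[i] - calc[i]) ** 2 + (obs[j] - calc[j]) ** 2
            swap = (obs[i] - calc[j]) ** 2 + (obs[j] - calc[i]) ** 2
            if swap < keep:
                obs[i], obs[j] = obs[j], obs[i]
                swaps += 1
    return swaps


def fit_position_and_tensors(
    datasets: list[PCSDataset],
    structure: Structure,
    box: tuple | None = None,
    grid_spacing: float = 2.0,
    xtol: float = 1e-4,
    weights: str = "uniform",
    ambiguous_pairs: dict | None = None,
    check_consistency: bool = True,
) -> JointFitResult:
    """Joint fit of a shared metal position and one Δχ tensor per dataset.

    Outer search over the 3 site coordinates: coarse grid over ``box``
    (default: structure bounding box inflated by 10 Å) followed by
    Nelder-Mead from the best grid node; inner step is the exact linear
    tensor solve per dataset.  The objective is the summed weighted squared
    residual over all datasets.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    data, keep_rows = [], []
    for ds in datasets:
        positions, obs, sigma, kept = _matched_arrays(ds, structure)
        if len(obs) < 5:
            raise DegenerateGeometryError(
                f"dataset {ds.metal_label}: {len(obs)} matched observations < 5"
            )
        w = np.ones_like(obs) if weights == "uniform" else 1.0 / sigma**2
        data.append((positions, obs.copy(), w))
        keep_rows.append(kept)

    if box is None:
        lo = structure.coords.min(axis=0) - 10.0
        hi = structure.coords.max(axis=0) + 10.0
    else:
        lo = np.asarray(box[0], dtype=float)
        hi = np.asarray(box[1], dtype=float)
    axes = [np.arange(lo[i], hi[i] + grid_spacing / 2, grid_spacing) for i in range(3)]

    best_val, best_site = np.inf, None
    values = []
    for xyz in itertools.product(*axes):
        val, _ = _objective_at_site(np.array(xyz), data)
        values.append(val)
        if val < best_val:
            best_val, best_site = val, np.array(xyz)
    finite = [v for v in values if np.isfinite(v)]
    if best_site is None or not finite:
        raise ValueError("search box contains no admissible site")
    if len(finite) > 1 and (max(finite) - min(finite)) <= 1e-12 * max(1.0, abs(best_val)):
        raise ValueError("objective flat across the search box: site not identifiable")

    for _ in range(3 if ambiguous_pairs else 1):
        res = minimize(
            lambda p: _objective_at_site(p, data)[0],
            best_site,
            method="Nelder-Mead",
            options={"xatol": xtol, "fatol": 1e-14, "maxiter": 2000},
        )
        best_site = res.x
        if ambiguous_pairs:
            _, sols = _objective_at_site(best_site, data)
            if _resolve_ambiguous(data, sols, best_site, ambiguous_pairs) == 0:
                break

    site = MetalSite.from_array(best_site)
    objective, _ = _objective_at_site(best_site, data)
    fits = []
    for ds, (positions, obs, w) in zip(datasets, data):
        design = pcs_design_matrix(positions, best_site)
        comps = _solve_tensor(design, obs, w)
        calc = design @ comps
        fits.append(
            FitResult(
                tensor=DeltaChiTensor.from_components(comps),
                site=site,
                residuals=obs - calc,
                q_factor=q_factor(obs, calc),
                n_obs=len(obs),
                metal_label=ds.metal_label,
            )
        )

    inconsistent = False
    if check_consistency and len(datasets) > 1:
        # if datasets prefer well-separated sites, the joint Q degrades;
        # the per-dataset refits start near the joint site, so this stays cheap
        sep_q = []
        sep_box = (best_site - 6.0, best_site + 6.0)
        for ds in datasets:
            sep = fit_position_and_tensors(
                [ds], structure, box=sep_box, grid_spacing=2.0, xtol=xtol,
                weights=weights,
            )
            sep_q.append(sep.fits[0].q_factor)
        for joint_fit, sq in zip(fits, sep_q):
            if sq > 1e-12 and joint_fit.q_factor / sq > 2.0:
                inconsistent = True
        if inconsistent:
            warnings.warn(
                "joint-site fit markedly worse than per-dataset fits: "
                "datasets may not share one metal site",
                stacklevel=2,
            )
    return JointFitResult(site=site, fits=fits, objective=objective, inconsistent=inconsistent)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def cross_validate(
    dataset: PCSDataset,
    structure: Structure,
    site: MetalSite,
    scheme: str = "loo",
    k: int = 5,
    holdout_nucleus: str | None = None,
    weights: str = "uniform",
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """(Q_work, Q_free) by refitting the tensor on training folds.

    With ``holdout_nucleus`` set (e.g. "31P" selecting phosphorus atoms, or
    an atom-name prefix like "P"), those nuclei form a single held-out set
    never used in training — the protocol used to validate a structure
    against backbone ³¹P shifts that played no part in refinement.
    """
    ent = dataset.entries
    n = len(ent)
    if holdout_nucleus is not None:
        name = holdout_nucleus.lstrip("0123456789")  # "31P" -> "P"
        test_mask = ent["atom_name"].str.startswith(name).to_numpy()
        if test_mask.sum() == 0:
            raise FoldSizeError(f"no entries match holdout nucleus {holdout_nucleus!r}")
        folds = [(~test_mask, test_mask)]
    elif scheme == "loo":
        folds = []
        for i in range(n):
            test = np.zeros(n, dtype=bool)
            test[i] = True
            folds.append((~test, test))
    elif scheme == "k_fold":
        rng = rng or np.random.default_rng(0)
        perm = rng.permutation(n)
        parts = np.array_split(perm, k)
        folds = []
        for part in parts:
            test = np.zeros(n, dtype=bool)
            test[part] = True
            folds.append((~test, test))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    obs_all, calc_work, obs_free, calc_free = [], [], [], []
    for train_mask, test_mask in folds:
        if train_mask.sum() < 5:
            raise FoldSizeError(
                f"fold leaves {int(train_mask.sum())} training observations < 5"
            )
        train = PCSDataset(dataset.metal_label, ent[train_mask], dataset.solvent)
        fit = fit_tensor_fixed_position(train, structure, site, weights=weights)
        obs_all.append(ent["pcs"].to_numpy(float)[train_mask])
        calc_work.append(ent["pcs"].to_numpy(float)[train_mask] - fit.residuals)
        test = ent[test_mask]
        pos = np.array(
            [structure.position(rn, an) for rn, an in zip(test["residue_number"], test["atom_name"])]
        )
        design = pcs_design_matrix(pos, site.as_array())
        obs_free.append(test["pcs"].to_numpy(float))
        calc_free.append(design @ fit.tensor.components)

    q_work = q_factor(np.concatenate(obs_all), np.concatenate(calc_work))
    q_free = q_factor(np.concatenate(obs_free), np.concatenate(calc_free))
    return q_work, q_free


# ---------------------------------------------------------------------------
# uncertainties
# ---------------------------------------------------------------------------


def mc_uncertainty(
    fit: JointFitResult,
    datasets: list[PCSDataset],
    structure: Structure,
    sigma: float,
    n_replicates: int = 100,
    seed: int = 0,
    grid_spacing: float = 2.0,
) -> dict:
    """Parametric-bootstrap standard deviations of the fitted parameters.

    PCS are resampled about the back-calculated values with Gaussian noise
    of the stated sigma and refit; SDs of Δχ_ax, Δχ_rh, PAF angles and site
    coordinates are reported per dataset.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n_replicates < 50:
        raise ValueError("need at least 50 replicates")
    rng = np.random.default_rng(seed)
    site0 = fit.site.as_array()
    box = (site0 - 3.0, site0 + 3.0)

    calc_sets = []
    for ds, f in zip(datasets, fit.fits):
        positions, obs, _, _ = _matched_arrays(ds, structure)
        design = pcs_design_matrix(positions, site0)
        calc_sets.append(design @ f.tensor.components)

    samples = {
        f.metal_label or str(i): {"dchi_ax": [], "dchi_rh": [], "angles": []}
        for i, f in enumerate(fit.fits)
    }
    sites = []
    for _ in range(n_replicates):
        perturbed = []
        for ds, calc in zip(datasets, calc_sets):
            positions, obs, sig, kept = _matched_arrays(ds, structure)
            ent = ds.entries.iloc[kept].copy()
            ent["pcs"] = calc + rng.normal(0.0, sigma, size=len(calc))
            perturbed.append(PCSDataset(ds.metal_label, ent, ds.solvent))
        rep = fit_position_and_tensors(
            perturbed, structure, box=box, grid_spacing=1.5, xtol=1e-5,
            check_consistency=False,
        )
        sites.append(rep.site.as_array())
        for i, f in enumerate(rep.fits):
            key = f.metal_label or str(i)
            ax, rh, angles, _ = f.tensor.principal()
            samples[key]["dchi_ax"].append(ax)
            samples[key]["dchi_rh"].append(rh)
            samples[key]["angles"].append(angles)

    out = {"site_sd": np.std(np.asarray(sites), axis=0)}
    for key, vals in samples.items():
        out[key] = {
            "dchi_ax_sd": float(np.std(vals["dchi_ax"])),
            "dchi_rh_sd": float(np.std(vals["dchi_rh"])),
            "angle_sd": np.std(np.asarray(vals["angles"]), axis=0),
        }
    return out
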