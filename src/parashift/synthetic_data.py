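"""Synthetic structures, PCS datasets and titrations with known ground truth.

The generators emulate the statistical structure of a lanthanide-binding
three-helix DNA junction study: idealized duplexes with a reduced atom set,
a junction with controlled interhelical angles, a single metal site shared
by several Δχ tensors (one per emulated lanthanide, magnitudes spanning the
range measured for DNA-bound ions), Gaussian shift noise, a PRE blind zone
that censors observations near the metal, and additional random peak loss.
PCS depends only on atom positions, so no nucleotide chemistry beyond named
pseudo-atoms is needed.  All randomness flows through one explicit seeded
generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import EmptyDatasetError, PCSDataset, Structure
from .pcs_core import DeltaChiTensor, MetalSite, pcs_forward_many
from .binding_rdc import BindingSystem, bound_fraction_ligand

#: Reduced per-nucleotide template: name -> (radius Å, phase deg, rise offset Å).
#: C1' atoms of paired residues are antipodal so base-pair C1'-midpoints lie
#: exactly on the helix axis.
NUCLEOTIDE_TEMPLATE = {
    "P": (8.9, 100.0, 1.8),
    "C1'": (5.9, 65.0, 0.0),
    "N1": (3.0, 40.0, 0.2),
    "H1'": (6.5, 72.0, -0.5),
    "H8": (3.8, 20.0, 0.5),
    "H2'": (6.8, 88.0, -1.0),
    "H2''": (7.2, 82.0, 0.3),
}

DEFAULT_ATOMS = ("P", "C1'", "N1", "H1'", "H8")


@dataclass(frozen=True)
class HelixSpec:
    """Idealized duplex parameters (B-form defaults: rise 3.38 Å, twist 36°)."""

    n_bp: int
    rise: float = 3.38
    twist: float = 36.0
    atoms_per_nucleotide: tuple = DEFAULT_ATOMS

    def __post_init__(self):
        if self.n_bp < 1:
            raise ValueError("n_bp must be >= 1")
        if self.rise <= 0 or self.twist <= 0:
            raise ValueError("rise and twist must be positive")
        unknown = set(self.atoms_per_nucleotide) - set(NUCLEOTIDE_TEMPLATE)
        if unknown:
            raise ValueError(f"unknown template atoms {unknown}")


@dataclass
class SimulationSpec:
    """Ground truth and noise model for planted PCS datasets."""

    site: MetalSite
    tensors: list[DeltaChiTensor]
    metal_labels: list[str] | None = None
    noise_sigma: float = 0.02  # ppm
    blind_radius: float = 7.0  # Å, PRE blind zone
    missing_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0 or self.blind_radius < 0:
            raise ValueError("noise_sigma and blind_radius must be >= 0")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.metal_labels is None:
            self.metal_labels = [f"M{i + 1}" for i in range(len(self.tensors))]
        if len(self.metal_labels) != len(self.tensors):
            raise ValueError("one label per tensor required")


def default_tensors() -> tuple[list[DeltaChiTensor], list[str]]:
    """Four planted tensors emulating a four-lanthanide experiment.

    Axialities span roughly −4 to +1.5 (10⁻³² m³) with mixed-sign
    rhombicities — the magnitude range measured for lanthanides in a
    DNA-bound, partially hydrated coordination environment — and each
    tensor carries a distinct principal-axis orientation so the four PCS
    patterns are genuinely independent.
    """
    params = [
        ("Ce", 0.96, -0.61, (10.0, 25.0, 40.0)),
        ("Eu", 1.42, -0.55, (70.0, 55.0, 15.0)),
        ("Tm", -3.88, 1.62, (130.0, 80.0, 60.0)),
        ("Yb", -2.77, 1.29, (200.0, 35.0, 110.0)),
    ]
    tensors = [
        DeltaChiTensor.from_axial_rhombic(ax, rh, *angles)
        for _, ax, rh, angles in params
    ]
    return tensors, [p[0] for p in params]


# ---------------------------------------------------------------------------
# structure generators
# ---------------------------------------------------------------------------


def make_helix(spec: HelixSpec, start_residue: int = 1) -> Structure:
    """Idealized antiparallel duplex built by helical symmetry along +z.

    Strand 1 runs residues start..start+n−1 bottom-up; strand 2 runs
    start+n..start+2n−1 with residue start+2n−1−k paired to strand-1 residue
    start+k (i.e. local residue i pairs with 2n+1−i).  Every atom of
    base-pair level k is the level-0 template atom rotated by k·twist and
    lifted by k·rise, so one twist/rise screw maps level k onto level k+1.
    """
    n = spec.n_bp
    resnums, resnames, atnames, coords = [], [], [], []

    def place(level: int, strand: int, residue: int):
        ang0 = math.radians(spec.twist) * level
        z0 = spec.rise * level
        for name in spec.atoms_per_nucleotide:
            radius, phase, dz = NUCLEOTIDE_TEMPLATE[name]
            phi = ang0 + math.radians(phase + (180.0 if strand == 2 else 0.0))
            dzs = dz if strand == 1 else -dz
            resnums.append(residue)
            resnames.append("DN")
            atnames.append(name)
            coords.append(
                [radius * math.cos(phi), radius * math.sin(phi), z0 + dzs]
            )

    for k in range(n):  # strand 1, 5'->3' bottom-up
        place(k, 1, start_residue + k)
    for k in range(n):  # strand 2, antiparallel
        place(n - 1 - k, 2, start_residue + n + k)
    order = np.argsort(np.array(resnums), kind="stable")
    return Structure(
        np.array(resnums)[order],
        [resnames[i] for i in order],
        [atnames[i] for i in order],
        np.array(coords)[order],
    )


def helix_base_pairs(spec: HelixSpec, start_residue: int = 1) -> list[tuple[int, int]]:
    """(strand-1 residue, strand-2 residue) pairs in 5'→3' order of strand 1."""
    n = spec.n_bp
    return [(start_residue + k, start_residue + 2 * n - 1 - k) for k in range(n)]


def _rotation_axis_angle(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    x, y, z = axis
    cross = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * cross + (1 - c) * np.outer(axis, axis)


class ClashError(ValueError):
    """Placed helices overlap."""


def make_junction(
    helices: list[tuple[HelixSpec, float, float]],
    gap: float = 6.0,
    min_separation: float = 1.0,
) -> tuple[Structure, dict]:
    """Assemble a multi-helix junction with controlled interhelical angles.

    ``helices`` lists (spec, angle_deg, azimuth_deg): the first helix runs
    along +z from the origin; each further helix axis is +z tilted by
    ``angle_deg`` about y (then spun by ``azimuth_deg`` about z) and grows
    outward from a junction point just above helix 1.  Residue numbering is
    sequential across helices.  Returns the structure and the ground truth
    (per-helix base pairs, axis directions and requested angles).
    """
    if len(helices) < 2:
        raise ValueError("a junction needs at least 2 helices")
    parts, truth_pairs, axes, angles = [], [], [], []
    start = 1
    spec0 = helices[0][0]
    junction = np.array([0.0, 0.0, spec0.rise * (spec0.n_bp - 1) + gap])
    for k, (spec, angle_deg, azimuth_deg) in enumerate(helices):
        helix = make_helix(spec, start_residue=start)
        pairs = helix_base_pairs(spec, start_residue=start)
        if k == 0:
            direction = np.array([0.0, 0.0, 1.0])
            coords = helix.coords
        else:
            rot = _rotation_axis_angle([0, 0, 1], azimuth_deg) @ _rotation_axis_angle(
                [0, 1, 0], angle_deg
            )
            direction = rot @ np.array([0.0, 0.0, 1.0])
            coords = helix.coords @ rot.T + junction + direction * gap
        parts.append(
            Structure(
                helix.residue_numbers, helix.residue_names, helix.atom_names, coords
            )
        )
        truth_pairs.append(pairs)
        axes.append(direction)
        angles.append(angle_deg)
        start += 2 * spec.n_bp

    all_coords = np.vstack([p.coords for p in parts])
    structure = Structure(
        np.concatenate([p.residue_numbers for p in parts]),
        sum((p.residue_names for p in parts), []),
        sum((p.atom_names for p in parts), []),
        all_coords,
    )
    # clash check between distinct helices
    offsets = np.cumsum([0] + [p.n_atoms for p in parts])
    for i in range(len(parts)):
        for j in range(i + 1, len(parts)):
            a = all_coords[offsets[i] : offsets[i + 1]]
            b = all_coords[offsets[j] : offsets[j + 1]]
            d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=2)
            if d2.min() < min_separation**2:
                raise ClashError(
                    f"helices {i + 1} and {j + 1} clash "
                    f"(min distance {math.sqrt(d2.min()):.2f} Å)"
                )
    truth = {
        "base_pairs": truth_pairs,
        "axes": axes,
        "angles_to_first": angles,
        "junction": junction,
    }
    return structure, truth


# ---------------------------------------------------------------------------
# observation generators
# ---------------------------------------------------------------------------


def plant_pcs(structure: Structure, sim: SimulationSpec) -> list[PCSDataset]:
    """Plant one PCS dataset per tensor with noise and PRE censoring.

    Observations are generated for every proton-like atom (name starting
    with H): pcs = forward model + N(0, noise_sigma); atoms within
    ``blind_radius`` of the metal are removed (PRE blind zone) and a further
    ``missing_fraction`` are dropped at random, independently per dataset.
    """
    rng = np.random.default_rng(sim.seed)
    site = sim.site.as_array()
    mask = np.array([name.startswith("H") for name in structure.atom_names])
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        raise EmptyDatasetError("structure contains no proton-like atoms")
    positions = structure.coords[idx]
    dist = np.linalg.norm(positions - site, axis=1)
    visible = dist >= sim.blind_radius
    if not visible.any():
        raise EmptyDatasetError("PRE blind zone removed every observable proton")
    sigma_col = sim.noise_sigma if sim.noise_sigma > 0 else 1e-6
    datasets = []
    for tensor, label in zip(sim.tensors, sim.metal_labels):
        keep = visible & (rng.random(len(idx)) >= sim.missing_fraction)
        if not keep.any():
            raise EmptyDatasetError(f"no observations survive censoring for {label}")
        rows = idx[keep]
        pcs = pcs_forward_many(tensor, sim.site, structure.coords[rows])
        if sim.noise_sigma > 0:
            pcs = pcs + rng.normal(0.0, sim.noise_sigma, size=len(rows))
        entries = pd.DataFrame(
            {
                "residue_number": structure.residue_numbers[rows],
                "atom_name": [structure.atom_names[i] for i in rows],
                "pcs": pcs,
                "sigma": sigma_col,
            }
        )
        datasets.append(PCSDataset(label, entries, solvent="D2O"))
    return datasets


def perturb_tensor_solvent(
    tensor: DeltaChiTensor,
    scale: float = 1.0,
    rotation_deg: float = 0.0,
    axis=(0.0, 0.0, 1.0),
) -> DeltaChiTensor:
    """Scale the eigenvalues and rotate the PAF, emulating a solvent change.

    A lanthanide that stays partially hydrated re-coordinates on H₂O→D₂O
    exchange; its Δχ tensor shrinks/grows and reorients while the site stays
    put.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    rot = _rotation_axis_angle(np.asarray(axis, float), rotation_deg)
    m = rot @ (scale * tensor.as_matrix()) @ rot.T
    return DeltaChiTensor.from_matrix(m)


def make_titration(
    kd: float,
    ligand_total: float,
    metal_points,
    signal_free: float = 0.0,
    signal_bound: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-column titration table from the 1:1 binding forward model."""
    rng = np.random.default_rng(seed)
    rows = []
    for m in metal_points:
        if m < 0:
            raise ValueError("metal_total must be non-negative")
        frac = (
            bound_fraction_ligand(BindingSystem(ligand_total, m, kd)) if m > 0 else 0.0
        )
        signal = signal_free + (signal_bound - signal_free) * frac
        if noise > 0:
            signal += rng.normal(0.0, noise)
        rows.append({"metal_total": m, "signal": signal})
    return pd.DataFrame(rows)
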