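"""Forward pseudocontact-shift model and Δχ-tensor representations.

The pseudocontact shift (PCS) experienced by a nucleus near a paramagnetic
center with anisotropic magnetic susceptibility is

    δ_PC = 1/(12π r³) · [Δχ_ax (3cos²θ − 1) + (3/2) Δχ_rh sin²θ cos2Ω]

where (r, θ, Ω) are polar coordinates of the metal→nucleus vector in the
principal axis frame (PAF) of the Δχ tensor.  Package-wide unit convention:
Δχ in 10⁻³² m³, distances in Å, PCS in ppm.  With those units the composite
prefactor is 10⁴/(12π): 10⁻³² m³ / (10⁻¹⁰ m)³ = 10⁻² (dimensionless), times
10⁶ for ppm.

The equivalent Cartesian form used for linear fitting is

    δ_PC = (10⁴/(12π)) · 3 (r̂ᵀ χ r̂) / r³

with χ the traceless symmetric Cartesian tensor; both code paths agree to
machine precision and are cross-checked in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

# 1e4/(12*pi): Δχ in 1e-32 m^3, r in Angstrom, PCS in ppm.
PCS_PREFACTOR = 1.0e4 / (12.0 * math.pi)

#: Minimum admissible metal-nucleus distance (Å); the point-dipole model
#: diverges at the metal position.
SINGULARITY_GUARD = 0.1


class SingularityError(ValueError):
    """Nucleus too close to the paramagnetic center for the point-dipole model."""


@dataclass(frozen=True)
class MetalSite:
    """Cartesian position of the paramagnetic center, Å, structure frame."""

    x: float
    y: float
    z: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("metal site coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, xyz) -> "MetalSite":
        x, y, z = np.asarray(xyz, dtype=float)
        return cls(float(x), float(y), float(z))


def _rotation_zyz(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Active ZYZ rotation matrix, angles in degrees.

    Columns are the principal axes of the rotated frame expressed in the
    laboratory frame: R = Rz(α) · Ry(β) · Rz(γ).
    """
    a, b, g = np.deg2rad([alpha, beta, gamma])
    ca, sa = math.cos(a), math.sin(a)
    cb, sb = math.cos(b), math.sin(b)
    cg, sg = math.cos(g), math.sin(g)
    rz_a = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1.0]])
    ry_b = np.array([[cb, 0, sb], [0, 1.0, 0], [-sb, 0, cb]])
    rz_g = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1.0]])
    return rz_a @ ry_b @ rz_g


def _euler_from_rotation(rot: np.ndarray) -> tuple[float, float, float]:
    """ZYZ Euler angles (degrees) of an active rotation matrix."""
    beta = math.acos(min(1.0, max(-1.0, rot[2, 2])))
    if abs(math.sin(beta)) < 1e-12:
        # gimbal: fold everything into alpha
        alpha = math.atan2(rot[1, 0], rot[0, 0])
        if rot[2, 2] < 0:
            alpha = -alpha
        gamma = 0.0
    else:
        alpha = math.atan2(rot[1, 2], rot[0, 2])
        gamma = math.atan2(rot[2, 1], -rot[2, 0])
    return tuple(np.rad2deg([alpha, beta, gamma]))


@dataclass(frozen=True)
class DeltaChiTensor:
    """Traceless symmetric magnetic susceptibility anisotropy tensor.

    Canonical storage is the five independent Cartesian components
    (χxx, χyy, χxy, χxz, χyz) with χzz = −χxx−χyy, in units of 10⁻³² m³.
    The principal-axis-frame representation (Δχ_ax, Δχ_rh plus ZYZ Euler
    angles in degrees) is derived by eigen-decomposition with eigenvalues
    ordered |χzz| ≥ |χyy| ≥ |χxx|, so

        Δχ_ax = χzz − (χxx + χyy)/2      Δχ_rh = χxx − χyy .

    ``degenerate`` flags orientations that are undetermined because of
    eigenvalue degeneracy (e.g. the zero tensor).
    """

    chi_xx: float
    chi_yy: float
    chi_xy: float
    chi_xz: float
    chi_yz: float
    degenerate: bool = field(default=False, compare=False)

    # -- constructors -------------------------------------------------

    @classmethod
    def from_components(cls, components) -> "DeltaChiTensor":
        c = np.asarray(components, dtype=float)
        if c.shape != (5,):
            raise ValueError("expected 5 components (chi_xx, chi_yy, chi_xy, chi_xz, chi_yz)")
        if not np.all(np.isfinite(c)):
            raise ValueError("tensor components must be finite")
        return cls(*(float(v) for v in c))

    @classmethod
    def from_matrix(cls, matrix) -> "DeltaChiTensor":
        m = np.asarray(matrix, dtype=float)
        if m.shape != (3, 3) or not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("expected a symmetric 3x3 matrix")
        if abs(np.trace(m)) > 1e-9 * max(1.0, float(np.abs(m).max())):
            raise ValueError("tensor must be traceless")
        return cls.from_components([m[0, 0], m[1, 1], m[0, 1], m[0, 2], m[1, 2]])

    @classmethod
    def from_axial_rhombic(
        cls,
        dchi_ax: float,
        dchi_rh: float,
        alpha: float = 0.0,
        beta: float = 0.0,
        gamma: float = 0.0,
    ) -> "DeltaChiTensor":
        """Build from PAF parameters; Euler angles in degrees, ZYZ, active."""
        # invert Δχax = 1.5 χzz, Δχrh = χxx − χyy (traceless)
        chi_zz = 2.0 * dchi_ax / 3.0
        chi_xx = -chi_zz / 2.0 + dchi_rh / 2.0
        chi_yy = -chi_zz / 2.0 - dchi_rh / 2.0
        diag = np.diag([chi_xx, chi_yy, chi_zz])
        rot = _rotation_zyz(alpha, beta, gamma)
        return cls.from_matrix(rot @ diag @ rot.T)

    # -- views --------------------------------------------------------

    @property
    def components(self) -> np.ndarray:
        return np.array(
            [self.chi_xx, self.chi_yy, self.chi_xy, self.chi_xz, self.chi_yz]
        )

    def as_matrix(self) -> np.ndarray:
        xx, yy, xy, xz, yz = self.components
        zz = -xx - yy
        return np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]])

    def principal(self) -> tuple[float, float, tuple[float, float, float], bool]:
        """(Δχ_ax, Δχ_rh, (α, β, γ) degrees, degenerate flag)."""
        evals, evecs = np.linalg.eigh(self.as_matrix())
        order = np.argsort(np.abs(evals))  # |xx| <= |yy| <= |zz|
        evals = evals[order]
        evecs = evecs[:, order]
        if np.linalg.det(evecs) < 0:
            evecs[:, 0] = -evecs[:, 0]
        xx, yy, zz = evals
        dchi_ax = zz - (xx + yy) / 2.0
        dchi_rh = xx - yy
        scale = max(1.0, float(np.abs(evals).max()))
        degenerate = (
            abs(zz - yy) < 1e-10 * scale or abs(yy - xx) < 1e-10 * scale
        )
        if degenerate:
            angles = (0.0, 0.0, 0.0)
        else:
            angles = _euler_from_rotation(evecs)
        return float(dchi_ax), float(dchi_rh), angles, degenerate

    @property
    def dchi_ax(self) -> float:
        return self.principal()[0]

    @property
    def dchi_rh(self) -> float:
        return self.principal()[1]

    def norm(self) -> float:
        """Frobenius norm of the Cartesian tensor."""
        return float(np.linalg.norm(self.as_matrix()))

    def rotated(self, rotation: np.ndarray) -> "DeltaChiTensor":
        """Tensor after an active rotation of the molecular frame."""
        r = np.asarray(rotation, dtype=float)
        return DeltaChiTensor.from_matrix(r @ self.as_matrix() @ r.T)

    # -- serialization -------------------------------------------------

    def to_text(self, label: str = "tensor") -> str:
        ax, rh, (a, b, g), degen = self.principal()
        lines = [
            f"# {label}: delta-chi tensor, units 1e-32 m^3, angles deg (ZYZ)",
            "chi_xx = %.10g" % self.chi_xx,
            "chi_yy = %.10g" % self.chi_yy,
            "chi_xy = %.10g" % self.chi_xy,
            "chi_xz = %.10g" % self.chi_xz,
            "chi_yz = %.10g" % self.chi_yz,
            "dchi_ax = %.10g" % ax,
            "dchi_rh = %.10g" % rh,
            "alpha = %.6g" % a,
            "beta = %.6g" % b,
            "gamma = %.6g" % g,
            "degenerate = %s" % degen,
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "DeltaChiTensor":
        values = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
        comps = [float(values[k]) for k in ("chi_xx", "chi_yy", "chi_xy", "chi_xz", "chi_yz")]
        return cls.from_components(comps)


def tensor_convert(tensor: DeltaChiTensor, target: str = "paf"):
    """Convert between Cartesian-component and PAF representations.

    target="paf" returns a dict with keys dchi_ax, dchi_rh, alpha, beta,
    gamma, degenerate; target="components" accepts either a DeltaChiTensor
    or such a dict and returns a DeltaChiTensor.
    """
    if target == "paf":
        ax, rh, (a, b, g), degen = tensor.principal()
        return {
            "dchi_ax": ax,
            "dchi_rh": rh,
            "alpha": a,
            "beta": b,
            "gamma": g,
            "degenerate": degen,
        }
    if target == "components":
        if isinstance(tensor, DeltaChiTensor):
            return tensor
        return DeltaChiTensor.from_axial_rhombic(
            tensor["dchi_ax"],
            tensor["dchi_rh"],
            tensor.get("alpha", 0.0),
            tensor.get("beta", 0.0),
            tensor.get("gamma", 0.0),
        )
    raise ValueError(f"unknown target representation {target!r}")


# -- forward model -----------------------------------------------------


def pcs_design_row(position: np.ndarray, site: np.ndarray) -> np.ndarray:
    """Row of the linear design matrix mapping the 5 tensor components to δ_PC.

    δ = PCS_PREFACTOR · 3/r⁵ · [χxx(x²−z²) + χyy(y²−z²) + 2χxy·xy
        + 2χxz·xz + 2χyz·yz]  with (x,y,z) = position − site.
    """
    d = np.asarray(position, dtype=float) - np.asarray(site, dtype=float)
    r2 = float(d @ d)
    r = math.sqrt(r2)
    if r < SINGULARITY_GUARD:
        raise SingularityError(
            f"nucleus {r:.3f} Å from the metal (guard {SINGULARITY_GUARD} Å)"
        )
    x, y, z = d
    k = PCS_PREFACTOR * 3.0 / r2 ** 2.5
    return k * np.array(
        [x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z]
    )


def pcs_design_matrix(positions: np.ndarray, site: np.ndarray) -> np.ndarray:
    """Vectorized design matrix, one row per nuclear position."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    d = pos - np.asarray(site, dtype=float)
    r2 = np.einsum("ij,ij->i", d, d)
    if np.any(r2 < SINGULARITY_GUARD**2):
        bad = int(np.argmin(r2))
        raise SingularityError(
            f"nucleus {math.sqrt(r2[bad]):.3f} Å from the metal "
            f"(guard {SINGULARITY_GUARD} Å)"
        )
    x, y, z = d[:, 0], d[:, 1], d[:, 2]
    k = PCS_PREFACTOR * 3.0 / r2**2.5
    return (
        k[:, None]
        * np.stack([x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z], axis=1)
    )


def pcs_forward(
    tensor: DeltaChiTensor, site: MetalSite | np.ndarray, position
) -> float:
    """Back-calculate the PCS (ppm) at one nuclear position (Å)."""
    site_xyz = site.as_array() if isinstance(site, MetalSite) else np.asarray(site, float)
    row = pcs_design_row(np.asarray(position, dtype=float), site_xyz)
    return float(row @ tensor.components)


def pcs_forward_many(tensor: DeltaChiTensor, site, positions) -> np.ndarray:
    site_xyz = site.as_array() if isinstance(site, MetalSite) else np.asarray(site, float)
    return pcs_design_matrix(positions, site_xyz) @ tensor.components


def pcs_forward_polar(
    dchi_ax: float, dchi_rh: float, r: float, theta: float, omega: float = 0.0
) -> float:
    """Direct polar-coordinate evaluation (r in Å, angles in radians)."""
    if r < SINGULARITY_GUARD:
        raise SingularityError(f"r={r:.3f} Å inside the singularity guard")
    ct = math.cos(theta)
    st = math.sin(theta)
    return (PCS_PREFACTOR / r**3) * (
        dchi_ax * (3 * ct * ct - 1) + 1.5 * dchi_rh * st * st * math.cos(2 * omega)
    )
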