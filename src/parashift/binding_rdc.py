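"""1:1 metal-binding equilibrium, Kd titration fitting, and self-alignment RDC limits.

At NMR concentrations (hundreds of µM) a site with Kd in the hundreds of nM
binds almost quantitatively; the closed-form 1:1 quadratic below quantifies
that.  A paramagnetic center with anisotropic susceptibility also partially
aligns the molecule in the field, producing residual dipolar couplings
(pRDC); ``max_rdc`` predicts the largest coupling for a given spin pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .pcs_core import DeltaChiTensor

# CODATA 2018
HBAR = 1.054571817e-34  # J s
K_BOLTZMANN = 1.380649e-23  # J/K
GAMMA_1H = 2.6752218744e8  # rad s^-1 T^-1
GAMMA_13C = 6.728284e7
GAMMA_31P = 1.08394e8
GAMMA_15N = -2.7116e7


class IdentifiabilityWarning(UserWarning):
    """Titration data do not constrain Kd."""


@dataclass(frozen=True)
class BindingSystem:
    """1:1 ligand-metal equilibrium: L + M <-> LM with dissociation constant Kd."""

    ligand_total: float  # molar
    metal_total: float  # molar
    kd: float  # molar

    def __post_init__(self):
        if self.ligand_total < 0 or self.metal_total < 0 or self.kd < 0:
            raise ValueError("concentrations and Kd must be non-negative")


def complex_concentration(ligand_total: float, metal_total: float, kd: float) -> float:
    """[LM] from the 1:1 mass-balance quadratic, cancellation-free.

    [LM]² − (L+M+Kd)[LM] + LM = 0; the physical root is written as
    2LM / (b + sqrt(b² − 4LM)) with b = L+M+Kd, which avoids subtracting
    nearly equal numbers when binding is nearly stoichiometric.
    """
    if ligand_total < 0 or metal_total < 0 or kd < 0:
        raise ValueError("concentrations and Kd must be non-negative")
    if ligand_total == 0 or metal_total == 0:
        return 0.0
    b = ligand_total + metal_total + kd
    disc = b * b - 4.0 * ligand_total * metal_total
    return 2.0 * ligand_total * metal_total / (b + math.sqrt(max(disc, 0.0)))


def bound_fraction(system: BindingSystem) -> float:
    """Fraction of the metal in the bound state, in [0, 1]."""
    if system.metal_total <= 0:
        raise ValueError("metal_total must be positive")
    frac = complex_concentration(system.ligand_total, system.metal_total, system.kd)
    return min(1.0, frac / system.metal_total)


def bound_fraction_ligand(system: BindingSystem) -> float:
    """Fraction of the ligand (oligonucleotide) in the bound state."""
    if system.ligand_total <= 0:
        raise ValueError("ligand_total must be positive")
    frac = complex_concentration(system.ligand_total, system.metal_total, system.kd)
    return min(1.0, frac / system.ligand_total)


# ---------------------------------------------------------------------------
# titration fitting
# ---------------------------------------------------------------------------


def fit_kd_titration(points, ligand_total: float, model: str = "1to1") -> dict:
    """Fit Kd from a titration of signal vs total metal.

    ``points`` is an iterable of (metal_total, signal) or a 2-column array.
    The observable is modeled as linear in the bound fraction of the ligand
    (the signal reports on the oligonucleotide's conformation):

        signal(M) = s_free + (s_bound − s_free) · f_bound_ligand(M; Kd)

    Returns a dict with kd, kd_stderr, kd_ci95, signal_free, signal_bound,
    residuals.  Saturated designs (no sub-stoichiometric information) emit
    IdentifiabilityWarning and a wide interval.
    """
    if model != "1to1":
        raise ValueError("only the 1:1 model is implemented")
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
        raise ValueError("need >= 4 (metal_total, signal) points")
    metal, signal = pts[:, 0], pts[:, 1]

    def model_fn(m, kd, s_free, s_bound):
        frac = np.array(
            [
                complex_concentration(ligand_total, mi, max(kd, 0.0)) / ligand_total
                for mi in m
            ]
        )
        return s_free + (s_bound - s_free) * frac

    s_free0 = signal[np.argmin(metal)]
    s_bound0 = signal[np.argmax(metal)]
    kd0 = max(ligand_total / 10.0, 1e-12)
    popt, pcov = curve_fit(
        model_fn,
        metal,
        signal,
        p0=[kd0, s_free0, s_bound0],
        bounds=([0.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    kd, s_free, s_bound = popt
    kd_err = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    resid = signal - model_fn(metal, *popt)

    # the design carries no Kd information when the ligand is essentially
    # fully bound already at the smallest titration point
    positive = metal[metal > 0]
    saturated = False
    if len(positive):
        frac_min = complex_concentration(ligand_total, positive.min(), kd) / ligand_total
        saturated = frac_min > 0.95
    if saturated or not np.isfinite(kd_err) or kd_err > 10 * max(kd, 1e-30):
        warnings.warn(
            "titration points do not sample the sub-stoichiometric regime; "
            "Kd is poorly identified",
            IdentifiabilityWarning,
            stacklevel=2,
        )
        kd_err = max(kd_err, 10.0 * max(kd, ligand_total))
    return {
        "kd": float(kd),
        "kd_stderr": kd_err,
        "kd_ci95": (float(kd - 1.96 * kd_err), float(kd + 1.96 * kd_err)),
        "signal_free": float(s_free),
        "signal_bound": float(s_bound),
        "residuals": resid,
    }


# ---------------------------------------------------------------------------
# self-alignment RDC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RDCSpec:
    """Inputs for a self-alignment RDC prediction.

    B0 in tesla, temperature in kelvin, gyromagnetic ratios in rad s⁻¹ T⁻¹,
    internuclear distance r in Å, Δχ tensor in 10⁻³² m³.
    """

    b0: float
    temperature: float
    gamma_a: float
    gamma_b: float
    r: float
    tensor: DeltaChiTensor

    def __post_init__(self):
        if self.b0 <= 0 or self.temperature <= 0 or self.r <= 0:
            raise ValueError("B0, temperature and r must be positive")
        if self.r < 0.5:
            raise ValueError("internuclear distance below 0.5 Å is unphysical")


def field_from_proton_mhz(mhz: float) -> float:
    """Magnetic field (T) of a spectrometer quoted by its ¹H frequency."""
    return 2.0 * math.pi * mhz * 1e6 / GAMMA_1H


def rdc_angular(dchi_ax: float, dchi_rh: float, theta: float, omega: float) -> float:
    """Angular factor Δχax(3cos²θ−1) + 1.5·Δχrh·sin²θ·cos2Ω (same units as Δχ)."""
    ct, st = math.cos(theta), math.sin(theta)
    return dchi_ax * (3 * ct * ct - 1) + 1.5 * dchi_rh * st * st * math.cos(2 * omega)


def rdc_forward(spec: RDCSpec, theta: float, omega: float) -> float:
    """Self-alignment RDC (Hz) for an internuclear vector at (θ, Ω) in the PAF."""
    ax, rh, _, _ = spec.tensor.principal()
    prefac = (spec.b0**2 / (15.0 * K_BOLTZMANN * spec.temperature)) * (
        spec.gamma_a * spec.gamma_b * HBAR / (8.0 * math.pi**2 * (spec.r * 1e-10) ** 3)
    )
    return -prefac * rdc_angular(ax * 1e-32, rh * 1e-32, theta, omega)


def max_rdc(spec: RDCSpec) -> float:
    """Maximum |RDC| (Hz) over internuclear-vector orientations.

    The angular factor is extremal on the principal axes, taking the values
    2Δχax (z), −Δχax + 1.5Δχrh (x) and −Δχax − 1.5Δχrh (y); the maximum
    magnitude among them gives the bound.
    """
    ax, rh, _, _ = spec.tensor.principal()
    extrema = [2.0 * ax, -ax + 1.5 * rh, -ax - 1.5 * rh]
    peak = max(abs(v) for v in extrema) * 1e-32
    prefac = (spec.b0**2 / (15.0 * K_BOLTZMANN * spec.temperature)) * (
        spec.gamma_a * spec.gamma_b * HBAR / (8.0 * math.pi**2 * (spec.r * 1e-10) ** 3)
    )
    return abs(prefac) * peak
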