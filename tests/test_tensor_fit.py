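"""Tensor/position fitting, Q-factors, cross-validation and uncertainties."""

import numpy as np
import pandas as pd
import pytest

from parashift.io_formats import PCSDataset, Structure
from parashift.pcs_core import DeltaChiTensor, MetalSite, pcs_design_matrix, pcs_forward_many
from parashift.tensor_fit import (
    DegenerateGeometryError,
    FoldSizeError,
    UndefinedQError,
    cross_validate,
    fit_position_and_tensors,
    fit_tensor_fixed_position,
    mc_uncertainty,
    q_factor,
)


def _structure_from_positions(positions):
    n = len(positions)
    return Structure(
        np.arange(1, n + 1), ["DN"] * n, ["H1'"] * n, np.asarray(positions, float)
    )


def _dataset_from_values(structure, values, label="M", sigma=0.02):
    return PCSDataset(
        label,
        pd.DataFrame(
            {
                "residue_number": structure.residue_numbers,
                "atom_name": structure.atom_names,
                "pcs": values,
                "sigma": sigma,
            }
        ),
    )


@pytest.fixture
def general_cloud(rng):
    """20 atoms in general position, 6-14 Å from the origin site."""
    v = rng.normal(size=(20, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return _structure_from_positions(v * rng.uniform(6, 14, size=(20, 1)))


class TestQFactor:
    def test_perfect_fit(self):
        assert q_factor([0.4, -0.2, 1.0], [0.4, -0.2, 1.0]) == 0.0

    def test_hand_arithmetic(self):
        # sqrt((0.1² + 0.1²) / (1 + 1)) = 0.100
        assert q_factor([1.0, -1.0], [0.9, -0.9]) == pytest.approx(0.100, abs=1e-12)

    def test_null_model(self):
        assert q_factor([0.3, -0.5], [0.0, 0.0]) == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        obs = rng.normal(size=30)
        calc = obs + rng.normal(scale=0.1, size=30)
        for c in (2.0, -5.0, 1e-3):
            assert q_factor(c * obs, c * calc) == pytest.approx(
                q_factor(obs, calc), rel=1e-12
            )

    def test_all_zero_observed_undefined(self):
        with pytest.raises(UndefinedQError):
            q_factor([0.0, 0.0], [0.1, 0.2])


class TestFixedPositionFit:
    def test_exact_recovery_20_atoms(self, general_cloud, random_tensor):
        site = MetalSite(0, 0, 0)
        values = pcs_forward_many(random_tensor, site, general_cloud.coords)
        fit = fit_tensor_fixed_position(
            _dataset_from_values(general_cloud, values), general_cloud, site
        )
        assert np.abs(fit.tensor.components - random_tensor.components).max() < 1e-10
        assert fit.q_factor < 1e-10

    def test_five_atoms_match_pseudoinverse_oracle(self, rng, random_tensor):
        site = MetalSite(0, 0, 0)
        positions = rng.normal(scale=8.0, size=(5, 3)) + np.array([10.0, 0, 0])
        structure = _structure_from_positions(positions)
        values = pcs_forward_many(random_tensor, site, positions)
        fit = fit_tensor_fixed_position(
            _dataset_from_values(structure, values), structure, site
        )
        oracle = np.linalg.pinv(pcs_design_matrix(positions, site.as_array())) @ values
        np.testing.assert_allclose(fit.tensor.components, oracle, atol=1e-9)

    def test_collinear_atoms_degenerate(self):
        positions = np.outer(np.arange(5, 15), [1.0, 0.0, 0.0])
        structure = _structure_from_positions(positions)
        ds = _dataset_from_values(structure, np.linspace(0.1, 1.0, 10))
        with pytest.raises(DegenerateGeometryError, match="null space"):
            fit_tensor_fixed_position(ds, structure, MetalSite(0, 0, 0))

    def test_unbiased_over_noise_replicates(self, general_cloud, rng):
        truth = DeltaChiTensor.from_axial_rhombic(-3.0, 1.1, 20, 50, 70)
        site = MetalSite(0, 0, 0)
        clean = pcs_forward_many(truth, site, general_cloud.coords)
        sigma = 0.02
        estimates = []
        for _ in range(200):
            noisy = clean + rng.normal(scale=sigma, size=len(clean))
            fit = fit_tensor_fixed_position(
                _dataset_from_values(general_cloud, noisy), general_cloud, site
            )
            estimates.append(fit.tensor.principal()[0])
        estimates = np.asarray(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - truth.principal()[0]) < 3 * se

    def test_q_grows_with_noise(self, general_cloud, rng, random_tensor):
        site = MetalSite(0, 0, 0)
        clean = pcs_forward_many(random_tensor, site, general_cloud.coords)
        mean_q = []
        for sigma in (0.01, 0.05, 0.2):
            qs = [
                fit_tensor_fixed_position(
                    _dataset_from_values(
                        general_cloud, clean + rng.normal(scale=sigma, size=len(clean))
                    ),
                    general_cloud, site,
                ).q_factor
                for _ in range(30)
            ]
            mean_q.append(np.mean(qs))
        assert mean_q[0] < mean_q[1] < mean_q[2]


class TestJointFit:
    def test_four_metal_site_and_tensor_recovery(self, planted):
        fit = fit_position_and_tensors(
            planted["datasets"], planted["structure"], check_consistency=False
        )
        assert np.linalg.norm(
            fit.site.as_array() - planted["site"].as_array()
        ) < 0.01
        for f, truth in zip(fit.fits, planted["tensors"]):
            rel = np.abs(f.tensor.components - truth.components).max()
            rel /= np.abs(truth.components).max()
            assert rel < 1e-6

    def test_single_dataset_site_recovery(self, planted):
        fit = fit_position_and_tensors(
            [planted["datasets"][2]], planted["structure"]
        )
        assert np.linalg.norm(fit.site.as_array() - planted["site"].as_array()) < 0.05

    def test_joint_single_dataset_agrees_with_fixed_fit(self, planted):
        joint = fit_position_and_tensors([planted["datasets"][0]], planted["structure"])
        fixed = fit_tensor_fixed_position(
            planted["datasets"][0], planted["structure"], joint.site
        )
        np.testing.assert_allclose(
            joint.fits[0].tensor.components, fixed.tensor.components, atol=1e-10
        )

    def test_conflicting_sites_flagged(self, planted, rng):
        structure = planted["structure"]
        t1, t2 = planted["tensors"][:2]
        site_a = planted["site"].as_array()
        site_b = site_a + np.array([5.0, 0.0, 0.0])
        protons = structure.select(
            np.array([n.startswith("H") for n in structure.atom_names])
        )
        ds_a = _dataset_from_values(
            protons, pcs_forward_many(t1, site_a, protons.coords), "A"
        )
        ds_b = _dataset_from_values(
            protons, pcs_forward_many(t2, site_b, protons.coords), "B"
        )
        with pytest.warns(UserWarning, match="share one metal site"):
            joint = fit_position_and_tensors([ds_a, ds_b], structure)
        assert joint.inconsistent


class TestCrossValidation:
    def test_noiseless_loo_is_exact(self, planted):
        ds = planted["datasets"][0]
        q_work, q_free = cross_validate(
            ds, planted["structure"], planted["site"], scheme="loo"
        )
        assert q_free < 1e-8

    def test_qfree_dominates_qwork_under_noise(self, planted, rng):
        structure, site = planted["structure"], planted["site"]
        tensor = planted["tensors"][0]
        protons = structure.select(
            np.array([n.startswith("H") for n in structure.atom_names])
        )
        clean = pcs_forward_many(tensor, site.as_array(), protons.coords)
        wins = 0
        n_rep = 25
        for _ in range(n_rep):
            noisy = clean + rng.normal(scale=0.02, size=len(clean))
            ds = _dataset_from_values(protons, noisy)
            q_work, q_free = cross_validate(ds, structure, site, scheme="loo")
            wins += q_free >= q_work
        assert wins >= int(0.9 * n_rep)

    def test_holdout_nucleus_without_entries(self, planted):
        with pytest.raises(FoldSizeError):
            cross_validate(
                planted["datasets"][0], planted["structure"], planted["site"],
                holdout_nucleus="31P",
            )

    def test_phosphorus_holdout_never_trains(self, planted):
        # plant values for both H and P atoms, then hold out P entirely
        structure, site = planted["structure"], planted["site"]
        tensor = planted["tensors"][1]
        mask = np.array(
            [n.startswith(("H", "P")) for n in structure.atom_names]
        )
        atoms = structure.select(mask)
        values = pcs_forward_many(tensor, site.as_array(), atoms.coords)
        ds = _dataset_from_values(atoms, values)
        q_work, q_free = cross_validate(
            ds, structure, site, holdout_nucleus="31P"
        )
        assert q_free < 1e-8  # noiseless: the exact model generalizes to 31P


class TestUncertainty:
    def _small_problem(self, rng):
        v = rng.normal(size=(15, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        structure = _structure_from_positions(v * rng.uniform(6, 12, size=(15, 1)))
        truth = DeltaChiTensor.from_axial_rhombic(2.5, -0.8, 15, 40, 75)
        site = MetalSite(0, 0, 0)
        values = pcs_forward_many(truth, site.as_array(), structure.coords)
        ds = _dataset_from_values(structure, values)
        fit = fit_position_and_tensors([ds], structure, box=(-3 * np.ones(3), 3 * np.ones(3)))
        return structure, ds, fit

    def test_seeded_bootstrap_is_deterministic(self, rng):
        structure, ds, fit = self._small_problem(rng)
        a = mc_uncertainty(fit, [ds], structure, sigma=0.02, n_replicates=50, seed=7)
        b = mc_uncertainty(fit, [ds], structure, sigma=0.02, n_replicates=50, seed=7)
        assert a["M"]["dchi_ax_sd"] == b["M"]["dchi_ax_sd"]
        np.testing.assert_array_equal(a["site_sd"], b["site_sd"])

    def test_sd_scales_linearly_with_sigma(self, rng):
        structure, ds, fit = self._small_problem(rng)
        lo = mc_uncertainty(fit, [ds], structure, sigma=0.01, n_replicates=60, seed=3)
        hi = mc_uncertainty(fit, [ds], structure, sigma=0.02, n_replicates=60, seed=3)
        ratio = hi["M"]["dchi_ax_sd"] / lo["M"]["dchi_ax_sd"]
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_nonpositive_sigma_rejected(self, rng):
        structure, ds, fit = self._small_problem(rng)
        with pytest.raises(ValueError):
            mc_uncertainty(fit, [ds], structure, sigma=0.0, n_replicates=50)
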