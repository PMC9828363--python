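"""PCS pseudo-energy, refinement protocol and ensemble analytics."""

import numpy as np
import pandas as pd
import pytest

from parashift.io_formats import PCSDataset, Structure, StructureEnsemble
from parashift.pcs_core import MetalSite, pcs_forward_many
from parashift.refine_ensemble import (
    GeometryTemplate,
    PCSRestraintSet,
    RestraintMappingError,
    bundle_stats,
    geometry_energy_grad,
    interhelical_angle,
    iterate_tensor_structure,
    kabsch,
    pcs_energy_grad,
    refine_rigid_profile,
    refine_structure,
)
from parashift.synthetic_data import (
    HelixSpec,
    _rotation_axis_angle,
    helix_base_pairs,
    make_helix,
)
from parashift.tensor_fit import fit_tensor_fixed_position


def _restraints(planted, tolerance=0.0, force_constant=1.0, n_datasets=None):
    datasets = planted["datasets"][: (n_datasets or len(planted["datasets"]))]
    tensors = planted["tensors"][: len(datasets)]
    return PCSRestraintSet(datasets, tensors, planted["site"],
                           force_constant=force_constant, tolerance=tolerance)


class TestPCSEnergy:
    def test_flat_bottom_zero_at_truth(self, planted):
        # observations were generated from these tensors at this site
        restr = _restraints(planted, tolerance=0.05)
        e, ga, gs = pcs_energy_grad(planted["structure"], restr)
        assert e == 0.0
        np.testing.assert_array_equal(ga, 0.0)
        np.testing.assert_array_equal(gs, 0.0)

    def test_additivity_over_datasets(self, planted, rng):
        pert = planted["structure"].with_coords(
            planted["structure"].coords + rng.normal(scale=0.4, size=planted["structure"].coords.shape)
        )
        total = pcs_energy_grad(pert, _restraints(planted))[0]
        parts = sum(
            pcs_energy_grad(
                pert,
                PCSRestraintSet([ds], [t], planted["site"], 1.0, 0.0),
            )[0]
            for ds, t in zip(planted["datasets"], planted["tensors"])
        )
        assert total == pytest.approx(parts, abs=1e-12)

    def test_gradient_matches_finite_differences(self, planted, rng):
        structure = planted["structure"]
        restr = _restraints(planted, tolerance=0.02)
        h = 1e-5
        for _ in range(6):
            pert = structure.with_coords(
                structure.coords + rng.normal(scale=0.3, size=structure.coords.shape)
            )
            e, ga, gs = pcs_energy_grad(pert, restr)
            # random atom coordinates
            for _ in range(4):
                i = rng.integers(pert.n_atoms)
                j = rng.integers(3)
                cp, cm = pert.coords.copy(), pert.coords.copy()
                cp[i, j] += h
                cm[i, j] -= h
                fd = (
                    pcs_energy_grad(pert.with_coords(cp), restr)[0]
                    - pcs_energy_grad(pert.with_coords(cm), restr)[0]
                ) / (2 * h)
                assert ga[i, j] == pytest.approx(fd, rel=1e-6, abs=1e-9)
            # site coordinates
            for j in range(3):
                sp, sm = planted["site"].as_array().copy(), planted["site"].as_array().copy()
                sp[j] += h
                sm[j] -= h
                rp = PCSRestraintSet(restr.datasets, restr.tensors,
                                     MetalSite.from_array(sp), 1.0, 0.02)
                rm = PCSRestraintSet(restr.datasets, restr.tensors,
                                     MetalSite.from_array(sm), 1.0, 0.02)
                fd = (pcs_energy_grad(pert, rp)[0] - pcs_energy_grad(pert, rm)[0]) / (2 * h)
                assert gs[j] == pytest.approx(fd, rel=1e-6, abs=1e-9)

    def test_missing_restrained_atom(self, planted):
        ds = planted["datasets"][0]
        bad = PCSDataset(
            "ghost",
            pd.DataFrame(
                {"residue_number": [999], "atom_name": ["H1'"], "pcs": [0.1], "sigma": [0.02]}
            ),
        )
        restr = PCSRestraintSet([bad], [planted["tensors"][0]], planted["site"])
        with pytest.raises(RestraintMappingError):
            pcs_energy_grad(planted["structure"], restr)


class TestRefinement:
    def test_stationary_at_planted_minimum(self, planted):
        structure = planted["structure"]
        geometry = GeometryTemplate.from_structure(structure, cutoff=5.0)
        restr = _restraints(planted)
        final, trace = refine_structure(structure, geometry, restr, steps=50)
        assert np.abs(final.coords - structure.coords).max() < 1e-6
        assert trace[0] == pytest.approx(0.0, abs=1e-18)

    def test_energy_trace_monotone_and_q_improves(self, planted, rng):
        structure = planted["structure"]
        geometry = GeometryTemplate.from_structure(structure, cutoff=5.0)
        restr = _restraints(planted, force_constant=5.0)
        start = structure.with_coords(
            structure.coords + rng.normal(scale=0.5, size=structure.coords.shape)
        )

        def q_of(s):
            return fit_tensor_fixed_position(
                planted["datasets"][0], s, planted["site"]
            ).q_factor

        final, trace = refine_structure(start, geometry, restr, steps=400)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))
        assert q_of(final) < q_of(start)

    def test_pcs_restraints_pull_toward_truth(self, planted, rng):
        # rotate one helix; geometry alone cannot restore the orientation
        structure = planted["structure"]
        truth = planted["truth"]
        helix2 = set(range(13, 25))
        blocks = [set(range(1, 13)), helix2]
        geometry = GeometryTemplate.from_structure(structure, cutoff=6.0, blocks=blocks)
        mask = np.array([int(rn) in helix2 for rn in structure.residue_numbers])
        rot = _rotation_axis_angle([0, 1, 0], 12.0)
        pivot = truth["junction"]
        coords = structure.coords.copy()
        coords[mask] = (coords[mask] - pivot) @ rot.T + pivot
        start = structure.with_coords(coords)

        s_geo, _ = refine_structure(start, geometry, None, steps=150)
        s_pcs, _, _ = refine_rigid_profile(
            start, planted["datasets"], blocks, planted["site"]
        )
        rmsd = lambda s: np.sqrt(np.mean(np.sum((s.coords - structure.coords) ** 2, axis=1)))
        assert rmsd(s_pcs) < rmsd(s_geo)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergent_step_raises(self, planted):
        structure = planted["structure"]
        # absurd template target forces a NaN-free but huge gradient; a
        # divergent energy must be reported, not silently accepted
        geometry = GeometryTemplate(
            [(structure.atom_keys()[0], structure.atom_keys()[1])], [1e300], [1e300]
        )
        with pytest.raises(FloatingPointError):
            refine_structure(structure, geometry, None, steps=5, step_size=1e280)


class TestIterativeProtocol:
    def test_fixed_point_at_ground_truth(self, planted):
        structure = planted["structure"]
        geometry = GeometryTemplate.from_structure(structure, cutoff=5.0)
        out = iterate_tensor_structure(
            structure, planted["datasets"], geometry,
            max_rounds=5, refine_steps=50,
            box=(planted["site"].as_array() - 5, planted["site"].as_array() + 5),
        )
        assert out["converged"]
        assert out["rounds"][0]["round"] == 1
        assert len(out["rounds"]) == 1
        for f, truth in zip(out["fit"].fits, planted["tensors"]):
            rel = np.abs(f.tensor.components - truth.components).max()
            rel /= np.abs(truth.components).max()
            assert rel < 1e-6

    def test_recovers_from_rotated_start(self, planted, rng):
        structure = planted["structure"]
        truth = planted["truth"]
        helix2 = set(range(13, 25))
        blocks = [set(range(1, 13)), helix2]
        geometry = GeometryTemplate.from_structure(structure, cutoff=6.0, blocks=blocks)
        mask = np.array([int(rn) in helix2 for rn in structure.residue_numbers])
        coords = structure.coords.copy()
        pivot = truth["junction"]
        coords[mask] = (coords[mask] - pivot) @ _rotation_axis_angle([0, 1, 0], 15.0).T + pivot
        start = structure.with_coords(coords)
        out = iterate_tensor_structure(
            start, planted["datasets"], geometry,
            max_rounds=10, refine_steps=100, blocks=blocks,
            box=(pivot - 8, pivot + 8),
        )
        assert len(out["rounds"]) <= 10
        for f, truth_t in zip(out["fit"].fits, planted["tensors"]):
            # compare in component space: PAF labels are unstable for
            # near-maximally-rhombic tensors
            rel = np.abs(f.tensor.components - truth_t.components).max()
            rel /= np.abs(truth_t.components).max()
            assert rel < 0.05

    def test_zero_rounds_returns_initial_fit(self, planted):
        out = iterate_tensor_structure(
            planted["structure"], planted["datasets"], None, max_rounds=0,
            box=(planted["site"].as_array() - 5, planted["site"].as_array() + 5),
        )
        assert out["converged"] is False
        assert out["rounds"] == []
        assert len(out["fit"].fits) == 4


class TestBundleStats:
    def test_identical_models_zero_rmsd(self, junction):
        structure, _ = junction
        ens = StructureEnsemble([
            Structure(structure.residue_numbers, structure.residue_names,
                      structure.atom_names, structure.coords, i + 1)
            for i in range(3)
        ])
        stats = bundle_stats(ens)
        assert stats.pairwise_rmsd_mean == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_is_invisible(self, junction, rng):
        structure, _ = junction
        rot = _rotation_axis_angle(rng.normal(size=3), 73.0)
        moved = structure.coords @ rot.T + np.array([5.0, -3.0, 8.0])
        ens = StructureEnsemble([
            structure,
            Structure(structure.residue_numbers, structure.residue_names,
                      structure.atom_names, moved, 2),
        ])
        assert bundle_stats(ens).pairwise_rmsd_mean == pytest.approx(0.0, abs=1e-9)

    def test_global_transform_of_whole_ensemble_invariant(self, junction, rng):
        structure, _ = junction
        models = [
            Structure(structure.residue_numbers, structure.residue_names,
                      structure.atom_names,
                      structure.coords + rng.normal(scale=0.5, size=structure.coords.shape),
                      i + 1)
            for i in range(3)
        ]
        before = bundle_stats(StructureEnsemble(models)).pairwise_rmsd_mean
        rot = _rotation_axis_angle([1, 2, 3], 41.0)
        moved = [
            Structure(m.residue_numbers, m.residue_names, m.atom_names,
                      m.coords @ rot.T + 7.0, m.model_id)
            for m in models
        ]
        after = bundle_stats(StructureEnsemble(moved)).pairwise_rmsd_mean
        assert after == pytest.approx(before, abs=1e-9)

    def test_single_displaced_atom_formula(self, rng):
        # superpose on N−1 identical atoms: the one atom moved by d gives
        # full-selection RMSD d/sqrt(N)
        n, d = 40, 1.3
        coords = rng.normal(scale=6.0, size=(n, 3))
        moved = coords.copy()
        moved[0] += np.array([d, 0.0, 0.0])
        rot, trans, _ = kabsch(moved[1:], coords[1:])
        aligned = moved @ rot.T + trans
        rmsd = np.sqrt(np.mean(np.sum((aligned - coords) ** 2, axis=1)))
        assert rmsd == pytest.approx(d / np.sqrt(n), rel=1e-6)

    def test_metal_spread(self, junction, rng):
        structure, truth = junction
        site = truth["junction"]
        models, metals = [], []
        for i in range(4):
            models.append(
                Structure(structure.residue_numbers, structure.residue_names,
                          structure.atom_names, structure.coords, i + 1)
            )
            metals.append(site + rng.normal(scale=0.1, size=3))
        stats = bundle_stats(StructureEnsemble(models), metal_positions=np.array(metals))
        assert 0.0 < stats.metal_spread_rmsd < 0.5

    def test_too_small_selection(self, junction):
        structure, _ = junction
        ens = StructureEnsemble([structure, structure])
        with pytest.raises(ValueError, match="at least 3 atoms"):
            bundle_stats(ens, selection=structure.atom_keys()[:2])


class TestInterhelicalAngle:
    def test_straight_duplex_halves_are_collinear(self):
        spec = HelixSpec(n_bp=10)
        helix = make_helix(spec)
        bp = helix_base_pairs(spec)
        angle = interhelical_angle(helix, bp[:5], bp[5:])
        assert angle == pytest.approx(0.0, abs=1.0)

    def test_constructed_angle_is_recovered(self, junction):
        structure, truth = junction
        bp = truth["base_pairs"]
        angle = interhelical_angle(structure, bp[0], bp[1])
        assert angle == pytest.approx(113.0, abs=1.0)

    def test_requires_three_base_pairs(self, junction):
        structure, truth = junction
        bp = truth["base_pairs"]
        with pytest.raises(ValueError, match="3 base pairs"):
            interhelical_angle(structure, bp[0], bp[1][:2])
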