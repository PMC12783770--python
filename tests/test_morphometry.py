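import numpy as np
import pytest

from conftest import ball_voxels

from neuritelab.morphometry import (
    NeuronReconstruction,
    coverage_fraction,
    depth_profile,
    grid_box_coverage,
    grid_boxes,
    sholl_topview,
    soma_composition,
    soma_diameter,
    synapse_depth_distribution,
)
from neuritelab.volume import LayerAnnotation

UM_VOXEL = (1000.0, 1000.0, 1000.0)  # 1 um isotropic voxels


@pytest.fixture()
def ipl_layers():
    # IPL spans sections 10..109 -> depth resolution 0.01 per section
    return LayerAnnotation(gcl_ipl=10, ipl_inl=110, n_sections=120)


def uniform_tube(ipl_layers):
    """One dendrite voxel per IPL section: a tube spanning the full depth."""
    zs = np.arange(ipl_layers.gcl_ipl, ipl_layers.ipl_inl)
    return np.column_stack([zs, np.full_like(zs, 5), np.full_like(zs, 5)])


class TestDepthProfile:
    def test_point_mass_lands_in_one_bin(self, ipl_layers):
        z = 105  # depth 0.05
        vox = np.array([[z, 1, 1]] * 7)
        prof = depth_profile(vox, ipl_layers, n_bins=10)
        assert prof.density[0] == 1.0
        assert prof.density[1:].sum() == 0.0

    def test_uniform_tube_is_flat(self, ipl_layers):
        prof = depth_profile(uniform_tube(ipl_layers), ipl_layers, n_bins=10)
        assert prof.density.sum() == pytest.approx(1.0)
        assert np.all(np.abs(prof.density - 0.1) <= 0.02)

    def test_density_sums_to_one_and_is_order_invariant(self, ipl_layers):
        rng = np.random.default_rng(0)
        vox = np.column_stack(
            [rng.integers(10, 110, 500), rng.integers(0, 50, 500), rng.integers(0, 50, 500)]
        )
        prof = depth_profile(vox, ipl_layers, n_bins=8)
        shuffled = depth_profile(rng.permutation(vox), ipl_layers, n_bins=8)
        assert prof.density.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(prof.density, shuffled.density)

    def test_out_of_ipl_voxels_excluded(self, ipl_layers):
        vox = np.vstack([uniform_tube(ipl_layers), [[2, 0, 0], [115, 0, 0]]])
        prof = depth_profile(vox, ipl_layers, n_bins=10)
        assert prof.n_excluded == 2
        assert prof.n_voxels == 100

    def test_no_ipl_voxels_rejected(self, ipl_layers):
        with pytest.raises(ValueError):
            depth_profile(np.array([[2, 0, 0]]), ipl_layers)

    @pytest.mark.parametrize(
        "off_share,expected",
        [(0.9, "OFF"), (0.1, "ON"), (0.5, "ON_OFF")],
    )
    def test_stratification_call_from_dominance(self, ipl_layers, off_share, expected):
        n = 1000
        n_off = int(n * off_share)
        off_z = np.full(n_off, 105)  # depth 0.05 -> OFF sublamina
        on_z = np.full(n - n_off, 30)  # depth 0.80 -> ON sublamina
        zs = np.concatenate([off_z, on_z])
        vox = np.column_stack([zs, np.zeros_like(zs), np.zeros_like(zs)])
        assert depth_profile(vox, ipl_layers).classify() == expected


class TestShollTopview:
    def test_single_radial_dendrite(self):
        # straight 50-um dendrite heading +x from the soma
        soma = (5.5, 10.5, 10.5)
        cols = np.arange(11, 61)
        vox = np.column_stack([np.full_like(cols, 5), np.full_like(cols, 10), cols])
        prof = sholl_topview(vox, soma, UM_VOXEL, ring_spacing_um=5.0, max_radius_um=60.0)
        expected = (prof.radii_um <= 50.0).astype(int)
        np.testing.assert_array_equal(prof.counts, expected)

    def test_no_dendrites_all_zero(self):
        prof = sholl_topview(
            np.empty((0, 3), dtype=int), (0.0, 5.0, 5.0), UM_VOXEL, max_radius_um=20.0
        )
        assert prof.counts.sum() == 0

    def test_star_counts_equal_arm_number(self):
        # 4 straight arms (E, N, W, S) of 30 um each
        soma = (0.5, 50.5, 50.5)
        arms = []
        for dr, dc in ((0, 1), (-1, 0), (0, -1), (1, 0)):
            steps = np.arange(1, 31)
            arms.append(
                np.column_stack(
                    [np.zeros_like(steps), 50 + dr * steps, 50 + dc * steps]
                )
            )
        vox = np.concatenate(arms)
        prof = sholl_topview(vox, soma, UM_VOXEL, ring_spacing_um=5.0, max_radius_um=40.0)
        inside = prof.radii_um <= 30.0
        assert np.all(prof.counts[inside] == 4)
        assert np.all(prof.counts[~inside] == 0)

    def test_y_branch_steps_from_one_to_two(self):
        # stem 20 um along +x, then two 45-degree branches out to ~45 um
        soma = (0.5, 60.5, 10.5)
        stem_cols = np.arange(11, 31)
        stem = np.column_stack(
            [np.zeros_like(stem_cols), np.full_like(stem_cols, 60), stem_cols]
        )
        steps = np.arange(1, 19)
        up = np.column_stack([np.zeros_like(steps), 60 - steps, 30 + steps])
        down = np.column_stack([np.zeros_like(steps), 60 + steps, 30 + steps])
        vox = np.concatenate([stem, up, down])
        prof = sholl_topview(vox, soma, UM_VOXEL, ring_spacing_um=5.0, max_radius_um=50.0)
        assert np.all(prof.counts[prof.radii_um <= 15.0] == 1)
        assert np.all(prof.counts[(prof.radii_um >= 25.0) & (prof.radii_um <= 40.0)] == 2)


class TestCoverage:
    def test_bounds(self):
        box = (0, 10, 0, 10)
        assert coverage_fraction(np.empty((0, 3), dtype=int), box) == 0.0
        full = np.array([(0, r, c) for r in range(10) for c in range(10)])
        assert coverage_fraction(full, box) == 1.0

    def test_two_pixel_tube_through_box(self):
        # projected width 2 px crossing a 100x100 box parallel to an edge
        vox = np.array(
            [(z, r, c) for z in range(3) for r in (40, 41) for c in range(100)]
        )
        assert coverage_fraction(vox, (0, 100, 0, 100)) == pytest.approx(0.02)

    def test_additive_for_disjoint_projections(self):
        a = np.array([(0, 1, c) for c in range(10)])
        b = np.array([(0, 5, c) for c in range(10)])
        box = (0, 10, 0, 10)
        both = coverage_fraction(np.vstack([a, b]), box)
        assert both == pytest.approx(
            coverage_fraction(a, box) + coverage_fraction(b, box)
        )

    def test_monotone_under_superset(self):
        rng = np.random.default_rng(2)
        vox = np.column_stack(
            [rng.integers(0, 5, 300), rng.integers(0, 50, 300), rng.integers(0, 50, 300)]
        )
        box = (0, 50, 0, 50)
        assert coverage_fraction(vox[:100], box) <= coverage_fraction(vox, box)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            coverage_fraction(np.empty((0, 3)), (5, 5, 0, 10))


class TestGridBoxCoverage:
    def test_uniform_pattern_gives_equal_boxes(self):
        # every other column covered everywhere -> every box at 0.5
        vox = np.array([(0, r, c) for r in range(100) for c in range(0, 100, 2)])
        report = grid_box_coverage(
            vox, np.empty((0, 3), dtype=int), (100, 100), (5, 5), n_boxes=5, seed=0
        )
        np.testing.assert_allclose(report.fractions, 0.5)
        assert report.mean == report.min == report.max == 0.5

    def test_soma_boxes_excluded_and_seeded_selection(self):
        vox = np.array([(0, r, c) for r in range(100) for c in range(0, 100, 2)])
        soma = np.array([(0, 10, 10)])  # occupies box (0, 0)
        a = grid_box_coverage(vox, soma, (100, 100), (5, 5), n_boxes=24, seed=3)
        assert (0, 0) not in a.box_indices
        b = grid_box_coverage(vox, soma, (100, 100), (5, 5), n_boxes=5, seed=3)
        c = grid_box_coverage(vox, soma, (100, 100), (5, 5), n_boxes=5, seed=3)
        assert b.box_indices == c.box_indices
        with pytest.raises(ValueError):
            grid_box_coverage(vox, soma, (100, 100), (5, 5), n_boxes=25, seed=0)

    def test_report_matches_direct_recount(self):
        rng = np.random.default_rng(9)
        vox = np.column_stack(
            [rng.integers(0, 8, 4000), rng.integers(0, 100, 4000), rng.integers(0, 100, 4000)]
        )
        report = grid_box_coverage(
            vox, np.empty((0, 3), dtype=int), (100, 100), (5, 5), n_boxes=5, seed=1
        )
        boxes = grid_boxes((100, 100), (5, 5))
        for idx, frac in zip(report.box_indices, report.fractions):
            r0, r1, c0, c1 = boxes[idx]
            proj = np.zeros((100, 100), dtype=bool)
            proj[vox[:, 1], vox[:, 2]] = True
            assert frac == pytest.approx(proj[r0:r1, c0:c1].mean())
        assert report.min <= report.mean <= report.max


class TestSomaMetrics:
    def test_nucleus_filling_whole_soma(self):
        soma = ball_voxels((20, 20, 20), 6)
        recon = NeuronReconstruction(
            neuron_id=1,
            soma_voxels=soma,
            dendrite_voxels=np.empty((0, 3), dtype=int),
            nucleus_voxels=soma.copy(),
        )
        comp = soma_composition(recon, UM_VOXEL)
        assert comp["nucleus_pct"] == pytest.approx(100.0)

    def test_concentric_spheres_volume_ratio(self):
        # nucleus radius half the soma radius -> (1/2)^3 = 12.5 %
        soma = ball_voxels((0, 0, 0), 10)
        nucleus = ball_voxels((0, 0, 0), 5)
        recon = NeuronReconstruction(
            neuron_id=1,
            soma_voxels=soma,
            dendrite_voxels=np.empty((0, 3), dtype=int),
            nucleus_voxels=nucleus,
        )
        comp = soma_composition(recon, UM_VOXEL)
        assert comp["nucleus_pct"] == pytest.approx(12.5, abs=1.0)

    def test_mitochondria_count_density(self):
        soma = np.array([(0, r, c) for r in range(10) for c in range(10)])  # 100 um^3
        mitos = [soma[i : i + 1] for i in range(10)]
        recon = NeuronReconstruction(
            neuron_id=1,
            soma_voxels=soma,
            dendrite_voxels=np.empty((0, 3), dtype=int),
            mitochondria=mitos,
        )
        comp = soma_composition(recon, UM_VOXEL)
        assert comp["mitochondria_per_um3"] == pytest.approx(0.1)
        assert comp["mitochondria_pct"] == pytest.approx(10.0)

    def test_organelles_outside_soma_rejected(self):
        recon = NeuronReconstruction(
            neuron_id=1,
            soma_voxels=np.array([(0, 0, 0)]),
            dendrite_voxels=np.empty((0, 3), dtype=int),
            nucleus_voxels=np.array([(5, 5, 5)]),
        )
        with pytest.raises(ValueError, match="outside"):
            soma_composition(recon, UM_VOXEL)

    def test_sphere_diameter(self):
        soma = ball_voxels((10, 10, 10), 5)
        d = soma_diameter(soma, UM_VOXEL)
        assert d == pytest.approx(10.0, abs=1.0)  # within one voxel
        shifted = soma + np.array([3, 7, 2])
        assert soma_diameter(shifted, UM_VOXEL) == pytest.approx(d)

    def test_single_voxel_diameter(self):
        d = soma_diameter(np.array([(0, 0, 0)]), UM_VOXEL)
        assert d == pytest.approx(2.0 / np.sqrt(np.pi))

    def test_empty_soma_rejected(self):
        with pytest.raises(ValueError):
            soma_diameter(np.empty((0, 3)), UM_VOXEL)


class TestSynapseDepth:
    def test_proportional_placement_correlates(self, ipl_layers):
        # dendrite mass peaked in the OFF sublamina, synapses on every voxel
        rng = np.random.default_rng(4)
        zs = np.clip(rng.normal(95, 8, 400).astype(int), 10, 109)
        vox = np.column_stack([zs, rng.integers(0, 30, 400), rng.integers(0, 30, 400)])
        result = synapse_depth_distribution(vox, vox, ipl_layers, n_bins=10)
        assert result["rank_correlation"] >= 0.8
        assert result["synapse_counts"].sum() == 400

    def test_zero_synapses(self, ipl_layers):
        result = synapse_depth_distribution(
            np.empty((0, 3), dtype=int), uniform_tube(ipl_layers), ipl_layers
        )
        assert result["synapse_counts"].sum() == 0

    def test_concentrated_synapses(self, ipl_layers):
        tube = uniform_tube(ipl_layers)
        synapses = np.repeat(tube[:1], 5, axis=0)  # all at depth 1.0
        result = synapse_depth_distribution(synapses, tube, ipl_layers, n_bins=10)
        assert result["synapse_counts"][-1] == 5
        assert result["synapse_counts"][:-1].sum() == 0

    def test_off_dendrite_synapse_rejected(self, ipl_layers):
        tube = uniform_tube(ipl_layers)
        bad = np.array([[50, 20, 20]])
        with pytest.raises(ValueError, match=r"\(50, 20, 20\)"):
            synapse_depth_distribution(bad, tube, ipl_layers)


def test_reconstruction_from_phantom_truth(clean_phantom):
    cfg, vol, truth = clean_phantom
    recon = NeuronReconstruction.from_truth(truth, 1, vol.voxel_size_nm)
    assert recon.soma_voxels.size and recon.dendrite_voxels.size
    # soma centroid should sit near the configured centre
    np.testing.assert_allclose(
        recon.soma_center_um, cfg.neurons[0].soma_center_um, atol=1.0
    )
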