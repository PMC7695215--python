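"""Leaflet assignment, grid APL vs the Voronoi oracle, and water counting."""

import numpy as np
import pytest

import lipidorder as lo
from lipidorder.exceptions import GeometryError

from conftest import monolayer_frame, periodic_voronoi_areas, voronoi_perimeters


def brute_force_water_count(frame, cutoff, region=None):
    """O(N·M) all-pairs reference for the water-insertion count."""
    centers = lo.carbonyl_centers(frame)
    if region is not None:
        centers = centers[np.isin(frame.lipid_ids, list(region))]
    waters = frame.waters % frame.box
    counted = 0
    for w in waters:
        d = centers - w
        d -= frame.box * np.round(d / frame.box)
        if np.any(np.einsum("ij,ij->i", d, d) <= cutoff**2):
            counted += 1
    return counted


class TestLeaflets:
    def test_bimodal_split(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 5, (20, 2))
        heads = np.vstack(
            [np.column_stack([xy[:10], np.full(10, 4.0)]),
             np.column_stack([xy[10:], np.full(10, 0.5)])]
        )
        f = lo.BilayerFrame(np.array([5.0, 5.0, 5.0]), np.arange(20), heads,
                            np.repeat(heads[:, None, :], 4, axis=1))
        upper = lo.assign_leaflets(f)
        assert upper[:10].all() and not upper[10:].any()

    def test_tie_rule_midplane_head_goes_upper(self):
        heads = np.array([[1.0, 1.0, 4.0], [2.0, 2.0, 0.0], [3.0, 3.0, 2.0]])
        f = lo.BilayerFrame(np.array([5.0, 5.0, 5.0]), np.arange(3), heads,
                            np.repeat(heads[:, None, :], 4, axis=1))
        upper = lo.assign_leaflets(f)
        assert upper.tolist() == [True, False, True]  # z=2 equals the mean

    def test_generator_tags_recovered(self):
        f, truth = lo.generate_frame(lo.FrameGeneratorConfig(seed=4, jitter_sigma=0.05))
        upper = lo.assign_leaflets(f)
        assert set(f.lipid_ids[upper]) == set(truth.upper_ids)
        assert set(f.lipid_ids[~upper]) == set(truth.lower_ids)

    def test_coplanar_rejected(self):
        heads = np.array([[1.0, 1.0, 2.0], [2.0, 2.0, 2.0]])
        f = lo.BilayerFrame(np.array([5.0, 5.0, 5.0]), np.arange(2), heads,
                            np.repeat(heads[:, None, :], 4, axis=1))
        with pytest.raises(GeometryError, match="coplanar"):
            lo.assign_leaflets(f)


class TestGridAPL:
    def test_single_lipid_owns_whole_box(self):
        f = monolayer_frame(np.array([[0.7, 1.3]]), np.array([2.0, 2.0, 4.0]))
        apl = lo.grid_apl(f, "upper")
        assert apl.areas[0] == pytest.approx(4.0)

    def test_four_lipid_lattice_exact_quarter(self):
        heads2 = np.array([[0.5, 0.5], [0.5, 1.5], [1.5, 0.5], [1.5, 1.5]])
        f = monolayer_frame(heads2, np.array([2.0, 2.0, 4.0]))
        apl = lo.grid_apl(f, "upper")
        np.testing.assert_allclose(apl.areas, 1.0)

    def test_conservation_and_voronoi_consistency(self):
        box = np.array([6.0, 5.0, 4.0])
        for seed in range(3):
            rng = np.random.default_rng(seed)
            heads2 = rng.uniform(0, box[:2], (20, 2))
            f = monolayer_frame(heads2, box)
            apl = lo.grid_apl(f, "upper")
            assert apl.areas.sum() == pytest.approx(box[0] * box[1], abs=1e-9)
            assert np.all(apl.areas > 0)
            ref = periodic_voronoi_areas(heads2, box[:2])
            per = voronoi_perimeters(heads2, box[:2])
            # worst-case misassignment: cells within half a diagonal of the
            # boundary, area <= sqrt(2) * perimeter * cell side
            h = max(box[0] / 100, box[1] / 100)
            bound = np.sqrt(2.0) * per * h
            assert np.all(np.abs(apl.areas - ref) <= bound)

    def test_refinement_converges_to_voronoi(self):
        box = np.array([6.0, 5.0, 4.0])
        rng = np.random.default_rng(1)
        heads2 = rng.uniform(0, box[:2], (20, 2))
        f = monolayer_frame(heads2, box)
        ref = periodic_voronoi_areas(heads2, box[:2])
        devs = [
            np.abs(lo.grid_apl(f, "upper", grid=(n, n)).areas - ref).max()
            for n in (50, 200, 800)
        ]
        assert devs[2] < devs[1] < devs[0]

    def test_translation_by_whole_cells_invariant(self):
        f, _ = lo.generate_frame(lo.FrameGeneratorConfig(seed=2, jitter_sigma=0.04))
        apl1 = lo.grid_apl(f, "upper")
        lx = f.box[0]
        shift = (7 * lx / 100, 13 * f.box[1] / 100, 0.0)  # whole grid cells
        apl2 = lo.grid_apl(f.translated(shift), "upper")
        np.testing.assert_allclose(
            np.sort(apl1.areas), np.sort(apl2.areas), atol=1e-9
        )

    def test_tiny_grid_rejected(self):
        f = monolayer_frame(np.array([[1.0, 1.0]]), np.array([2.0, 2.0, 4.0]))
        with pytest.raises(GeometryError, match="10x10"):
            lo.grid_apl(f, "upper", grid=(5, 5))


class TestNearChannel:
    def test_inside_outside_cutoff(self):
        heads2 = np.array([[2.2, 2.0], [2.5, 2.0], [4.0, 4.0]])
        f = monolayer_frame(heads2, np.array([5.0, 5.0, 5.0]))
        f = lo.BilayerFrame(f.box, f.lipid_ids, f.heads, f.carbonyls,
                            peptide=np.array([[2.0, 2.0, 2.5]]))
        near, bulk = lo.near_channel_selection(f, cutoff=0.3)
        assert 0 in near and 3 in near  # 0.2 nm away (both leaflet copies)
        assert 1 in bulk and 2 in bulk  # 0.5 and ~2.8 nm away

    def test_no_peptide_rejected(self):
        f = monolayer_frame(np.array([[1.0, 1.0]]), np.array([2.0, 2.0, 4.0]))
        with pytest.raises(GeometryError, match="peptide"):
            lo.near_channel_selection(f)

    def test_planted_ring_selected_exactly(self):
        f, truth = lo.generate_frame(
            lo.FrameGeneratorConfig(seed=9, channel=True, jitter_sigma=0.02)
        )
        near, bulk = lo.near_channel_selection(f)
        assert sorted(near.tolist()) == sorted(truth.near_ids.tolist())
        assert len(near) + len(bulk) == f.n_lipids


class TestWaterInsertion:
    def test_no_waters(self):
        f, _ = lo.generate_frame(
            lo.FrameGeneratorConfig(seed=0, waters_in_shell=0, waters_bulk=0)
        )
        assert lo.water_insertion_count(f) == 0

    def test_cutoff_boundary(self):
        heads2 = np.array([[2.0, 2.0]])
        box = np.array([5.0, 5.0, 5.0])
        n = len(heads2)
        heads = np.vstack(
            [np.column_stack([heads2, [3.75]]), np.column_stack([heads2, [1.25]])]
        )
        carbonyls = np.repeat(heads[:, None, :], 4, axis=1)
        near = lo.BilayerFrame(box, np.arange(2), heads, carbonyls,
                               waters=np.array([[2.0, 2.0, 3.75 + 0.29]]))
        far = lo.BilayerFrame(box, np.arange(2), heads, carbonyls,
                              waters=np.array([[2.0, 2.0, 3.75 + 0.31]]))
        assert lo.water_insertion_count(near, cutoff=0.3) == 1
        assert lo.water_insertion_count(far, cutoff=0.3) == 0

    def test_water_counted_once_across_lipids(self):
        heads2 = np.array([[2.0, 2.0], [2.2, 2.0]])
        box = np.array([5.0, 5.0, 5.0])
        heads = np.vstack(
            [np.column_stack([heads2, [3.75, 3.75]]),
             np.column_stack([heads2, [1.25, 1.25]])]
        )
        carbonyls = np.repeat(heads[:, None, :], 4, axis=1)
        f = lo.BilayerFrame(box, np.arange(4), heads, carbonyls,
                            waters=np.array([[2.1, 2.0, 3.75]]))
        assert lo.water_insertion_count(f, cutoff=0.3) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        box = np.array([6.0, 6.0, 6.0])
        n = 50
        heads2 = rng.uniform(0, box[:2], (n, 2))
        heads = np.vstack(
            [np.column_stack([heads2[: n // 2], np.full(n // 2, 4.5)]),
             np.column_stack([heads2[n // 2:], np.full(n - n // 2, 1.5)])]
        )
        carbonyls = (heads[:, None, :] + rng.normal(0, 0.05, (n, 4, 3))) % box
        waters = rng.uniform(0, box, (500, 3))
        f = lo.BilayerFrame(box, np.arange(n), heads, carbonyls, waters=waters)
        for cutoff in (0.29, 0.3, 0.31, 0.5):
            assert lo.water_insertion_count(f, cutoff) == brute_force_water_count(
                f, cutoff
            )
        region = set(range(0, n, 3))
        assert lo.water_insertion_count(f, 0.3, region=region) == (
            brute_force_water_count(f, 0.3, region=region)
        )

    def test_monotone_in_cutoff(self):
        f, _ = lo.generate_frame(
            lo.FrameGeneratorConfig(seed=6, waters_in_shell=5, waters_bulk=150)
        )
        counts = [lo.water_insertion_count(f, c) for c in (0.1, 0.3, 0.6, 1.2)]
        assert counts == sorted(counts)

    def test_translation_invariance(self):
        f, _ = lo.generate_frame(
            lo.FrameGeneratorConfig(seed=7, waters_in_shell=6, jitter_sigma=0.03)
        )
        shifted = f.translated([1.234, -0.77, 2.1])
        assert lo.water_insertion_count(f) == lo.water_insertion_count(shifted)


class TestFrameStatistics:
    def test_identical_frames_zero_sd(self):
        f, _ = lo.generate_frame(lo.FrameGeneratorConfig(seed=1))
        per_frame, summary = lo.frame_statistics([f] * 5, grid=(50, 50))
        assert len(per_frame) == 5
        assert summary.loc["apl_both", "std"] == 0.0

    def test_mean_arithmetic(self):
        fa, _ = lo.generate_frame(lo.FrameGeneratorConfig(seed=1, bulk_apl=0.6))
        fb, _ = lo.generate_frame(lo.FrameGeneratorConfig(seed=1, bulk_apl=0.7))
        _, summary = lo.frame_statistics([fa, fb], grid=(50, 50))
        assert summary.loc["apl_both", "mean"] == pytest.approx(0.65)

    def test_planted_apl_fluctuation_recovered(self):
        sigma = 0.012
        frames = [
            f for f, _ in lo.generate_frames(
                lo.FrameGeneratorConfig(seed=10), n_frames=60, apl_jitter_sigma=sigma
            )
        ]
        per_frame, summary = lo.frame_statistics(frames, grid=(20, 20))
        # overall mean APL per frame is exact (partition), so the recovered
        # SD estimates the planted sigma within sampling error at n=60
        sd = summary.loc["apl_both", "std"]
        se = sigma / np.sqrt(2 * (60 - 1))
        assert sd == pytest.approx(sigma, abs=4 * se)
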