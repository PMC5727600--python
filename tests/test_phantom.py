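"""Phantom generation, virtual sectioning and in-silico studies."""

import warnings

import numpy as np
import pytest

from disector import (
    BoxRoi,
    EllipsoidRoi,
    SamplingDesign,
    estimate_from_table,
    generate_lesion_cohort,
    generate_phantom,
    rank_correlation,
    simulate_study,
    virtual_sectioning,
)
from disector.exceptions import ValidationError


class TestGeneratePhantom:
    def test_empty_phantom(self):
        ph = generate_phantom(0, seed=0)
        assert ph.true_n == 0

    def test_deterministic_per_seed(self):
        a = generate_phantom(300, seed=5)
        b = generate_phantom(300, seed=5)
        np.testing.assert_array_equal(a.centers, b.centers)
        np.testing.assert_array_equal(a.radii, b.radii)

    def test_centers_inside_roi_and_separated(self):
        ph = generate_phantom(400, BoxRoi((800, 800, 800)), seed=1)
        assert ph.roi.contains(ph.centers).all()
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(ph.centers))
        np.fill_diagonal(d, np.inf)
        need = ph.radii[:, None] + ph.radii[None, :] + 2.0
        assert (d >= need - 1e-9).all()

    def test_density_uniform_across_octants(self):
        # mean occupancy of each spatial octant matches n/8 within 2%
        counts = np.zeros(8)
        n, n_seeds = 4000, 40
        roi = BoxRoi((1000.0, 1000.0, 1000.0))
        for seed in range(n_seeds):
            ph = generate_phantom(n, roi, min_separation=0.0, seed=seed)
            octant = (
                (ph.centers[:, 0] > 500).astype(int)
                + 2 * (ph.centers[:, 1] > 500).astype(int)
                + 4 * (ph.centers[:, 2] > 500).astype(int)
            )
            counts += np.bincount(octant, minlength=8)
        frac = counts / (n * n_seeds)
        assert np.abs(frac / (1 / 8) - 1).max() < 0.02

    def test_ellipsoid_roi_supported(self):
        roi = EllipsoidRoi(semiaxes=(400.0, 300.0, 500.0))
        ph = generate_phantom(200, roi, seed=2)
        assert ph.roi.contains(ph.centers).all()

    def test_impossible_packing_raises(self):
        from disector.exceptions import PackingError

        with pytest.raises(PackingError):
            generate_phantom(
                500, BoxRoi((50.0, 50.0, 50.0)), min_separation=30.0, seed=0
            )


class TestVirtualSectioning:
    def test_sphere_spans_three_or_four_sections(self):
        # diameter 12 µm across 5 µm slabs: 3 or 4 slabs depending on phase
        roi = BoxRoi((100.0, 100.0, 100.0))
        seen = set()
        for z in np.linspace(20.0, 25.0, 21):
            ph_c = np.array([[50.0, 50.0, z]])
            from disector.phantom import Phantom

            ph = Phantom(centers=ph_c, radii=np.array([6.0]), roi=roi)
            stack = virtual_sectioning(ph, 5.0)
            span = int(stack.top_slab[0] - stack.bottom_slab[0] + 1)
            seen.add(span)
            assert span in (3, 4)
        assert seen == {3, 4}

    def test_tops_conserved(self):
        for seed, t in [(0, 5.0), (1, 3.0), (2, 7.5)]:
            ph = generate_phantom(800, BoxRoi((600, 600, 600)), seed=seed)
            stack = virtual_sectioning(ph, t)
            assert stack.tops_per_section().sum() == ph.true_n

    def test_equator_profile_radius(self):
        from disector.phantom import Phantom

        roi = BoxRoi((100.0, 100.0, 100.0))
        # centre at a slab midplane: the equatorial profile has radius r
        ph = Phantom(
            centers=np.array([[50.0, 50.0, 22.5]]), radii=np.array([8.0]), roi=roi
        )
        stack = virtual_sectioning(ph, 5.0)
        _, _, _, rho = stack.profile_discs(4)  # slab [20, 25)
        assert rho[0] == pytest.approx(8.0)

    def test_padding_slabs_are_empty(self):
        ph = generate_phantom(500, BoxRoi((400, 400, 400)), seed=3)
        stack = virtual_sectioning(ph, 5.0)
        tops = stack.tops_per_section()
        assert tops[0] == 0 and tops[-1] == 0


class TestSimulateStudy:
    def test_census_design_recovers_truth_exactly(self):
        ph = generate_phantom(500, BoxRoi((400.0, 400.0, 400.0)), seed=2)
        design = SamplingDesign(
            ssf_period=1, frame_area=1600.0, step_x=40.0, step_y=40.0
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = simulate_study(ph, design, seed=3)
            res = estimate_from_table(table, design)
        assert res.n == ph.true_n
        assert res.v_mm3 == pytest.approx(ph.true_volume_mm3, rel=0.01)

    def test_counts_deterministic_per_seed(self, paper_design):
        ph = generate_phantom(2000, seed=4)
        a = simulate_study(ph, paper_design, seed=9)
        b = simulate_study(ph, paper_design, seed=9)
        assert a.q_list == b.q_list
        np.testing.assert_array_equal(a.p, b.p)

    def test_study_scale_matches_design_expectations(self, paper_design):
        # the default phantom under the default design should produce the
        # designed workload: 10-15 pairs and ~150-200 counting events
        ph = generate_phantom(10_000, seed=0)
        table = simulate_study(ph, paper_design, seed=1)
        assert 10 <= table.n_pairs <= 15
        assert 100 <= table.sum_q <= 240

    def test_no_pairs_warns_and_returns_empty(self):
        ph = generate_phantom(50, BoxRoi((200.0, 200.0, 40.0)), seed=0)
        design = SamplingDesign(ssf_period=1000)
        with pytest.warns(UserWarning, match="no sampled section pairs"):
            table = simulate_study(ph, design, seed=0)
        assert table.n_pairs == 0


class TestLesionCohort:
    def test_no_effect_leaves_sides_equal_on_average(self):
        df = generate_lesion_cohort(n_animals=200, effect_size=0.0, loss_sd=0.0,
                                    seed=0)
        ratio = (df.n_ipsi_est / df.n_contra_est).mean()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_rotations_anticorrelate_with_ipsi_count(self):
        negative = 0
        for seed in range(60):
            df = generate_lesion_cohort(n_animals=26, effect_size=0.55, seed=seed)
            res = rank_correlation(
                df.n_ipsi_est, df.rotations_amphetamine, seed=seed
            )
            negative += res.rho < 0
        assert negative >= 57  # >= 95%

    def test_severe_lesion_recovers_group_reduction(self):
        reductions = []
        for seed in range(60):
            df = generate_lesion_cohort(n_animals=10, effect_size=0.85, seed=seed)
            reductions.append(100 * (1 - df.n_ipsi_est / df.n_contra_est).mean())
        assert abs(np.mean(reductions) - 85.0) < 3.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            generate_lesion_cohort(effect_size=1.5)
        with pytest.raises(ValidationError):
            generate_lesion_cohort(between_animal_cv=0.0)
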