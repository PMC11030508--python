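"""Ground-truth bookkeeping, determinism, and forward-simulation physics."""

import warnings
from dataclasses import replace

import numpy as np
import pytest
from skimage.measure import label as cc_label

from organoidqpi.phantoms import (
    AcquisitionSpec,
    CohortSpec,
    GroupTrend,
    PhantomSpec,
    PlacementError,
    expected_ground_truth,
    generate_organoid_phantom,
    generate_two_group_cohort,
    make_fractal_fixture,
)
from organoidqpi.phantoms import simulate_qobm_acquisition


class TestPhantomGroundTruth:
    def test_rosette_components_match_requested_count(self):
        spec = PhantomSpec(image_size=512, rosette_count=10, seed=5)
        phantom = generate_organoid_phantom(spec)
        rosette_region = (phantom.labels == 2) | (phantom.labels == 3)
        assert cc_label(rosette_region, connectivity=2).max() == 10

    def test_zero_droplet_fraction_leaves_ri_below_threshold(self, small_spec):
        phantom = generate_organoid_phantom(
            replace(small_spec, droplet_area_fraction=0.0)
        )
        assert not phantom.label_mask("droplet").any()
        assert phantom.ri_map.max() < 1.46

    def test_droplet_fraction_recorded_within_ten_percent(self):
        spec = PhantomSpec(image_size=512, droplet_area_fraction=0.05, seed=7)
        phantom = generate_organoid_phantom(spec)
        assert phantom.droplet_fraction() == pytest.approx(0.05, abs=0.005)

    def test_seed_determinism_bit_identical(self, small_spec):
        a = generate_organoid_phantom(small_spec)
        b = generate_organoid_phantom(small_spec)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.ri_map, b.ri_map)

    def test_infeasible_rosette_density_raises_capacity_error(self):
        spec = PhantomSpec(
            image_size=128, organoid_axes=(40.0, 40.0), rosette_count=40,
            rosette_radius_range=(20.0, 25.0), fissure_count=0, seed=0,
        )
        with pytest.raises(PlacementError):
            generate_organoid_phantom(spec)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("droplet_area_fraction", 0.5),
            ("lumen_offset_fraction", 1.2),
            ("pixel_size", 0.0),
            ("directional_cell_aspect", 0.5),
        ],
    )
    def test_invalid_spec_rejected(self, small_spec, field, value):
        with pytest.raises(ValueError):
            generate_organoid_phantom(replace(small_spec, **{field: value}))


class TestAcquisition:
    def test_flat_phantom_gives_background_frames(self, small_spec):
        spec = replace(
            small_spec,
            rosette_count=0, fissure_count=0, droplet_area_fraction=0.0,
            nucleus_density=0.0, texture_amplitude=0.0,
            compartment_ri={**dict(small_spec.compartment_ri),
                            "cytoplasm": 1.3440, "background": 1.3440,
                            "medium": 1.3440},
        )
        phantom = generate_organoid_phantom(spec)
        raw = simulate_qobm_acquisition(phantom, AcquisitionSpec(snr_db=None))
        assert np.allclose(raw.frames, 1.0, atol=1e-12)

    def test_opposing_frames_are_antisymmetric_about_background(
        self, small_phantom, noiseless_acq
    ):
        raw = simulate_qobm_acquisition(small_phantom, noiseless_acq)
        bg = noiseless_acq.background
        np.testing.assert_allclose(
            raw.frames[0] - bg, -(raw.frames[1] - bg), atol=1e-12
        )
        np.testing.assert_allclose(
            raw.frames[2] - bg, -(raw.frames[3] - bg), atol=1e-12
        )

    def test_noise_variance_matches_configured_snr(self, small_phantom):
        acq = AcquisitionSpec(snr_db=20.0)
        raw = simulate_qobm_acquisition(small_phantom, acq)
        corner = raw.frames[0][:40, :40]  # outside the organoid: flat region
        sigma_expected = acq.background / 10 ** (acq.snr_db / 20)
        assert corner.std() == pytest.approx(sigma_expected, rel=0.10)

    def test_extreme_noise_clips_with_warning(self, small_phantom):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            raw = simulate_qobm_acquisition(
                small_phantom, AcquisitionSpec(snr_db=-3.0)
            )
        assert raw.n_clipped > 0
        assert any("clipped" in str(w.message) for w in caught)
        assert np.all(raw.frames > 0)


class TestCohort:
    def test_full_retention_keeps_density_constant(self):
        cs = CohortSpec(
            control=GroupTrend(1.0, 1.0, 0.0),
            experimental=GroupTrend(1.0, 1.0, 0.0),
        )
        dens = [
            expected_ground_truth(cs, "control", w)["directional_cell_density"]
            for w in cs.weeks
        ]
        assert len(set(dens)) == 1

    def test_half_retention_halves_density_per_post_switch_week(self):
        cs = CohortSpec()
        base = cs.base_spec.directional_cell_density
        for w in cs.weeks:
            post = max(0, w - cs.differentiation_switch_week)
            got = expected_ground_truth(cs, "control", w)["directional_cell_density"]
            assert got == pytest.approx(base * 0.5**post)

    def test_droplet_gap_strictly_increasing_after_switch(self):
        # generator-mean oracle over 10 seeds
        gaps = {w: [] for w in (4, 5, 6)}
        for seed in range(10):
            cs = CohortSpec(seed=seed, n_control=2, n_experimental=2)
            cohort = generate_two_group_cohort(cs)
            for w in gaps:
                by_group = {"control": [], "experimental": []}
                for ph, meta in cohort:
                    if meta["week"] == w:
                        by_group[meta["group"]].append(
                            meta["truth_droplet_fraction_actual"]
                        )
                gaps[w].append(
                    np.mean(by_group["experimental"]) - np.mean(by_group["control"])
                )
        means = [np.mean(gaps[w]) for w in (4, 5, 6)]
        assert means[0] < means[1] < means[2]

    def test_metadata_carries_design_keys(self):
        cohort = generate_two_group_cohort(
            CohortSpec(n_control=1, n_experimental=1, seed=3)
        )
        assert len(cohort) == 2 * 4
        _, meta = cohort[0]
        for key in ("group", "week", "organoid_id", "truth_droplet_area_fraction"):
            assert key in meta

    def test_switch_week_must_be_member_of_weeks(self):
        with pytest.raises(ValueError):
            CohortSpec(differentiation_switch_week=9).validate()


class TestFractalFixtures:
    @pytest.mark.parametrize("kind", ["filled_square", "line", "sierpinski_carpet"])
    def test_fixture_deterministic_and_binary(self, kind):
        a = make_fractal_fixture(kind, 81)
        assert a.dtype == bool and a.shape == (81, 81)
        assert np.array_equal(a, make_fractal_fixture(kind, 81))

    def test_carpet_rejects_non_power_of_three(self):
        with pytest.raises(ValueError):
            make_fractal_fixture("sierpinski_carpet", 100)

    def test_carpet_occupancy_is_eight_ninths_per_level(self):
        carpet = make_fractal_fixture("sierpinski_carpet", 243)
        assert carpet.sum() == 8**5
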