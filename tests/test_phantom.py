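"""Phantom generator: contact-map sampling, analytic ground truth, artifacts.

The key check is dual-route: the analytic ground-truth BIC must agree with an
independent voxel-walk oracle that inspects the constructed volume directly,
without going through any of the package's measurement code.
"""

from dataclasses import replace

import numpy as np
import pytest

from microbic.phantom import (
    ContactMap,
    PhantomConfig,
    add_artifacts,
    build_phantom,
    sample_contact_map,
)

BONE_MIN, BONE_MAX, IMPLANT_MIN = 60.0, 90.0, 200.0


class TestContactMap:
    def test_boundary_targets(self):
        assert sample_contact_map(1.0, seed=3).contact.all()
        assert not sample_contact_map(0.0, seed=3).contact.any()

    def test_exact_sector_count_per_groove(self):
        cm = sample_contact_map(0.5, granularity=36, seed=7)
        assert (cm.contact.sum(axis=1) == 18).all()

    def test_global_fraction_within_one_sector(self):
        for tf in (0.2, 0.33, 0.8):
            cm = sample_contact_map(tf, granularity=8, seed=1)
            assert abs(cm.fraction() - tf) <= 1.0 / 8

    def test_seeded_reproducibility(self):
        a = sample_contact_map(0.4, seed=5)
        b = sample_contact_map(0.4, seed=5)
        np.testing.assert_array_equal(a.contact, b.contact)

    def test_monotone_in_target_fraction(self):
        prev = -1.0
        for tf in (0.0, 0.25, 0.5, 0.75, 1.0):
            frac = sample_contact_map(tf, granularity=8, seed=9).contact.mean()
            assert frac >= prev
            prev = frac

    def test_target_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            sample_contact_map(1.2)


class TestGroundTruth:
    def test_full_and_zero_contact_limits(self, small_cfg):
        n = small_cfg.grooves_per_side_available
        _, gt_full = build_phantom(small_cfg, sample_contact_map(1.0, n_grooves=n))
        _, gt_zero = build_phantom(small_cfg, sample_contact_map(0.0, n_grooves=n))
        assert all(v == 100.0 for v in gt_full.per_plane.values())
        assert all(v == 0.0 for v in gt_zero.per_plane.values())

    def test_mean_is_mean_of_planes(self, half_contact):
        _, gt, _ = half_contact
        assert gt.bic_mean_percent == pytest.approx(np.mean(list(gt.per_plane.values())))

    def test_per_plane_symmetric_under_half_turn(self, half_contact):
        # a plane at theta shows the sides theta and theta+180: per-groove
        # values swap sides between theta and theta+180
        _, gt, cm = half_contact
        for g in range(1, cm.n_grooves + 1):
            assert gt.per_plane_groove[(0.0, "right", g)] == 100.0 * cm.indicator(0.0, g)
            assert gt.per_plane_groove[(0.0, "left", g)] == 100.0 * cm.indicator(180.0, g)

    def test_voxel_walk_oracle_agrees_with_analytic_truth(self, small_cfg):
        """March along the thread profile of the raw volume at the two
        axis-aligned planes and score bone presence beyond the separation
        gap, independently of all measurement code."""
        n = small_cfg.grooves_per_side_available
        cm = sample_contact_map(0.5, seed=7, n_grooves=n)
        vol, gt = build_phantom(small_cfg, cm)
        cy, cx = small_cfg.axis_center
        zc = small_cfg.crest_centers_z()
        probe_off = 1  # direct contact: bone immediately beside the metal

        for angle, plane, center in ((0.0, vol.voxels[:, cy, :], cx), (90.0, vol.voxels[:, :, cx], cy)):
            scores = []
            for g in range(1, 5):  # the four measured grooves
                for sign, side in ((+1, "right"), (-1, "left")):
                    hits = total = 0
                    for z in range(int(zc[g - 1]) + 1, int(zc[g])):
                        row = plane[z]
                        cols = np.flatnonzero(row >= IMPLANT_MIN)
                        edge = cols.max() if sign > 0 else cols.min()
                        probe = row[edge + sign * probe_off]
                        hits += BONE_MIN <= probe <= BONE_MAX
                        total += 1
                    scores.append(100.0 * hits / total)
                    expected = gt.per_plane_groove[(angle, side, g)]
                    assert abs(scores[-1] - expected) <= 2.0
            assert abs(np.mean(scores) - gt.per_plane[angle]) <= 2.0


class TestBuildPhantom:
    def test_deterministic_given_seed(self, small_cfg):
        n = small_cfg.grooves_per_side_available
        cm = sample_contact_map(0.5, seed=3, n_grooves=n)
        v1, _ = build_phantom(small_cfg, cm)
        v2, _ = build_phantom(small_cfg, cm)
        np.testing.assert_array_equal(v1.voxels, v2.voxels)

    def test_implant_does_not_fit_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            PhantomConfig.validation_scale(volume_shape=(100, 128, 128))

    def test_intensity_ordering_enforced(self):
        with pytest.raises(ValueError):
            PhantomConfig.validation_scale(intensity_background=80.0)


class TestArtifacts:
    def test_no_artifacts_is_identity(self, half_contact, small_cfg):
        vol, _, _ = half_contact
        out = add_artifacts(vol, small_cfg)
        np.testing.assert_array_equal(out.voxels, vol.voxels)

    def test_halo_shell_classifies_as_bone(self, half_contact, small_cfg):
        """The one-voxel interface band lands inside the bone window."""
        vol, _, _ = half_contact
        cfg = replace(small_cfg, halo_width_voxels=1, halo_intensity=75.0)
        out = add_artifacts(vol, cfg)
        from scipy import ndimage

        implant = vol.voxels >= IMPLANT_MIN
        shell = (ndimage.distance_transform_edt(~implant) <= 1) & ~implant
        vals = out.voxels[shell]
        frac_bone = ((vals >= BONE_MIN) & (vals <= BONE_MAX)).mean()
        assert frac_bone == 1.0

    def test_noise_seeded_determinism(self, half_contact, small_cfg):
        vol, _, _ = half_contact
        cfg = replace(small_cfg, noise_sd=5.0, seed=42)
        a = add_artifacts(vol, cfg)
        b = add_artifacts(vol, cfg)
        np.testing.assert_array_equal(a.voxels, b.voxels)
        assert not np.array_equal(a.voxels, vol.voxels)

    def test_granules_are_bone_intensity_and_spare_implant(self, half_contact, small_cfg):
        vol, _, _ = half_contact
        cfg = replace(small_cfg, granule_count=200, seed=1)
        out = add_artifacts(vol, cfg)
        changed = out.voxels != vol.voxels
        assert changed.any()
        assert np.all(out.voxels[changed] == cfg.intensity_bone)
        implant = vol.voxels >= IMPLANT_MIN
        assert not changed[implant].any()
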