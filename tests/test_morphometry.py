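"""Morphometry against analytic shape oracles and generator ground truth."""

import numpy as np
import pytest

import spermdfi as s
from spermdfi.errors import DomainError, MeasurementError, NoCellFound
from spermdfi.morphometry import (
    HeadMask,
    axial_gray_profile,
    measure_acrosome,
    measure_head,
    measure_midpiece,
    measure_vacuoles,
    segment_head,
)
from spermdfi.synthetic import _coverage, ramanujan_perimeter

PX = 0.05


def render_ellipse(a, b, px=PX, fg=0.7, bg=0.2, margin=1.0):
    """Antialiased high-contrast ellipse raster (uint16)."""
    W, H = 2 * a + 2 * margin, 2 * b + 2 * margin
    ny, nx = int(np.ceil(H / px)), int(np.ceil(W / px))
    xc, yc = W / 2, H / 2
    cov = _coverage((ny, nx), px,
                    lambda x, y: ((x - xc) / a) ** 2 + ((y - yc) / b) ** 2 <= 1)
    img = bg + (fg - bg) * cov
    return np.round(img * 65535).astype(np.uint16)


class TestSegmentHead:
    def test_blank_raster_raises(self):
        blank = np.full((80, 80), 1000, dtype=np.uint16)
        with pytest.raises(NoCellFound):
            segment_head(blank, PX)

    def test_two_disjoint_heads_returns_larger_with_warning(self, caplog):
        big = render_ellipse(2.0, 1.5)
        small = render_ellipse(1.0, 0.8)
        canvas = np.full((big.shape[0], big.shape[1] + small.shape[1] + 40),
                         int(0.2 * 65535), dtype=np.uint16)
        canvas[:, :big.shape[1]] = big
        canvas[:small.shape[0], big.shape[1] + 40:] = small
        with caplog.at_level("WARNING", logger="spermdfi.morphometry"):
            head = segment_head(canvas, PX)
        assert any("candidate heads" in r.message for r in caplog.records)
        area = head.n_pixels * PX ** 2
        assert area == pytest.approx(np.pi * 2.0 * 1.5, rel=0.02)

    def test_mask_iou_against_generator_truth(self, default_cell):
        row, _, images = default_cell
        head = segment_head(images.brightfield, PX)
        # reference mask from the fluorescence footprint (exact head region)
        ref = images.green > 0
        inter = (head.mask & ref).sum()
        union = (head.mask | ref).sum()
        assert inter / union >= 0.95


class TestMeasureHead:
    def test_circle_oracle(self):
        img = render_ellipse(2.0, 2.0)
        head = segment_head(img, PX)
        d = measure_head(head, PX)
        assert d.A == pytest.approx(4 * np.pi, rel=0.01)
        assert d.L == pytest.approx(d.HW, rel=0.02)
        assert d.P == pytest.approx(4 * np.pi, rel=0.02)

    def test_ellipse_perimeter_matches_ramanujan(self):
        img = render_ellipse(2.48, 1.68)
        head = segment_head(img, PX)
        d = measure_head(head, PX)
        assert d.P == pytest.approx(ramanujan_perimeter(2.48, 1.68), rel=0.02)
        assert d.L == pytest.approx(2 * 2.48, rel=0.02)
        assert d.HW == pytest.approx(2 * 1.68, rel=0.02)

    def test_pixel_size_units_contract(self):
        img = render_ellipse(2.0, 1.5)
        head = segment_head(img, PX)
        d1 = measure_head(head, PX)
        d2 = measure_head(head, 2 * PX)
        assert d2.L == pytest.approx(2 * d1.L)
        assert d2.HW == pytest.approx(2 * d1.HW)
        assert d2.A == pytest.approx(4 * d1.A)

    def test_degenerate_mask_raises(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        with pytest.raises(MeasurementError):
            measure_head(HeadMask(mask, (5.0, 5.0), (0.0, 1.0)), PX)


class TestCircularity:
    def test_closed_forms(self):
        assert s.circularity(np.pi, 2 * np.pi) == pytest.approx(1.0, abs=1e-15)
        assert s.circularity(1.0, 4.0) == pytest.approx(np.pi / 4, abs=1e-15)

    def test_ellipse_closed_form(self):
        a, b = 2.48, 1.68
        expected = 4 * np.pi * (np.pi * a * b) / ramanujan_perimeter(a, b) ** 2
        img = render_ellipse(a, b)
        head = segment_head(img, PX)
        d = measure_head(head, PX)
        assert s.circularity(d.A, d.P) == pytest.approx(expected, rel=0.02)

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(DomainError):
            s.circularity(0.0, 1.0)
        with pytest.raises(DomainError):
            s.circularity(1.0, -2.0)

    @pytest.mark.parametrize("aspect", [1.0, 1.5, 2.5, 4.0])
    def test_bounded_by_one_and_decreasing_in_aspect(self, aspect):
        area = 8.0  # fixed area, varying elongation
        b = np.sqrt(area / (np.pi * aspect))
        a = aspect * b
        img = render_ellipse(a, b)
        head = segment_head(img, PX)
        d = measure_head(head, PX)
        c = s.circularity(d.A, d.P)
        assert c <= 1.02
        expected = 4 * np.pi * (np.pi * a * b) / ramanujan_perimeter(a, b) ** 2
        assert c == pytest.approx(expected, rel=0.02)


class TestAxialProfile:
    def test_uniform_head_gives_flat_profile_of_expected_length(self):
        img = render_ellipse(2.48, 1.68)
        head = segment_head(img, PX)
        profile = axial_gray_profile(img, head)
        # interior slabs are flat; end slabs mix in partial boundary pixels
        assert np.ptp(profile.values[4:-4]) < 0.02
        assert len(profile) == pytest.approx(2 * 2.48 / PX, rel=0.03)

    def test_step_located_at_acrosome_boundary(self, default_cell):
        row, truth_row, images = default_cell
        head = segment_head(images.brightfield, PX)
        profile = axial_gray_profile(images.brightfield, head)
        acro = measure_acrosome(profile, head, images.brightfield, PX)
        assert acro.detected
        dims = measure_head(head, PX)
        # boundary position implied by the anterior-area fraction
        frac_len = acro.boundary_um / dims.L
        assert 0.3 < frac_len < 0.95


class TestAcrosome:
    def test_area_matches_generator_fraction(self, rendered_cohort):
        cfg, table, truth, images = rendered_cohort
        rel = []
        for i, imgs in enumerate(images[:15]):
            head = segment_head(imgs.brightfield, PX)
            profile = axial_gray_profile(imgs.brightfield, head)
            acro = measure_acrosome(profile, head, imgs.brightfield, PX)
            rel.append(acro.aa_um2 / table["AA"].iloc[i] - 1)
        assert np.median(np.abs(rel)) < 0.05

    def test_flat_profile_flagged_no_acrosome(self):
        img = render_ellipse(2.48, 1.68)
        head = segment_head(img, PX)
        profile = axial_gray_profile(img, head)
        acro = measure_acrosome(profile, head, img, PX)
        assert not acro.detected
        assert acro.aa_um2 == 0.0

    def test_near_whole_head_elevated_gives_aa_close_to_a(self, quiet_cohort):
        cfg = quiet_cohort[0]
        from spermdfi.synthetic import ellipse_circularity
        a, b = 4.9618 / 2, 3.3639 / 2
        row = {"C": 0.999 * ellipse_circularity(a, b), "HW": 2 * b,
               "L": 2 * a, "MW": 1.32, "VA": 0.0,
               "AA": 0.9 * np.pi * a * b, "DFI": 0.1,
               "cell_id": "c0", "donor": 0}
        images = s.generate_cell_images(row, None, cfg,
                                        rng=np.random.default_rng(0))
        head = segment_head(images.brightfield, PX)
        dims = measure_head(head, PX)
        profile = axial_gray_profile(images.brightfield, head)
        acro = measure_acrosome(profile, head, images.brightfield, PX)
        assert acro.detected
        assert acro.aa_um2 >= 0.85 * dims.A

    def test_partition_property(self, default_cell):
        row, _, images = default_cell
        head = segment_head(images.brightfield, PX)
        profile = axial_gray_profile(images.brightfield, head)
        acro = measure_acrosome(profile, head, images.brightfield, PX)
        posterior = head.n_pixels - acro.region.sum()
        total = acro.aa_um2 + posterior * PX ** 2
        assert total == pytest.approx(head.n_pixels * PX ** 2, abs=1e-9)


class TestVacuoles:
    def test_no_vacuoles_rendered_gives_zero(self, quiet_cohort):
        cfg, table, _ = quiet_cohort
        row = table.iloc[0].copy()
        row["VA"] = 0.0
        images = s.generate_cell_images(row, None, cfg,
                                        rng=np.random.default_rng(0))
        head = segment_head(images.brightfield, PX)
        profile = axial_gray_profile(images.brightfield, head)
        acro = measure_acrosome(profile, head, images.brightfield, PX)
        vac = measure_vacuoles(images.brightfield, head, acro.region, PX)
        assert vac.va_um2 == 0.0

    def test_single_vacuole_recovered_within_ten_percent(self, quiet_cohort):
        cfg, table, _ = quiet_cohort
        row = table.iloc[0].copy()
        row["VA"] = 0.68287  # the published VA centering value
        images = s.generate_cell_images(row, None, cfg,
                                        rng=np.random.default_rng(0))
        head = segment_head(images.brightfield, PX)
        profile = axial_gray_profile(images.brightfield, head)
        acro = measure_acrosome(profile, head, images.brightfield, PX)
        vac = measure_vacuoles(images.brightfield, head, acro.region, PX)
        assert vac.va_um2 == pytest.approx(0.68287, rel=0.10)

    def test_two_vacuoles_are_additive(self):
        # hand-built acrosome region with two separated dark discs
        ny, nx = 120, 200
        img = np.full((ny, nx), 0.72)
        region = np.zeros((ny, nx), dtype=bool)
        region[10:110, 10:190] = True
        yy, xx = np.mgrid[0:ny, 0:nx]
        d1 = (yy - 50) ** 2 + (xx - 60) ** 2 <= 12 ** 2
        d2 = (yy - 50) ** 2 + (xx - 140) ** 2 <= 9 ** 2
        img[d1] = 0.60
        img[d2] = 0.60
        u16 = np.round(img * 65535).astype(np.uint16)
        head = HeadMask(region, (60.0, 100.0), (0.0, 1.0))
        vac = measure_vacuoles(u16, head, region, PX)
        expected = (d1.sum() + d2.sum()) * PX ** 2
        assert vac.count == 2
        assert vac.va_um2 == pytest.approx(expected, rel=0.05)


class TestMidpiece:
    def test_generator_width_recovered(self, rendered_cohort):
        cfg, table, truth, images = rendered_cohort
        rel = []
        for i, imgs in enumerate(images[:15]):
            head = segment_head(imgs.brightfield, PX)
            mid = measure_midpiece(imgs.brightfield, head, PX)
            assert mid.found
            rel.append(mid.mw_um / table["MW"].iloc[i] - 1)
        assert np.median(np.abs(rel)) < 0.05

    def test_head_only_image_flagged_missing(self):
        img = render_ellipse(2.48, 1.68)
        head = segment_head(img, PX)
        mid = measure_midpiece(img, head, PX)
        assert not mid.found
        assert np.isnan(mid.mw_um)

    def test_width_scales_with_pixel_size(self, default_cell):
        row, _, images = default_cell
        head = segment_head(images.brightfield, PX)
        w1 = measure_midpiece(images.brightfield, head, PX).mw_um
        w2 = measure_midpiece(images.brightfield, head, 2 * PX,
                              band_um=2.0, gap_tolerance_um=0.6).mw_um
        assert w2 == pytest.approx(2 * w1, rel=0.05)


class TestInvariances:
    def test_rotation_and_translation_invariance(self, default_cell):
        row, _, images = default_cell

        def all_measures(bf):
            head = segment_head(bf, PX)
            d = measure_head(head, PX)
            profile = axial_gray_profile(bf, head)
            acro = measure_acrosome(profile, head, bf, PX)
            mid = measure_midpiece(bf, head, PX)
            return np.array([d.A, d.P, d.HW, d.L, acro.aa_um2, mid.mw_um])

        base = all_measures(images.brightfield)
        rotated = all_measures(np.rot90(images.brightfield))
        shifted = all_measures(np.roll(images.brightfield, (7, -5), axis=(0, 1)))
        np.testing.assert_allclose(rotated, base, rtol=0.02)
        np.testing.assert_allclose(shifted, base, rtol=0.02)

    def test_generator_roundtrip_recovers_features(self, rendered_cohort):
        from spermdfi.pipeline import measure_image_table

        cfg, table, truth, images = rendered_cohort
        measured = measure_image_table(images)
        ok = np.ones(len(table), dtype=bool)
        for f in s.FEATURES:
            rel = np.abs(measured[f].to_numpy() / table[f].to_numpy() - 1)
            ok &= rel <= 0.05
        assert ok.mean() >= 0.95
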