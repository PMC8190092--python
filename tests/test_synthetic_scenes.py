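"""Forward-model tests: determinism, ground truth, photon bookkeeping,
distribution correctness of the sampled protein points."""

import numpy as np
import pytest
from scipy import stats

from thylaquant.geometry import region_labels
from thylaquant.synthetic_scenes import (
    OpticsNoiseParams,
    ProteinDistributionParams,
    SceneSpec,
    Shell,
    ShellSet,
    make_scene,
    render_fluorescence,
    render_tem,
)

QUIET = OpticsNoiseParams(background=0.0, poisson_gain=0.0, read_sigma=0.0)


class TestMakeScene:
    def test_empty_protein_list(self):
        scene = make_scene(
            "GL", distribution=ProteinDistributionParams(n_points=0), seed=1
        )
        assert len(scene.proteins) == 0
        assert scene.geometry.length >= scene.geometry.width > 0

    def test_gl_preset_shell_spacing(self):
        scene = make_scene("GL", seed=0)
        for side in (scene.shells.side1, scene.shells.side2):
            offs = np.array([s.offset_nm for s in side])
            assert len(offs) == 3
            assert np.allclose(np.diff(offs), 78.4)

    def test_hl_preset_layer_plus_fragment(self):
        scene = make_scene("HL", seed=0)
        s1, s2 = scene.shells.side1, scene.shells.side2
        assert len(s1) == 2 and len(s2) == 1
        fragments = [s for s in s1 if s.arc_extent < 1.0]
        assert len(fragments) == 1  # single fragment, on one side only
        assert all(s.arc_extent == 1.0 for s in s2)
        # fragment sits closer to the plasma membrane than the full layer
        assert fragments[0].offset_nm < max(s.offset_nm for s in s1)

    def test_determinism_bitwise(self):
        a = make_scene("HL", seed=7)
        b = make_scene("HL", seed=7)
        assert a.geometry == b.geometry
        np.testing.assert_array_equal(a.proteins, b.proteins)
        assert a.to_dict() == b.to_dict()

    def test_serialization_roundtrip(self):
        scene = make_scene("LL2", seed=9)
        back = SceneSpec.from_dict(scene.to_dict())
        assert back.to_dict() == scene.to_dict()
        np.testing.assert_array_equal(back.proteins, scene.proteins)

    def test_invalid_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            make_scene("XL", seed=0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ProteinDistributionParams(n_points=-1)

    def test_shell_invariants(self):
        with pytest.raises(ValueError):
            ShellSet(side1=(Shell(100.0), Shell(50.0)))
        with pytest.raises(ValueError):
            Shell(40.0, arc_extent=0.0)


class TestDistributionCorrectness:
    def test_side_ratio_matches_binomial_oracle(self):
        scene = make_scene(
            "GL",
            distribution=ProteinDistributionParams(
                n_points=10_000, side_asymmetry=2.0
            ),
            seed=5,
        )
        g = scene.geometry
        labels = region_labels(scene.proteins[:, 0], g.length, g.width)
        n1 = int((labels == "L1").sum())
        n2 = int((labels == "L2").sum())
        assert abs(n1 / n2 - 2.0) / 2.0 < 0.05

    def test_kappa_zero_is_uniform(self):
        scene = make_scene(
            "GL", distribution=ProteinDistributionParams(n_points=5_000), seed=8
        )
        stat = stats.kstest(scene.proteins[:, 0], "uniform")
        assert stat.pvalue > 0.01

    def test_polar_enrichment_scales_cap_density(self):
        base = ProteinDistributionParams(n_points=8_000)
        rich = ProteinDistributionParams(n_points=8_000, polar_enrichment=3.0)
        g = make_scene("GL", distribution=base, seed=3).geometry

        def cap_fraction(dist):
            scene = make_scene("GL", distribution=dist, seed=3)
            lbl = region_labels(scene.proteins[:, 0], g.length, g.width)
            return np.isin(lbl, ["P1", "P2"]).mean()

        # density multiplier acts on the odds of landing on a cap
        f0, f3 = cap_fraction(base), cap_fraction(rich)
        odds_ratio = (f3 / (1 - f3)) / (f0 / (1 - f0))
        assert abs(odds_ratio - 3.0) / 3.0 < 0.15


class TestRenderFluorescence:
    def test_zero_proteins_zero_gfp(self):
        scene = make_scene(
            "GL", distribution=ProteinDistributionParams(n_points=0),
            optics=QUIET, seed=2,
        )
        fl = render_fluorescence(scene)
        assert np.all(fl.gfp == 0)
        assert fl.chl.max() > 0  # shells still rendered

    def test_photon_conservation_against_kernel_sum(self):
        """Total blurred intensity equals the direct summation of the
        analytic Gaussian kernel over the grid (blur redistributes, never
        creates, photons)."""
        base = make_scene(
            "GL", distribution=ProteinDistributionParams(n_points=0),
            optics=QUIET, seed=4,
        )
        amp = 350.0
        scene = SceneSpec(
            base.geometry, base.shells, np.array([[0.1, 0, amp]]),
            base.distribution, QUIET, seed=4,
        )
        fl = render_fluorescence(scene)
        total = fl.gfp.sum()
        assert abs(total - amp) / amp < 0.01

        r0, c0 = fl.protein_px[0]
        sigma = QUIET.psf_sigma_nm / QUIET.pixel_size_nm
        rows, cols = np.mgrid[0 : fl.gfp.shape[0], 0 : fl.gfp.shape[1]]
        kernel = np.exp(-((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * sigma**2))
        # direct summation of the normalized analytic kernel over the grid
        oracle = amp * (kernel / (2 * np.pi * sigma**2)).sum()
        assert abs(total - oracle) / amp < 0.01

    def test_brightest_pixel_at_ground_truth_point(self):
        base = make_scene(
            "GL", distribution=ProteinDistributionParams(n_points=0),
            optics=QUIET, seed=6,
        )
        scene = SceneSpec(
            base.geometry, base.shells, np.array([[0.25, 0, 200.0]]),
            base.distribution, QUIET, seed=6,
        )
        fl = render_fluorescence(scene)
        r, c = np.unravel_index(np.argmax(fl.gfp), fl.gfp.shape)
        sigma_px = QUIET.psf_sigma_nm / QUIET.pixel_size_nm
        assert np.hypot(r - fl.protein_px[0, 0], c - fl.protein_px[0, 1]) <= sigma_px

    def test_identical_seed_identical_images(self):
        a = render_fluorescence(make_scene("GL", seed=13))
        b = render_fluorescence(make_scene("GL", seed=13))
        np.testing.assert_array_equal(a.gfp, b.gfp)
        np.testing.assert_array_equal(a.chl, b.chl)

    def test_grid_too_small_rejected(self):
        scene = make_scene("GL", seed=1)
        with pytest.raises(ValueError, match="grid too small"):
            render_fluorescence(scene, shape=(20, 20), origin_um=(-0.3, -0.3))


class TestRenderTem:
    def test_empty_shellset_plasma_membrane_only(self):
        base = make_scene(
            "GL", distribution=ProteinDistributionParams(n_points=0), seed=3
        )
        scene = SceneSpec(
            base.geometry, ShellSet(), np.empty((0, 3)), base.distribution,
            base.optics, seed=3,
        )
        tem = render_tem(scene)
        half_nm = base.geometry.radius * 1000.0
        np.testing.assert_allclose(
            tem.transect_positions_nm, [-half_nm, half_nm]
        )
        # interior well away from membranes is flat: low relative spread
        interior = tem.image[tem.footprint]
        assert interior.size > 0

    def test_transect_minima_at_ground_truth_offsets(self):
        from thylaquant.geometry import RodGeometry
        from thylaquant.tem_spacing import detect_layer_peaks, midcell_transect

        g = RodGeometry((2.0, 1.5), 0.0, 3.0, 1.0)
        base = make_scene(
            "custom",
            shells=ShellSet(side1=(Shell(0.0), Shell(109.2))),
            distribution=ProteinDistributionParams(n_points=0),
            geometry=g, seed=5,
        )
        tem = render_tem(
            base,
            optics=OpticsNoiseParams(
                pixel_size_nm=5.0, psf_sigma_nm=3.0, background=0.0,
                poisson_gain=0.0, read_sigma=0.0,
            ),
        )
        # image-local geometry: shift world center by the canvas origin
        g_img = RodGeometry(
            (g.center[0] - tem.origin_um[0], g.center[1] - tem.origin_um[1]),
            g.orientation, g.length, g.width,
        )
        tr = midcell_transect(tem.image, g_img, tem.pixel_size_nm)
        peaks = detect_layer_peaks(tr)
        for gt in tem.transect_positions_nm:
            assert np.min(np.abs(peaks.positions_nm - gt)) <= tem.pixel_size_nm

    def test_hl_preset_one_layer_plus_fragment_on_one_side(self):
        tem = render_tem(make_scene("HL", seed=1))
        gt = tem.transect_positions_nm
        half = np.max(gt)
        side1 = gt[(gt < 0) & (gt > -half)]
        side2 = gt[(gt > 0) & (gt < half)]
        assert len(side1) == 2 and len(side2) == 1

    def test_determinism(self):
        a = render_tem(make_scene("HL", seed=17))
        b = render_tem(make_scene("HL", seed=17))
        np.testing.assert_array_equal(a.image, b.image)
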