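import numpy as np
import pytest

from nervemap import (
    PhantomSpec,
    classify_fibers,
    compute_density_map,
    compute_tissue_mask,
    make_phantom_heart,
    make_phantom_ring,
    make_phantom_slide,
)
from nervemap.phantom import _geometry_mask, inverse_placement
from nervemap.ring import FragmentPlacement, _place, _placement_matrix, assemble_ring


class TestMakePhantomSlide:
    def test_seeded_determinism(self, small_spec):
        s1, t1 = make_phantom_slide(small_spec)
        s2, t2 = make_phantom_slide(small_spec)
        np.testing.assert_array_equal(s1.pixels, s2.pixels)
        np.testing.assert_array_equal(t1.mask, t2.mask)

    def test_zero_fraction_gives_empty_truth(self):
        spec = PhantomSpec(seed=1, canvas=(120, 120), radii=(20, 50), fiber_fraction=0.0)
        slide, truth = make_phantom_slide(spec)
        assert truth.count == 0
        fibers = classify_fibers(slide, compute_tissue_mask(slide))
        dm = compute_density_map(fibers, window_mm2=0.01)
        assert (dm.grid == 0).all()

    def test_fiber_count_within_binomial_band(self):
        """With constant fraction p, the truth count lies within 3 sigma of
        the binomial expectation over the tissue pixels."""
        spec = PhantomSpec(seed=2, canvas=(200, 200), geometry="disc",
                           radii=(0, 60), fiber_fraction=0.2)
        _slide, truth = make_phantom_slide(spec)
        n = _geometry_mask(spec).sum()
        expected = 0.2 * n
        sigma = np.sqrt(n * 0.2 * 0.8)
        assert abs(truth.count - expected) <= 3 * sigma

    def test_truth_bookkeeping_exact(self, phantom_slide):
        _slide, truth = phantom_slide
        assert truth.count == int(truth.mask.sum())

    def test_classification_recovers_truth_exactly(self, phantom_slide):
        """Default stain colours sit strictly inside/outside the default
        HSV range, so pipeline classification equals the truth mask."""
        slide, truth = phantom_slide
        fibers = classify_fibers(slide, compute_tissue_mask(slide))
        np.testing.assert_array_equal(fibers.mask, truth.mask)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(radii=(50, 40))
        with pytest.raises(ValueError):
            PhantomSpec(canvas=(100, 100), radii=(10, 80))

    def test_half_annulus_confined_to_upper_half(self):
        spec = PhantomSpec(seed=3, canvas=(100, 100), geometry="half-annulus", radii=(15, 40))
        _slide, truth = make_phantom_slide(spec)
        tissue = _geometry_mask(spec)
        assert tissue[:50, :].any()
        assert not tissue[51:, :].any()

    def test_curvilinear_mode_stays_in_tissue(self):
        spec = PhantomSpec(seed=4, canvas=(150, 150), radii=(25, 60),
                           fiber_fraction=0.05, curvilinear=True)
        _slide, truth = make_phantom_slide(spec)
        tissue = _geometry_mask(spec)
        assert truth.count > 0
        assert (truth.mask <= tissue).all()


class TestInversePlacement:
    @pytest.mark.parametrize("rotation,flip", [(0.0, False), (90.0, False), (180.0, True),
                                               (270.0, False), (90.0, True)])
    def test_round_trip_is_identity(self, rng, rotation, flip):
        pl = FragmentPlacement("f", translation=(6, -4), rotation=rotation, flip=flip)
        inv = inverse_placement(pl, (80, 80))
        arr = np.zeros((80, 80))
        arr[30:50, 25:45] = rng.random((20, 20))
        a1, t1 = _placement_matrix(pl, (80, 80))
        a2, t2 = _placement_matrix(inv, (80, 80))
        moved = _place(arr, a1, t1, (80, 80), 0.0)
        back = _place(moved, a2, t2, (80, 80), 0.0)
        np.testing.assert_allclose(back, arr, atol=1e-9)


class TestMakePhantomRing:
    def test_single_fragment_identity(self):
        frags, layout, truth = make_phantom_ring(
            PhantomSpec(seed=7, canvas=(160, 160), radii=(25, 70)), n_fragments=1,
            placements=[FragmentPlacement("frag0")],
        )
        np.testing.assert_array_equal(frags["frag0"].tissue, truth.tissue)
        np.testing.assert_array_equal(frags["frag0"].fiber, truth.fiber)

    def test_exact_reassembly_with_default_placements(self):
        frags, layout, truth = make_phantom_ring(
            PhantomSpec(seed=8, canvas=(240, 240), radii=(35, 100)), n_fragments=4
        )
        comp = assemble_ring(frags, layout)
        inter = (comp.tissue & truth.tissue).sum()
        union = (comp.tissue | truth.tissue).sum()
        assert inter / union >= 0.999

    def test_invalid_fragment_count(self):
        with pytest.raises(ValueError):
            make_phantom_ring(PhantomSpec(), n_fragments=0)

    def test_jitter_creates_gaps(self):
        spec = PhantomSpec(seed=9, canvas=(300, 300), radii=(40, 120))
        f0, l0, _ = make_phantom_ring(spec, n_fragments=3, seam_jitter=0.0)
        f2, l2, _ = make_phantom_ring(spec, n_fragments=3, seam_jitter=2.0)
        t0 = sum(f.tissue.sum() for f in f0.values())
        t2 = sum(f.tissue.sum() for f in f2.values())
        assert t2 < t0


class TestMakePhantomHeart:
    def test_too_few_slices_rejected(self):
        with pytest.raises(ValueError):
            make_phantom_heart(1, [0.1])

    def test_gradient_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            make_phantom_heart(3, [0.1, 0.2])

    def test_constant_gradient_mean_densities_stable(self):
        """With a constant gradient, per-slice mean fibre fractions agree
        within sampling noise (CV < 5%)."""
        spec = PhantomSpec(canvas=(200, 200), radii=(30, 90))
        slides, _ref, truth = make_phantom_heart(
            5, [0.05] * 5, spec_template=spec, seed=3, mode="uniform"
        )
        tissue_n = _geometry_mask(spec).sum()
        fracs = [t.count / tissue_n for _s, t in slides]
        assert np.std(fracs) / np.mean(fracs) < 0.05

    def test_sector_mode_mean_follows_gradient(self):
        spec = PhantomSpec(canvas=(200, 200), radii=(30, 90))
        grad = np.linspace(0.02, 0.2, 4)
        slides, _ref, truth = make_phantom_heart(4, grad, spec_template=spec, seed=5)
        tissue_n = _geometry_mask(spec).sum()
        for (s, t), g in zip(slides, grad):
            assert t.count / tissue_n == pytest.approx(g, rel=0.15)

    def test_reference_volume_geometry(self):
        spec = PhantomSpec(canvas=(120, 120), radii=(20, 50))
        _slides, ref, _truth = make_phantom_heart(3, [0.05] * 3, spec_template=spec,
                                                  seed=1, dz_mm=4.0)
        assert ref.voxels.shape == (3, 120, 120)
        assert ref.spacing[0] == 4.0

    def test_truth_fields_match_fraction(self):
        spec = PhantomSpec(canvas=(150, 150), radii=(25, 60))
        grad = [0.01, 0.05, 0.1]
        _slides, _ref, truth = make_phantom_heart(3, grad, spec_template=spec, seed=2)
        tissue = _geometry_mask(spec)
        for field, g in zip(truth.fields, grad):
            assert field[tissue].mean() == pytest.approx(g, rel=0.05)

    def test_seeded_determinism(self):
        spec = PhantomSpec(canvas=(100, 100), radii=(15, 45))
        a, _, _ = make_phantom_heart(2, [0.05, 0.1], spec_template=spec, seed=42)
        b, _, _ = make_phantom_heart(2, [0.05, 0.1], spec_template=spec, seed=42)
        for (s1, t1), (s2, t2) in zip(a, b):
            np.testing.assert_array_equal(s1.pixels, s2.pixels)
            np.testing.assert_array_equal(t1.mask, t2.mask)


class TestEndToEndRecovery:
    def test_density_map_correlates_with_truth_field(self):
        """Window-averaged truth fibre fractions and the pipeline density
        map correlate at r >= 0.9."""
        spec = PhantomSpec(canvas=(300, 300), radii=(45, 135))
        slides, _ref, truth = make_phantom_heart(
            3, [0.02, 0.05, 0.1], spec_template=spec, seed=11
        )
        tissue_geom = _geometry_mask(spec)
        for (slide, _t), field in zip(slides, truth.fields):
            fibers = classify_fibers(slide, compute_tissue_mask(slide))
            dm = compute_density_map(fibers, window_mm2=0.01)
            wp = dm.window_px
            r_, c_ = dm.shape
            truth_win = np.zeros((r_, c_))
            for i in range(r_):
                for j in range(c_):
                    truth_win[i, j] = (field * tissue_geom)[
                        i * wp : (i + 1) * wp, j * wp : (j + 1) * wp
                    ].mean()
            r = np.corrcoef(truth_win.ravel(), dm.grid.ravel())[0, 1]
            assert r >= 0.9
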