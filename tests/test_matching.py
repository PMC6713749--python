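import numpy as np
import pytest

from myotrack.core import BlockSpec, HierarchyParams
from myotrack.matching import (
    ControlPointSet,
    MatchResult,
    decompose,
    hierarchical_match,
    match_block,
    ncc,
    ncc_surface,
    pyramid_validate,
)


def ncc_triple_sum(b, f, lag):
    """Brute-force oracle: explicit triple-sum evaluation of the NCC."""
    p, q, r = lag
    patch = f[p:p + b.shape[0], q:q + b.shape[1], r:r + b.shape[2]]
    fbar, bbar = patch.mean(), b.mean()
    num = d1 = d2 = 0.0
    for x in range(b.shape[0]):
        for y in range(b.shape[1]):
            for z in range(b.shape[2]):
                num += (patch[x, y, z] - fbar) * (b[x, y, z] - bbar)
                d1 += (patch[x, y, z] - fbar) ** 2
                d2 += (b[x, y, z] - bbar) ** 2
    return num / np.sqrt(d1 * d2)


class TestNCC:
    def test_self_correlation_is_one(self, rng):
        b = rng.random((4, 4, 4))
        assert ncc(b, b, (0, 0, 0)) == pytest.approx(1.0, abs=1e-12)

    def test_affine_intensity_invariance(self, rng):
        b = rng.random((4, 4, 4))
        f = 2.5 * b + 0.7
        assert ncc(b, f, (0, 0, 0)) == pytest.approx(1.0, abs=1e-12)

    def test_negated_block_gives_minus_one(self, rng):
        b = rng.random((4, 4, 4))
        b -= b.mean()
        assert ncc(b, -b, (0, 0, 0)) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_triple_sum_oracle(self, rng):
        for _ in range(25):
            b = rng.random((4, 4, 4))
            f = rng.random((9, 8, 10))
            lag = tuple(rng.integers(0, np.array(f.shape) - 4 + 1))
            assert ncc(b, f, lag) == pytest.approx(ncc_triple_sum(b, f, lag), abs=1e-12)

    def test_surface_matches_single_lag_everywhere(self, rng):
        b = rng.random((3, 4, 5))
        f = rng.random((8, 9, 10))
        lam = ncc_surface(b, f)
        for lag in [(0, 0, 0), (5, 5, 5), (2, 3, 1)]:
            assert lam[lag] == pytest.approx(ncc(b, f, lag), abs=1e-10)

    def test_zero_variance_defined_as_zero(self, rng):
        const = np.full((4, 4, 4), 3.0)
        f = rng.random((8, 8, 8))
        assert ncc(const, f, (0, 0, 0)) == 0.0
        assert ncc(f[:4, :4, :4], np.full((8, 8, 8), 1.0), (1, 1, 1)) == 0.0

    def test_block_larger_than_region_raises(self, rng):
        with pytest.raises(ValueError):
            ncc(rng.random((8, 8, 8)), rng.random((4, 4, 4)), (0, 0, 0))
        with pytest.raises(ValueError):
            ncc_surface(rng.random((8, 8, 8)), rng.random((4, 4, 4)))

    def test_fft_path_agrees_with_oracle(self, rng):
        # region large enough to trigger the FFT branch
        b = rng.random((16, 16, 16))
        f = rng.random((40, 40, 40))
        lam = ncc_surface(b, f)
        assert lam.shape == (25, 25, 25)
        for lag in [(0, 0, 0), (12, 7, 3), (24, 24, 24)]:
            assert lam[lag] == pytest.approx(ncc(b, f, lag), abs=1e-9)


class TestDecompose:
    def test_counts_32_cube(self):
        templates = decompose((32, 32, 32), HierarchyParams())
        assert len(templates) == 8
        segs = [s for t in templates for s in t.children()]
        chunks = [c for s in segs for c in s.children()]
        wins = [w for c in chunks for w in c.children()]
        assert (len(segs), len(chunks), len(wins)) == (64, 512, 4096)

    def test_single_template(self):
        assert len(decompose((16, 16, 16), HierarchyParams())) == 1

    def test_trailing_margin_untiled(self):
        templates = decompose((33, 33, 33), HierarchyParams())
        assert len(templates) == 8
        covered = max(t.origin[0] + t.size for t in templates)
        assert covered == 32  # voxel 32 belongs to no template

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError):
            decompose((8, 20, 20), HierarchyParams())


class TestMatchBlock:
    def test_exact_shift_recovery(self, rng):
        f = rng.random((20, 20, 20))
        blk = f[5:9, 3:7, 6:10].copy()
        mr = match_block(blk, f, moving_block=BlockSpec((2, 1, 2), 4, "window"),
                         region_origin=(0, 0, 0))
        assert mr.matched_origin == (5, 3, 6)
        assert mr.cc == pytest.approx(1.0, abs=1e-12)
        assert mr.valid

    def test_tie_broken_by_smallest_displacement(self):
        # two identical copies of the block; the nearer one must win
        region = np.zeros((4, 4, 12))
        blk = np.zeros((2, 2, 2))
        blk[0, 0, 0] = 1.0
        region[1, 1, 2] = 1.0
        region[1, 1, 8] = 1.0
        mr = match_block(blk, region, moving_block=BlockSpec((1, 1, 3), 2, "window"),
                         region_origin=(0, 0, 0), cc_tolerance=1e-9)
        assert mr.matched_origin == (1, 1, 2)  # displacement (0,0,-1) beats (0,0,5)

    def test_constant_block_degenerate(self):
        mr = match_block(np.ones((2, 2, 2)), np.random.default_rng(0).random((6, 6, 6)),
                         moving_block=BlockSpec((3, 3, 3), 2, "window"),
                         region_origin=(0, 0, 0))
        assert not mr.valid
        assert mr.matched_origin == (3, 3, 3)

    def test_empty_lag_set_raises(self, rng):
        with pytest.raises(ValueError):
            match_block(rng.random((8, 8, 8)), rng.random((4, 8, 8)),
                        moving_block=BlockSpec((0, 0, 0), 8, "segment"),
                        region_origin=(0, 0, 0))


class TestPyramidValidate:
    def _mr(self, origin, disp, size=8):
        block = BlockSpec(origin, size, "segment")
        return MatchResult(block, tuple(np.array(origin) + disp), 0.9, True)

    def test_agreement_valid(self):
        seg = self._mr((8, 8, 8), (3, 0, 0))
        ovs = [self._mr((7, 7, 7), (3, 0, 0), 10), self._mr((6, 6, 6), (2, 1, 0), 12)]
        assert pyramid_validate(seg, ovs, tol=2.0)

    def test_disagreement_invalid(self):
        seg = self._mr((8, 8, 8), (3, 0, 0))
        ovs = [self._mr((7, 7, 7), (0, 0, 0), 10)]
        assert not pyramid_validate(seg, ovs, tol=1.0)

    def test_infinite_tolerance_always_valid(self):
        seg = self._mr((8, 8, 8), (5, -5, 5))
        ovs = [self._mr((7, 7, 7), (-5, 5, -5), 10)]
        assert pyramid_validate(seg, ovs, tol=np.inf)


def _textured(shape, rng):
    """Aperiodic smooth texture with voxel-scale detail for match tests."""
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(rng.standard_normal(shape), 1.0)


class TestHierarchicalMatch:
    def test_identity_all_non_displaced(self, rng):
        img = _textured((32, 32, 32), rng)
        cps = hierarchical_match(img, img, HierarchyParams(search_radius=6))
        assert len(cps) == 4096
        assert np.array_equal(cps.moving, cps.reference)
        assert cps.valid.all()

    def test_translation_recovered_at_interior_windows(self, rng):
        ref = _textured((32, 32, 32), rng)
        d = np.array([2, -1, 3])
        mov = np.zeros_like(ref)
        # moving[x] = ref[x - d]
        mov[2:, :31, 3:] = ref[:30, 1:, :29]
        cps = hierarchical_match(mov, ref, HierarchyParams(search_radius=6))
        disp = cps.reference - cps.moving
        interior = np.all((cps.moving >= 6) & (cps.moving < 24), axis=1)
        good = cps.valid & interior
        assert good.sum() > 100
        assert np.all(disp[good] == -d)

    def test_constant_frame_all_degenerate(self):
        img = np.full((32, 32, 32), 2.0)
        cps = hierarchical_match(img, img, HierarchyParams(search_radius=4))
        assert (~cps.valid).all()
        assert cps.degenerate.all()
        assert np.array_equal(cps.moving, cps.reference)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            hierarchical_match(rng.random((32, 32, 32)), rng.random((32, 32, 16)),
                               HierarchyParams())

    def test_every_window_appears_once(self, rng):
        img = _textured((32, 32, 32), rng)
        params = HierarchyParams(search_radius=4)
        cps = hierarchical_match(img, img, params)
        windows = {
            w.representative_point
            for t in decompose(img.shape, params)
            for s in t.children() for c in s.children() for w in c.children()
        }
        seen = {tuple(p) for p in cps.moving}
        assert seen == windows
        assert len(cps) == len(windows)

    def test_translation_equivariance(self, rng):
        # shifting both images identically leaves interior displacements unchanged
        base = _textured((40, 32, 32), rng)
        ref = base[:32]
        mov = np.roll(ref, 1, axis=1)  # some in-plane motion to estimate
        cps1 = hierarchical_match(mov, ref, HierarchyParams(search_radius=4))
        ref2 = base[8:40]
        mov2 = np.roll(ref2, 1, axis=1)
        cps2 = hierarchical_match(mov2, ref2, HierarchyParams(search_radius=4))
        d1 = {tuple(m): tuple(r - m) for m, r, v in zip(cps1.moving, cps1.displacements + cps1.moving, cps1.valid) if v}
        d2 = {tuple(m): tuple(r - m) for m, r, v in zip(cps2.moving, cps2.displacements + cps2.moving, cps2.valid) if v}
        shared = [k for k in d1 if k in d2 and 8 <= k[0] < 24]
        assert len(shared) > 100
        agree = sum(d1[k] == d2[k] for k in shared)
        assert agree / len(shared) > 0.95

    def test_monotone_containment_of_matches(self, rng):
        # every valid window's matched position lies within the image and its
        # displacement within the template search range
        ref = _textured((32, 32, 32), rng)
        mov = np.roll(ref, (1, -2, 0), axis=(0, 1, 2))
        params = HierarchyParams(search_radius=5)
        cps = hierarchical_match(mov, ref, params)
        v = cps.valid
        assert np.all(cps.reference[v] >= 0)
        assert np.all(cps.reference[v] + params.level_sizes["window"] <= 32)
        # window displacement bounded by template search + nested slack
        assert np.all(np.abs(cps.displacements[v]) <= params.search_radius + params.template_size)


def test_control_point_set_invariants():
    with pytest.raises(ValueError):
        ControlPointSet(
            moving=np.array([[0, 0, 0]]),
            reference=np.array([[1, 0, 0]]),
            cc=np.array([0.5]),
            valid=np.array([False]),  # invalid pair must be non-displaced
        )
    cps = ControlPointSet(
        moving=np.array([[0, 0, 0], [2, 0, 0]]),
        reference=np.array([[1, 0, 0], [2, 0, 0]]),
        cc=np.array([0.9, 0.0]),
        valid=np.array([True, False]),
        degenerate=np.array([False, True]),
    )
    assert len(cps.informative()) == 1
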