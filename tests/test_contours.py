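"""Contour data model, resampling and the DTW similarity primitive."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import dtw_brute_force, make_contour
from whistlekit.contours import (
    ContourSet,
    WhistleContour,
    dtw_align,
    read_contours_csv,
    resample_contour,
    similarity,
    similarity_arrays,
    write_contours_csv,
)
from whistlekit.errors import (
    InfeasibleAlignmentError,
    InvalidInputError,
    InvalidParameterError,
)


class TestDataModel:
    def test_contour_validation(self):
        with pytest.raises(InvalidInputError):
            make_contour([5.0])  # single point
        with pytest.raises(InvalidInputError):
            make_contour([5.0, -1.0])  # non-positive frequency
        with pytest.raises(InvalidParameterError):
            make_contour([5.0, 6.0], dt_s=0.0)
        with pytest.raises(InvalidParameterError):
            make_contour([5.0, 6.0], snr_class="great")

    def test_duration_identity(self):
        c = make_contour(np.full(11, 5.0), dt_s=0.01)
        assert c.duration_s == pytest.approx(0.1)

    def test_contour_set_rejects_duplicate_ids(self):
        cs = ContourSet([make_contour([5, 6], cid="a")])
        with pytest.raises(InvalidInputError):
            cs.add(make_contour([5, 6], cid="a"))
        assert "a" in cs and len(cs) == 1


class TestResample:
    def test_constant_contour_stays_constant(self):
        c = make_contour(np.full(21, 5.0), dt_s=0.01)
        for dt in (0.002, 0.0137, 0.05):
            r = resample_contour(c, dt)
            assert np.allclose(r.freqs_khz, 5.0)
            assert r.duration_s == pytest.approx(c.duration_s)

    def test_linear_midpoints(self):
        # 5 -> 10 kHz over 0.5 s; halving the spacing inserts 7.5 at the middle
        c = make_contour(np.linspace(5, 10, 11), dt_s=0.05)
        r = resample_contour(c, 0.025)
        assert r.n_points == 21
        assert r.freqs_khz[10] == pytest.approx(7.5)
        assert r.freqs_khz[0] == 5.0 and r.freqs_khz[-1] == 10.0

    def test_round_trip_bounded_by_interpolation_error(self, rng):
        """Down- then up-sampling deviates by no more than the local linear
        interpolation error of an independent brute-force interpolator."""
        f = 6 + np.cumsum(rng.normal(0, 0.2, 40))
        f = np.clip(f, 2, 15)
        c = make_contour(f, dt_s=0.005)
        down = resample_contour(c, 0.012)
        back = resample_contour(down, 0.005)
        # brute-force oracle: pointwise linear interpolation of the coarse grid
        t_c = np.arange(down.n_points) * down.dt_s
        t_f = np.arange(back.n_points) * back.dt_s
        expect = np.array([
            np.interp(t, t_c, down.freqs_khz) for t in t_f
        ])
        assert np.max(np.abs(back.freqs_khz - expect)) < 1e-12

    def test_invalid_spacing(self, flat5):
        with pytest.raises(InvalidParameterError):
            resample_contour(flat5, 0.0)


class TestDtw:
    def test_identity_alignment_is_100(self, rng):
        for _ in range(5):
            f = rng.uniform(2, 15, int(rng.integers(5, 60)))
            c = make_contour(f)
            assert dtw_align(c, c, 3).similarity_pct == pytest.approx(100.0)

    def test_constant_5_vs_10_is_50(self):
        a = make_contour(np.full(6, 5.0))
        b = make_contour(np.full(6, 10.0))
        assert similarity(a, b, 3) == pytest.approx(50.0)
        # frozen from the exhaustive oracle on the same pair
        assert dtw_brute_force(a.freqs_khz, b.freqs_khz, 3) == pytest.approx(50.0)

    @pytest.mark.parametrize("warp", [1, 2, 3])
    def test_matches_exhaustive_enumeration(self, warp, rng):
        """DP similarity equals brute-force max over all admissible paths
        on random pairs of <= 8-point contours."""
        for _ in range(12):
            fa = rng.uniform(2, 16, int(rng.integers(2, 9)))
            fb = rng.uniform(2, 16, int(rng.integers(2, 9)))
            oracle = dtw_brute_force(fa, fb, warp)
            got = similarity_arrays(fa, fb, warp)
            if oracle is None:
                assert got == 0.0
            else:
                assert got == pytest.approx(oracle, abs=1e-9)

    def test_symmetry(self, rng):
        for _ in range(50):
            fa = rng.uniform(2, 16, int(rng.integers(5, 40)))
            fb = rng.uniform(2, 16, int(rng.integers(5, 40)))
            a, b = make_contour(fa, cid="a"), make_contour(fb, cid="b")
            assert similarity(a, b, 3) == pytest.approx(similarity(b, a, 3), abs=1e-9)

    @pytest.mark.parametrize("stretch", [1.5, 2, 3])
    def test_invariant_to_admissible_time_stretch(self, stretch, rng):
        """Stretching one contour up to the warp factor (frequency values
        unchanged) leaves similarity at 100."""
        for _ in range(7):
            f = rng.uniform(3, 12, int(rng.integers(8, 30)))
            idx = np.floor(np.arange(int(round(f.size * stretch))) / stretch)
            g = f[idx.astype(int).clip(max=f.size - 1)]
            assert similarity_arrays(f, g, 3) == pytest.approx(100.0)

    def test_stretch_beyond_warp_not_fully_alignable(self, rng):
        f = rng.uniform(3, 12, 12)
        g = f[np.repeat(np.arange(f.size), 4)]
        assert similarity_arrays(f, g, 3) < 100.0

    def test_bounds_and_equality_condition(self, rng):
        for _ in range(20):
            fa = rng.uniform(2, 16, 15)
            fb = rng.uniform(2, 16, 15)
            s = similarity_arrays(fa, fb, 3)
            assert 0.0 <= s <= 100.0
            if not np.array_equal(fa, fb):
                # 100 requires every aligned pair equal
                al = dtw_align(make_contour(fa), make_contour(fb), 3)
                pairs_equal = np.allclose(fa[al.path[:, 0]], fb[al.path[:, 1]])
                assert (al.similarity_pct == pytest.approx(100.0)) == pairs_equal

    def test_path_is_monotone_and_complete(self, rng):
        a = make_contour(rng.uniform(3, 12, 20))
        b = make_contour(rng.uniform(3, 12, 35))
        al = dtw_align(a, b, 3)
        steps = np.diff(al.path, axis=0)
        assert tuple(al.path[0]) == (0, 0)
        assert tuple(al.path[-1]) == (19, 34)
        assert (steps >= 0).all() and (steps.sum(axis=1) >= 1).all()

    def test_infeasible_alignment(self):
        a = make_contour(np.full(4, 5.0))
        b = make_contour(np.full(40, 5.0))
        with pytest.raises(InfeasibleAlignmentError):
            dtw_align(a, b, 3)
        assert similarity(a, b, 3) == 0.0

    def test_warp_factor_validation(self, flat5):
        with pytest.raises(InvalidParameterError):
            dtw_align(flat5, flat5, 0)


class TestContourCsv:
    def test_round_trip_exact_and_byte_stable(self, tmp_path, rng):
        cs = ContourSet(
            make_contour(
                rng.uniform(2, 16, int(rng.integers(3, 30))),
                cid=f"w{k:03d}",
                onset_s=float(rng.uniform(0, 100)),
                visual_label=None if k % 3 else "A",
                snr_class=["high", "medium", "low"][k % 3],
            )
            for k in range(10)
        )
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_contours_csv(cs, p1)
        back = read_contours_csv(p1)
        assert back.ids() == cs.ids()
        for cid in cs.ids():
            assert np.array_equal(back[cid].freqs_khz, cs[cid].freqs_khz)
            assert back[cid].onset_s == cs[cid].onset_s
            assert back[cid].dt_s == cs[cid].dt_s
            assert back[cid].visual_label == cs[cid].visual_label
        write_contours_csv(back, p2)
        assert p1.read_bytes() == p2.read_bytes()
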