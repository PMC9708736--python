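"""Stage-1 tests: dense scoring, selection, consistency filtering."""

import numpy as np
import pytest

from celmfuse import (
    consistency_filter,
    initial_fuse,
    label_map,
    make_texture,
    score_map,
)
from celmfuse.network import elm_predict, pair_features


def consistency_oracle(c, a, b, f):
    """Literal transcription of the three neighbour-sum rules."""
    h, w = c.shape
    cp = np.pad(c, 1, mode="edge")
    f_out = f.copy().astype(float)
    c_out = c.copy()
    for i in range(h):
        for j in range(w):
            s = cp[i : i + 3, j : j + 3].sum() - cp[i + 1, j + 1]
            if s >= 5:
                f_out[i, j], c_out[i, j] = a[i, j], 1
            elif s <= 3:
                f_out[i, j], c_out[i, j] = b[i, j], 0
    return f_out, c_out


class TestScoreMap:
    def test_output_matches_source_dimensions(self, small_model, rng):
        a, b = rng.random((50, 41)), rng.random((50, 41))
        for stride in (1, 3, 4, 7):
            assert score_map(a, b, small_model, stride=stride).shape == (50, 41)

    def test_equal_inputs_give_symmetric_map(self, small_model, rng):
        a = rng.random((40, 40))
        np.testing.assert_array_equal(
            score_map(a, a, small_model), score_map(a, a, small_model)
        )

    def test_grid_scores_subset_of_exact(self, small_model, rng):
        a, b = rng.random((48, 44)), rng.random((48, 44))
        exact = score_map(a, b, small_model, exact=True)
        coarse = score_map(a, b, small_model, stride=4)
        gy, gx = np.arange(0, 48, 4), np.arange(0, 44, 4)
        np.testing.assert_array_equal(
            coarse[np.ix_(gy, gx)], exact[np.ix_(gy, gx)]
        )

    def test_matches_patchwise_evaluation(self, small_model, rng):
        # the whole-image convolutional evaluation must agree with
        # scoring each reflect-padded pixel-centred patch directly
        a, b = rng.random((45, 39)), rng.random((45, 39))
        exact = score_map(a, b, small_model, exact=True)
        cfg = small_model.config
        pad = cfg.patch_size // 2
        ap = np.pad(a, pad, mode="reflect")
        bp = np.pad(b, pad, mode="reflect")
        p = cfg.patch_size
        for i, j in [(0, 0), (44, 38), (17, 5), (30, 21), (3, 33)]:
            s = elm_predict(
                pair_features(
                    ap[i : i + p, j : j + p], bp[i : i + p, j : j + p],
                    small_model.bank, cfg,
                ),
                small_model.elm,
            )
            assert exact[i, j] == pytest.approx(s, abs=1e-9)

    def test_size_mismatch_rejected(self, small_model, rng):
        with pytest.raises(ValueError):
            score_map(rng.random((40, 40)), rng.random((40, 41)), small_model)

    def test_too_small_image_rejected(self, small_model, rng):
        with pytest.raises(ValueError):
            score_map(rng.random((16, 16)), rng.random((16, 16)), small_model)


class TestLabelMap:
    def test_extremes(self):
        assert np.all(label_map(np.ones((4, 4))) == 1)
        assert np.all(label_map(np.zeros((4, 4))) == 0)

    def test_tie_goes_to_a(self):
        np.testing.assert_array_equal(
            label_map(np.array([[0.49, 0.5, 0.51]])), [[0, 1, 1]]
        )

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            label_map(np.zeros((2, 2)), threshold=1.0)


class TestInitialFuse:
    def test_pure_selections(self, rng):
        a, b = rng.random((10, 10)), rng.random((10, 10))
        f, c = initial_fuse(a, b, np.ones((10, 10), dtype=int))
        np.testing.assert_array_equal(f, a)
        assert np.all(c == 1)
        f, c = initial_fuse(a, b, np.zeros((10, 10), dtype=int))
        np.testing.assert_array_equal(f, b)

    def test_identical_sources(self, rng):
        a = rng.random((8, 8))
        labels = (rng.random((8, 8)) > 0.5).astype(int)
        f, _ = initial_fuse(a, a, labels)
        np.testing.assert_array_equal(f, a)

    def test_selection_closure(self, rng):
        a, b = rng.random((12, 12)), rng.random((12, 12))
        labels = (rng.random((12, 12)) > 0.5).astype(int)
        f, _ = initial_fuse(a, b, labels)
        assert np.all((f == a) | (f == b))


class TestConsistencyFilter:
    def test_unanimous_map_selects_a(self, rng):
        a, b = rng.random((9, 9)), rng.random((9, 9))
        c = np.ones((9, 9), dtype=int)
        f, _ = initial_fuse(a, b, c)
        f2, c2 = consistency_filter(c, a, b, f)
        np.testing.assert_array_equal(f2, a)
        assert np.all(c2 == 1)

    def test_isolated_pixel_flips(self, rng):
        a, b = rng.random((7, 7)), rng.random((7, 7))
        c = np.zeros((7, 7), dtype=int)
        c[3, 3] = 1
        f, _ = initial_fuse(a, b, c)
        f2, c2 = consistency_filter(c, a, b, f)
        assert f2[3, 3] == b[3, 3]
        assert c2[3, 3] == 0

    def test_exhaustive_3x3_neighbourhoods(self):
        # all 512 binary patterns against the literal-rule oracle
        rng = np.random.default_rng(0)
        a, b = rng.random((3, 3)), rng.random((3, 3))
        for code in range(512):
            c = np.array([(code >> k) & 1 for k in range(9)]).reshape(3, 3)
            f, _ = initial_fuse(a, b, c)
            got_f, got_c = consistency_filter(c, a, b, f)
            exp_f, exp_c = consistency_oracle(c, a, b, f)
            np.testing.assert_array_equal(got_f, exp_f)
            np.testing.assert_array_equal(got_c, exp_c)

    def test_single_pass_no_cascade(self, rng):
        # a 2-wide diagonal stripe: with cascading updates the stripe
        # would erode from one end; single-pass must treat all pixels
        # against the ORIGINAL map
        c = np.zeros((8, 8), dtype=int)
        for i in range(8):
            for j in range(8):
                if abs(i - j) <= 1:
                    c[i, j] = 1
        a, b = rng.random((8, 8)), rng.random((8, 8))
        f, _ = initial_fuse(a, b, c)
        f2, c2 = consistency_filter(c, a, b, f)
        exp_f, exp_c = consistency_oracle(c, a, b, f)
        np.testing.assert_array_equal(f2, exp_f)
        np.testing.assert_array_equal(c2, exp_c)
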