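"""Intensity-fraction colocalization and puncta scoring."""

import numpy as np
import pytest

from stingquant.coloc import (
    DegenerateCellError,
    coloc_fraction,
    coloc_fraction_puncta_mode,
    detect_puncta,
    puncta_mean_intensity,
    resolve_threshold,
)
from stingquant.image import CellROI, ImageField, ThresholdSpec


def _field(a, b=None):
    ch = {"chA": np.asarray(a, dtype=float)}
    if b is not None:
        ch["chB"] = np.asarray(b, dtype=float)
    return ImageField(channels=ch)


def _oracle_fraction(src, tgt, mask, percentile, offset):
    """Independent re-implementation: explicit loops + sort-based percentile."""
    vals = sorted(tgt[y][x] for y in range(len(tgt)) for x in range(len(tgt[0])) if mask[y][x])
    pos = percentile / 100.0 * (len(vals) - 1)
    lo, hi = int(np.floor(pos)), int(np.ceil(pos))
    thr = vals[lo] + (pos - lo) * (vals[hi] - vals[lo]) + offset
    num = den = 0.0
    for y in range(len(src)):
        for x in range(len(src[0])):
            if mask[y][x]:
                den += src[y][x]
                if tgt[y][x] >= thr:
                    num += src[y][x]
    return num / den


class TestResolveThreshold:
    def test_matches_sorted_percentile_plus_offset(self, full_roi):
        img = _field(np.arange(256, dtype=float).reshape(16, 16))
        got = resolve_threshold(img, full_roi, "chA", ThresholdSpec(90.0, 5.0))
        assert got == pytest.approx(np.percentile(np.arange(256.0), 90) + 5)

    def test_threshold_is_per_cell(self):
        # two cells with disjoint intensity ranges resolve different values
        img = _field(np.concatenate([np.full((8, 16), 10.0), np.full((8, 16), 100.0)]))
        top = CellROI("top", mask=np.pad(np.ones((8, 16), bool), ((0, 8), (0, 0))))
        bot = CellROI("bot", mask=np.pad(np.ones((8, 16), bool), ((8, 0), (0, 0))))
        spec = ThresholdSpec(50.0, 1.0)
        assert resolve_threshold(img, top, "chA", spec) == 11.0
        assert resolve_threshold(img, bot, "chA", spec) == 101.0


class TestColocFraction:
    def test_target_everywhere_above_threshold_gives_one(self, full_roi):
        img = _field(np.random.default_rng(0).uniform(1, 10, (16, 16)),
                     np.full((16, 16), 50.0))
        m = coloc_fraction(img, full_roi, "chA", "chB",
                          target_spec=ThresholdSpec(0.0, 0.0))
        assert m.fraction == 1.0

    def test_target_nowhere_above_threshold_gives_zero(self, full_roi):
        img = _field(np.random.default_rng(1).uniform(1, 10, (16, 16)),
                     np.full((16, 16), 50.0))
        m = coloc_fraction(img, full_roi, "chA", "chB",
                          target_spec=ThresholdSpec(100.0, 1.0))
        assert m.fraction == 0.0

    def test_hand_computed_three_by_three(self):
        # source 10 at p1=(0,0), 20 at p2=(1,1); target above threshold at p2 only
        src = np.zeros((3, 3)); src[0, 0] = 10.0; src[1, 1] = 20.0
        tgt = np.zeros((3, 3)); tgt[1, 1] = 100.0
        roi = CellROI("c", mask=np.ones((3, 3), bool))
        m = coloc_fraction(_field(src, tgt), roi, "chA", "chB",
                           target_spec=ThresholdSpec(100.0, 0.0))
        assert m.fraction == pytest.approx(20.0 / 30.0)

    def test_matches_independent_oracle_on_random_rasters(self, full_roi):
        rng = np.random.default_rng(7)
        for _ in range(5):
            src = rng.uniform(0, 100, (16, 16))
            tgt = rng.uniform(0, 100, (16, 16))
            img = _field(src, tgt)
            for pct in (50.0, 90.0):
                got = coloc_fraction(
                    img, full_roi, "chA", "chB", target_spec=ThresholdSpec(pct, 2.0)
                ).fraction
                want = _oracle_fraction(src, tgt, np.ones((16, 16), bool), pct, 2.0)
                assert got == pytest.approx(want, abs=1e-12)

    def test_zero_source_intensity_is_an_error_not_zero(self, full_roi):
        img = _field(np.zeros((16, 16)), np.ones((16, 16)))
        with pytest.raises(DegenerateCellError, match="cell"):
            coloc_fraction(img, full_roi, "chA", "chB")

    def test_monotone_nonincreasing_in_target_threshold(self, random_two_channel, full_roi):
        fracs = [
            coloc_fraction(
                random_two_channel, full_roi, "chA", "chB",
                target_spec=ThresholdSpec(p, 0.0),
            ).fraction
            for p in (0.0, 25.0, 50.0, 75.0, 90.0, 99.0, 100.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_source_floor_restricts_denominator(self):
        # floor excludes the dim source pixel from both sums
        src = np.zeros((3, 3)); src[0, 0] = 10.0; src[1, 1] = 20.0
        tgt = np.zeros((3, 3)); tgt[1, 1] = 100.0
        roi = CellROI("c", mask=np.ones((3, 3), bool))
        m = coloc_fraction(
            _field(src, tgt), roi, "chA", "chB",
            target_spec=ThresholdSpec(100.0, 0.0),
            source_floor=ThresholdSpec(0.0, 15.0),
        )
        assert m.fraction == pytest.approx(1.0)


class TestPunctaMode:
    def test_equal_specs_equal_fractions(self, random_two_channel, full_roi):
        spec = ThresholdSpec(90.0, 0.0)
        a = coloc_fraction(random_two_channel, full_roi, "chA", "chB", target_spec=spec)
        b = coloc_fraction_puncta_mode(
            random_two_channel, full_roi, "chA", "chB", elevated_spec=spec
        )
        assert a.fraction == b.fraction
        assert b.mode == "puncta"

    def test_percentile_100_with_offset_gives_zero(self, random_two_channel, full_roi):
        m = coloc_fraction_puncta_mode(
            random_two_channel, full_roi, "chA", "chB",
            elevated_spec=ThresholdSpec(100.0, 1.0),
        )
        assert m.fraction == 0.0

    def test_elevated_threshold_never_increases_fraction(self, random_two_channel, full_roi):
        base = coloc_fraction(
            random_two_channel, full_roi, "chA", "chB",
            target_spec=ThresholdSpec(80.0, 0.0),
        ).fraction
        for pct in (85.0, 90.0, 95.0, 99.0):
            elevated = coloc_fraction_puncta_mode(
                random_two_channel, full_roi, "chA", "chB",
                elevated_spec=ThresholdSpec(pct, 0.0),
            ).fraction
            assert elevated <= base + 1e-12


class TestDetectPuncta:
    def _blob_image(self):
        img = np.zeros((16, 16))
        img[2:4, 2:4] = 100.0  # 4 px
        img[2, 4] = 100.0      # -> 5 px blob
        img[10:12, 10:12] = 80.0
        img[12, 12] = 80.0     # diagonal: 8-connectivity joins -> 5 px blob
        return img

    def test_blank_channel_zero_puncta(self, full_roi):
        img = _field(np.zeros((16, 16)) + 1.0)
        labels = detect_puncta(img, full_roi, "chA", ThresholdSpec(0.0, 5.0), 1)
        assert labels.max() == 0

    def test_two_blobs_min_area_three(self, full_roi):
        labels = detect_puncta(
            _field(self._blob_image()), full_roi, "chA",
            ThresholdSpec(0.0, 50.0), min_area=3,
        )
        assert labels.max() == 2

    def test_diagonal_pixels_join_under_8_connectivity(self, full_roi):
        labels = detect_puncta(
            _field(self._blob_image()), full_roi, "chA",
            ThresholdSpec(0.0, 70.0), min_area=5,
        )
        # both blobs survive only because the diagonal pixel counts
        assert labels.max() == 2

    def test_min_area_above_every_blob_gives_zero(self, full_roi):
        labels = detect_puncta(
            _field(self._blob_image()), full_roi, "chA",
            ThresholdSpec(0.0, 50.0), min_area=10,
        )
        assert labels.max() == 0

    def test_count_monotone_in_threshold_and_min_area(self):
        # unimodal, non-overlapping spots: raising the threshold shrinks each
        # spot (never splits it), so counts can only stay or drop
        from stingquant.synth import _render_spots

        img = np.zeros((64, 64))
        centers = np.array(
            [[10, 10], [30, 10], [50, 10], [10, 40], [30, 40], [50, 40]], float
        )
        amps = np.linspace(50, 300, 6)
        for c, a in zip(centers, amps):
            _render_spots(img, c[None, :], a, 1.5)
        field = _field(img)
        roi = CellROI("c", mask=np.ones((64, 64), bool))
        counts_thr = [
            detect_puncta(field, roi, "chA", ThresholdSpec(0.0, off), 1).max()
            for off in (20.0, 60.0, 120.0, 250.0, 400.0)
        ]
        assert counts_thr[0] >= 1
        assert all(a >= b for a, b in zip(counts_thr, counts_thr[1:]))
        counts_area = [
            detect_puncta(field, roi, "chA", ThresholdSpec(0.0, 20.0), a).max()
            for a in (1, 4, 9, 25)
        ]
        assert all(a >= b for a, b in zip(counts_area, counts_area[1:]))


class TestPunctaMeanIntensity:
    def test_single_uniform_punctum(self, full_roi):
        img = np.zeros((16, 16)); img[3:6, 3:6] = 200.0
        m = puncta_mean_intensity(_field(img), full_roi, "chA",
                                  ThresholdSpec(0.0, 100.0), 2)
        assert m.mean_puncta_intensity == 200.0
        assert m.puncta_count == 1
        assert m.above_threshold_area == 9

    def test_zero_puncta_scores_zero_by_convention(self, full_roi):
        img = _field(np.ones((16, 16)))
        m = puncta_mean_intensity(img, full_roi, "chA", ThresholdSpec(0.0, 10.0), 2)
        assert m.mean_puncta_intensity == 0.0
        assert m.puncta_count == 0

    def test_pixel_weighted_versus_per_punctum_mean(self, full_roi):
        img = np.zeros((16, 16))
        img[2:4, 2:4] = 100.0     # 4 px at 100
        img[10:12, 10:14] = 200.0  # 8 px at 200
        field = _field(img)
        spec = ThresholdSpec(0.0, 50.0)
        pw = puncta_mean_intensity(field, full_roi, "chA", spec, 2)
        assert pw.mean_puncta_intensity == pytest.approx((400 + 1600) / 12)
        pp = puncta_mean_intensity(field, full_roi, "chA", spec, 2, per_punctum=True)
        assert pp.mean_puncta_intensity == pytest.approx(150.0)

    def test_equal_sized_puncta_pixel_weighted_mean(self, full_roi):
        img = np.zeros((16, 16))
        img[2:4, 2:4] = 100.0
        img[10:12, 10:12] = 200.0
        m = puncta_mean_intensity(_field(img), full_roi, "chA",
                                  ThresholdSpec(0.0, 50.0), 2)
        assert m.mean_puncta_intensity == pytest.approx(150.0)

    def test_mean_at_least_threshold_when_puncta_present(self, random_two_channel, full_roi):
        m = puncta_mean_intensity(random_two_channel, full_roi, "chA",
                                  ThresholdSpec(90.0, 0.0), 1)
        if m.puncta_count > 0:
            assert m.mean_puncta_intensity >= m.threshold
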