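"""Segmentation, inclusion filtering, foci counting and cfoci."""

import numpy as np
import pytest

import slicequant as sq
from slicequant.nuclei import FociParams, NucleusRecord, records_to_frame

from _oracles import enumerate_maxima, match_points

PARAMS = FociParams(pixel_size=0.25)


class TestSegmentation:
    def test_uniform_raster_zero_nuclei(self):
        with pytest.warns(UserWarning, match="constant"):
            labels, records = sq.segment_nuclei(np.zeros((64, 64)), 0.25)
        assert labels.max() == 0 and records == []

    def test_disjoint_ellipses_recovered_with_areas(self):
        dapi, _, truth = sq.generate_foci_scene(
            20, ("fixed", 0), seed=6, shape=(512, 512)
        )
        labels, records = sq.segment_nuclei(dapi, truth.pixel_size)
        assert len(records) == 20
        by_label = {r.label: r for r in records}
        for nuc in truth.nuclei:
            x, y = int(round(nuc.center[0])), int(round(nuc.center[1]))
            seg_label = labels[y, x]
            assert seg_label > 0, "truth center must fall in a segmented nucleus"
            rel_err = abs(by_label[seg_label].area_um2 - nuc.area_um2) / nuc.area_um2
            assert rel_err < 0.05

    def test_touching_pair_split(self):
        dapi, _, truth = sq.generate_foci_scene(
            2, ("fixed", 0), seed=8, shape=(256, 256), touching_fraction=1.0
        )
        labels, records = sq.segment_nuclei(dapi, truth.pixel_size, split_touching=True)
        seg_at_centers = {
            labels[int(round(n.center[1])), int(round(n.center[0]))] for n in truth.nuclei
        }
        assert len(records) == 2
        assert len(seg_at_centers) == 2 and 0 not in seg_at_centers

    def test_non_finite_rejected(self):
        img = np.zeros((32, 32))
        img[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            sq.segment_nuclei(img, 0.25)


def _rec(label, area, **kw):
    return NucleusRecord(label=label, area_um2=area, centroid=(0.0, 0.0), **kw)


class TestInclusion:
    def test_area_filter_is_strictly_above(self):
        records = [_rec(1, 60.0), _rec(2, 64.9), _rec(3, 65.0), _rec(4, 65.1), _rec(5, 100.0)]
        out = sq.apply_inclusion(records, PARAMS)
        status = {r.label: (r.included, r.exclusion_reason) for r in out}
        assert status[1] == (False, "below_area")
        assert status[2] == (False, "below_area")
        assert status[3] == (False, "below_area")  # exactly 65 is not "above 65"
        assert status[4] == (True, "none")
        assert status[5] == (True, "none")

    def test_exclusion_list_and_unknown_label(self):
        records = [_rec(1, 100.0), _rec(2, 100.0)]
        out = sq.apply_inclusion(records, PARAMS, exclusion_list={2})
        assert [r.exclusion_reason for r in out] == ["none", "listed_excluded"]
        with pytest.raises(ValueError, match="99"):
            sq.apply_inclusion(records, PARAMS, exclusion_list={99})

    def test_border_policy(self):
        labels = np.zeros((32, 32), dtype=int)
        labels[0:5, 10:20] = 1  # touches the top border
        labels[15:25, 10:20] = 2
        records = [_rec(1, 100.0), _rec(2, 100.0)]
        out = sq.apply_inclusion(records, PARAMS, label_raster=labels, border_policy="drop")
        assert {r.label: r.exclusion_reason for r in out} == {1: "border", 2: "none"}
        out = sq.apply_inclusion(records, PARAMS, label_raster=labels, border_policy="keep")
        assert all(r.included for r in out)

    def test_excluded_nuclei_carry_zero_foci(self):
        records = [_rec(1, 10.0, foci_count=7), _rec(2, 100.0, foci_count=7)]
        out = sq.apply_inclusion(records, PARAMS)
        assert out[0].foci_count == 0 and out[1].foci_count == 7

    def test_area_min_monotonicity(self):
        rng = np.random.default_rng(0)
        records = [_rec(i + 1, a) for i, a in enumerate(rng.uniform(20, 200, 50))]
        n_prev = None
        for area_min in [0, 40, 65, 100, 150, 250]:
            p = FociParams(pixel_size=0.25, area_min_um2=area_min)
            n = sum(r.included for r in sq.apply_inclusion(records, p))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n


class TestCountFoci:
    def test_flat_channel_zero_foci(self):
        labels = np.zeros((64, 64), dtype=int)
        labels[20:40, 20:40] = 1
        res = sq.count_foci(np.zeros((64, 64)), labels, PARAMS)
        assert res.counts == {1: 0}

    def test_single_spot_single_focus(self):
        labels = np.zeros((64, 64), dtype=int)
        labels[16:48, 16:48] = 1
        gamma = np.zeros((64, 64))
        yy, xx = np.mgrid[0:64, 0:64]
        gamma += np.exp(-((xx - 32) ** 2 + (yy - 32) ** 2) / (2 * 4.0))
        res = sq.count_foci(gamma, labels, PARAMS)
        assert res.counts == {1: 1}
        (pos,) = res.positions[1]
        assert pos == pytest.approx((32.0, 32.0), abs=0.6)

    def test_well_separated_spots_counted_exactly(self, small_scene):
        _, gamma, truth = small_scene
        res = sq.count_foci(gamma, truth.labels, PARAMS)
        for nuc in truth.nuclei:
            assert res.counts[nuc.label] == nuc.foci_count == 9

    def test_matches_bruteforce_oracle(self, small_scene):
        _, gamma, truth = small_scene
        res = sq.count_foci(gamma, truth.labels, PARAMS)
        oracle = enumerate_maxima(
            gamma, truth.labels, PARAMS.blur_sigma, PARAMS.maxima_prominence
        )
        assert res.counts == oracle

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            sq.count_foci(np.zeros((8, 8)), np.zeros((9, 9), dtype=int), PARAMS)

    def test_deterministic(self, small_scene):
        _, gamma, truth = small_scene
        r1 = sq.count_foci(gamma, truth.labels, PARAMS)
        r2 = sq.count_foci(gamma, truth.labels, PARAMS)
        assert r1.counts == r2.counts and r1.positions == r2.positions


class TestCfoci:
    def test_mean_area_nucleus_keeps_count(self):
        records = [
            _rec(1, 100.0, foci_count=10),
            _rec(2, 100.0, foci_count=4),
        ]
        out, summary = sq.compute_cfoci(records)
        assert out[0].cfoci == pytest.approx(10.0)  # area == group mean
        assert summary.mean_area_um2 == pytest.approx(100.0)

    def test_double_area_halves_count(self):
        # areas 40 + 60 + 200 -> group mean 100, so the 200 um^2 nucleus is
        # exactly twice the mean and its count scales by 1/2
        records = [_rec(1, 40.0), _rec(2, 60.0), _rec(3, 200.0, foci_count=10)]
        out, summary = sq.compute_cfoci(records)
        assert summary.mean_area_um2 == pytest.approx(100.0)
        assert out[2].cfoci == pytest.approx(5.0)

    def test_equal_areas_mean_cfoci_equals_mean_foci(self, rng):
        counts = rng.poisson(6, size=20)
        records = [_rec(i + 1, 120.0, foci_count=int(c)) for i, c in enumerate(counts)]
        _, summary = sq.compute_cfoci(records)
        assert summary.mean_cfoci == pytest.approx(summary.mean_foci)

    def test_conservation_identity(self, rng):
        areas = rng.uniform(70, 250, size=40)
        counts = rng.poisson(8, size=40)
        records = [
            _rec(i + 1, float(a), foci_count=int(c))
            for i, (a, c) in enumerate(zip(areas, counts))
        ]
        out, summary = sq.compute_cfoci(records)
        lhs = sum(r.cfoci * r.area_um2 for r in out) / summary.mean_area_um2
        assert lhs == pytest.approx(counts.sum(), abs=1e-9)

    def test_no_included_nuclei_flagged(self):
        records = [_rec(1, 10.0, included=False, exclusion_reason="below_area")]
        with pytest.warns(UserWarning, match="no included"):
            _, summary = sq.compute_cfoci(records)
        assert np.isnan(summary.mean_area_um2) and summary.n_included == 0

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            sq.compute_cfoci([_rec(1, 0.0, foci_count=1)])


class TestBinaryPositivity:
    def test_flat_channel_fraction_zero(self):
        labels = np.zeros((64, 64), dtype=int)
        labels[10:30, 10:30] = 1
        labels[40:60, 40:60] = 2
        _, frac = sq.score_binary_positivity(np.ones((64, 64)), labels)
        assert frac == 0.0

    def test_panbright_scene_fraction_one(self):
        _, gamma, truth = sq.generate_foci_scene(
            8, ("fixed", 0), class_probs=(0.0, 1.0, 0.0), seed=10, shape=(256, 256)
        )
        _, frac = sq.score_binary_positivity(gamma, truth.labels)
        assert frac == 1.0

    def test_mixed_scene_recovers_truth_fraction(self):
        _, gamma, truth = sq.generate_foci_scene(
            50, ("fixed", 0), class_probs=(0.6, 0.4, 0.0), seed=12,
            shape=(1024, 1024), nucleus_area_law=("lognormal", 60.0, 0.2),
        )
        # threshold set between the dim pan-nuclear baseline (~3x slide
        # background) and the pan-bright level (~30x)
        verdicts, frac = sq.score_binary_positivity(
            gamma, truth.labels, positivity_threshold=10.0
        )
        truth_frac = np.mean([n.nucleus_class != "normal" for n in truth.nuclei])
        assert frac == pytest.approx(truth_frac, abs=0.02)

    def test_no_nuclei_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            _, frac = sq.score_binary_positivity(
                np.zeros((16, 16)), np.zeros((16, 16), dtype=int)
            )
        assert np.isnan(frac)


class TestPipeline:
    def test_end_to_end_counts_match_truth(self):
        dapi, gamma, truth = sq.generate_foci_scene(
            10, ("poisson", 7.0), seed=21, shape=(512, 512)
        )
        frame, summary, labels, _ = sq.analyze_scene(dapi, gamma, PARAMS)
        truth_by_seg = {}
        for nuc in truth.nuclei:
            l = labels[int(round(nuc.center[1])), int(round(nuc.center[0]))]
            truth_by_seg[l] = nuc.foci_count
        included = frame[frame.included]
        for _, row in included.iterrows():
            assert row.foci == truth_by_seg[row.label]

    def test_pipeline_bit_stable(self, small_scene):
        dapi, gamma, _ = small_scene
        f1, s1, l1, _ = sq.analyze_scene(dapi, gamma, PARAMS)
        f2, s2, l2, _ = sq.analyze_scene(dapi, gamma, PARAMS)
        assert f1.equals(f2) and np.array_equal(l1, l2)
        assert s1 == s2

    def test_records_frame_columns(self):
        frame = records_to_frame([_rec(1, 80.0)])
        assert list(frame.columns) == [
            "label", "x", "y", "area_um2", "foci", "cfoci", "included", "reason",
        ]
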