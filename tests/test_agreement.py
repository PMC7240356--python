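"""Annotation parsing, rasterization, IoU and overlays against counting
oracles."""

import numpy as np
import pytest

from virtualstain import agreement as agr
from virtualstain.imaging import RGBImage


def _square(x0, y0, side):
    return np.array(
        [[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]],
        dtype=float,
    )


def _ann(regions, image_id="img", rater="r1"):
    a = agr.AnnotationSet(rater_id=rater, image_id=image_id)
    a.regions = [agr.Region(polygon=p, label=lbl) for p, lbl in regions]
    return a


# ---------------------------------------------------------------------------
# XML dialect
# ---------------------------------------------------------------------------


class TestAnnotationXML:
    def test_triangle_round_trip(self, tmp_path):
        tri = np.array([[10, 10], [40, 10], [25, 35]], dtype=float)
        ann = _ann([(tri, "G3")])
        ann.regions[0].comment = "atypical gland"
        path = tmp_path / "a.xml"
        agr.write_annotations(ann, path)
        back = agr.parse_annotations(path)
        assert len(back.regions) == 1
        region = back.regions[0]
        assert region.label == "G3"
        assert region.comment == "atypical gland"
        assert region.polygon.shape == (3, 2)
        np.testing.assert_allclose(region.polygon, tri)

    def test_empty_session_gives_empty_region_list(self, tmp_path):
        path = tmp_path / "empty.xml"
        agr.write_annotations(_ann([]), path)
        assert agr.parse_annotations(path).regions == []

    def test_unknown_pen_colour_names_offender(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text(
            "<session><image identifier='x'><overlays>"
            "<graphic type='polygon'><pen color='#123456'/>"
            "<point-list><point>0,0</point><point>5,0</point>"
            "<point>5,5</point></point-list>"
            "</graphic></overlays></image></session>"
        )
        with pytest.raises(ValueError, match="#123456"):
            agr.parse_annotations(path)

    def test_malformed_xml_raises(self, tmp_path):
        from lxml import etree

        path = tmp_path / "broken.xml"
        path.write_text("<session><image></session>")
        with pytest.raises(etree.XMLSyntaxError):
            agr.parse_annotations(path)

    def test_write_parse_write_is_stable(self, tmp_path):
        ann = _ann([(_square(5, 5, 20), "G4"), (_square(40, 40, 10), "benign")])
        p1, p2 = tmp_path / "1.xml", tmp_path / "2.xml"
        agr.write_annotations(ann, p1)
        agr.write_annotations(agr.parse_annotations(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


class TestRasterize:
    def test_axis_aligned_square_covers_exact_area(self):
        mask = agr.rasterize(_ann([(_square(5, 5, 10), "G3")]), (64, 64))
        assert (mask == agr.MASK_G3).sum() == 100

    def test_disjoint_squares_label_counts_equal_areas(self):
        mask = agr.rasterize(
            _ann([(_square(0, 0, 10), "G3"), (_square(30, 30, 20), "G4")]),
            (64, 64),
        )
        assert (mask == agr.MASK_G3).sum() == 100
        assert (mask == agr.MASK_G4).sum() == 400

    def test_overlap_resolved_by_severity(self):
        mask = agr.rasterize(
            _ann([(_square(0, 0, 20), "G4"), (_square(10, 10, 20), "G3")]),
            (64, 64),
        )
        # the 10x10 overlap belongs to G4 regardless of drawing order
        assert mask[15, 15] == agr.MASK_G4
        assert (mask == agr.MASK_G4).sum() == 400
        assert (mask == agr.MASK_G3).sum() == 300

    def test_degenerate_polygon_skipped_with_warning(self):
        ann = _ann([(np.array([[0.0, 0.0], [5.0, 5.0]]), "G3")])
        with pytest.warns(UserWarning, match="degenerate"):
            mask = agr.rasterize(ann, (16, 16))
        assert mask.sum() == 0

    def test_even_odd_fill_leaves_hole(self):
        # self-overlapping star-of-david style: outer square + inner square
        # listed as one even-odd polygon -> inner square is a hole
        outer = _square(0, 0, 20)
        inner = _square(5, 5, 10)
        poly = np.vstack([outer, outer[:1], inner[::-1], inner[-1:]])
        mask = agr.rasterize(_ann([(poly, "G3")]), (32, 32))
        assert mask[10, 10] == agr.MASK_NONE
        assert mask[2, 2] == agr.MASK_G3


# ---------------------------------------------------------------------------
# IoU
# ---------------------------------------------------------------------------


class TestIoU:
    def test_identical_masks_give_one(self):
        m = agr.rasterize(_ann([(_square(4, 4, 12), "G3")]), (32, 32))
        assert agr.iou(m, m, "G3") == 1.0
        assert agr.iou(m, m, "any_tumor") == 1.0

    def test_disjoint_equal_areas_give_zero(self):
        a = agr.rasterize(_ann([(_square(0, 0, 10), "G3")]), (64, 64))
        b = agr.rasterize(_ann([(_square(40, 40, 10), "G3")]), (64, 64))
        assert agr.iou(a, b, "G3") == 0.0

    def test_shifted_square_exact_third(self):
        a = agr.rasterize(_ann([(_square(10, 10, 10), "G3")]), (64, 64))
        b = agr.rasterize(_ann([(_square(15, 10, 10), "G3")]), (64, 64))
        assert agr.iou(a, b, "G3") == pytest.approx(50 / 150)

    def test_na_when_class_absent_from_both(self):
        a = agr.rasterize(_ann([(_square(0, 0, 10), "G3")]), (32, 32))
        assert agr.iou(a, a, "G5") is None

    def test_healthy_modes(self):
        a = agr.rasterize(
            _ann([(_square(0, 0, 10), "G3"), (_square(20, 20, 8), "benign")]),
            (32, 32),
        )
        assert agr.iou(a, a, "healthy") == 1.0  # annotated benign outlines
        comp = agr.iou(a, a, "healthy", healthy_mode="complement")
        assert comp == 1.0

    def test_matches_exhaustive_pixel_counting(self, rng):
        for _ in range(5):
            a = (rng.random((40, 40)) < 0.3).astype(np.uint8) * agr.MASK_G4
            b = (rng.random((40, 40)) < 0.3).astype(np.uint8) * agr.MASK_G4
            expected_union = np.sum((a > 0) | (b > 0))
            expected_inter = np.sum((a > 0) & (b > 0))
            got = agr.iou(a, b, "G4")
            if expected_union == 0:
                assert got is None
            else:
                assert got == pytest.approx(expected_inter / expected_union)

    def test_monotone_in_intersection(self):
        # growing the intersection while holding the union fixed never
        # decreases IoU
        base = np.zeros((20, 20), dtype=np.uint8)
        base[:10, :] = agr.MASK_G3  # A = top half
        prev = -1.0
        for k in (0, 4, 8, 10):
            b = np.zeros_like(base)
            b[:k, :] = agr.MASK_G3  # B grows inside A
            b[10:, :] = agr.MASK_G3  # keeps union = everything
            val = agr.iou(base, b, "G3")
            assert val >= prev
            prev = val

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            agr.iou(np.zeros((4, 4), np.uint8), np.zeros((5, 5), np.uint8))


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


class TestAggregate:
    def test_published_inter_rater_table(self):
        table = agr.aggregate(agr.INTER_RATER_IOU)
        assert table.loc["healthy", "mean"] == 0.90
        assert table.loc["G3", "mean"] == 0.70
        assert table.loc["G4", "mean"] == 0.73
        assert table.loc["G5", "mean"] == 0.64
        assert table.loc["G5", "sd"] == 0.0
        assert table.loc["G5", "n"] == 1
        # the any-tumor column averages to 0.798; the reported overall score
        # of 0.79 agrees to within one unit in its last printed digit
        raw = agr.aggregate(agr.INTER_RATER_IOU, decimals=None)
        assert raw.loc["any_tumor", "mean"] == pytest.approx(0.79, abs=0.01)
        assert table.loc["any_tumor", "n"] == 11

    def test_published_table_sds(self):
        table = agr.aggregate(agr.INTER_RATER_IOU)
        assert table.loc["any_tumor", "sd"] == 0.14
        assert table.loc["healthy", "sd"] == 0.12
        assert table.loc["G3", "sd"] == 0.17
        assert table.loc["G4", "sd"] == 0.15

    def test_records_interface_matches_frame_interface(self):
        records = [
            agr.AgreementRecord("i1", "inter", "G3", 0.5),
            agr.AgreementRecord("i2", "inter", "G3", 0.7),
            agr.AgreementRecord("i1", "inter", "G4", None),
            agr.AgreementRecord("i2", "inter", "G4", None),
        ]
        table = agr.aggregate(records)
        assert table.loc["G3", "mean"] == pytest.approx(0.6)
        assert np.isnan(table.loc["G4", "mean"])
        assert table.loc["G4", "n"] == 0


# ---------------------------------------------------------------------------
# error overlays
# ---------------------------------------------------------------------------


class TestErrorOverlay:
    def _base(self, shape=(32, 32)):
        return RGBImage(np.full((*shape, 3), 128, dtype=np.uint8))

    def test_perfect_prediction_only_green(self):
        m = agr.rasterize(_ann([(_square(4, 4, 10), "G3")]), (32, 32))
        out = agr.error_overlay(m, m, self._base(), opacity=1.0)
        green = (out.pixels == [0, 255, 0]).all(axis=2)
        assert green.sum() == 100
        assert (out.pixels[~green] == 128).all()

    def test_empty_prediction_only_blue(self):
        truth = agr.rasterize(_ann([(_square(4, 4, 10), "G3")]), (32, 32))
        pred = np.zeros_like(truth)
        out = agr.error_overlay(pred, truth, self._base(), opacity=1.0)
        blue = (out.pixels == [0, 0, 255]).all(axis=2)
        assert blue.sum() == 100
        assert not (out.pixels == [0, 255, 0]).all(axis=2).any()

    def test_colour_counts_equal_confusion_matrix(self):
        truth = agr.rasterize(_ann([(_square(0, 0, 10), "G3")]), (32, 32))
        pred = agr.rasterize(_ann([(_square(5, 0, 10), "G3")]), (32, 32))
        out = agr.error_overlay(pred, truth, self._base(), opacity=1.0)
        tp = ((truth > 0) & (pred > 0)).sum()
        fn = ((truth > 0) & (pred == 0)).sum()
        fp = ((truth == 0) & (pred > 0)).sum()
        assert (out.pixels == [0, 255, 0]).all(axis=2).sum() == tp
        assert (out.pixels == [0, 0, 255]).all(axis=2).sum() == fn
        assert (out.pixels == [255, 0, 0]).all(axis=2).sum() == fp
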