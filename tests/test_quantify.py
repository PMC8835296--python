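"""Thresholding, calcification split, per-exam volumes, longitudinal stats."""

import numpy as np
import pytest

from pleuravol import (
    BinaryMask,
    PhantomSpec,
    PlaqueParams,
    binarize,
    generate_exam,
    longitudinal_compare,
    quantify_exam,
    split_calcified,
)
from pleuravol.ct_io import GeometryError
from pleuravol.quantify import PlaqueQuant


class TestBinarize:
    def test_threshold_is_inclusive(self):
        mask = binarize(np.array([[0.49, 0.5, 0.51]]))
        assert mask.pixels.tolist() == [[0, 1, 1]]

    def test_all_zero_map_empty(self):
        assert binarize(np.zeros((4, 4))).count() == 0

    def test_idempotent(self):
        prob = np.random.default_rng(0).random((6, 6))
        once = binarize(prob)
        twice = binarize(once.pixels.astype(float))
        assert np.array_equal(once.pixels, twice.pixels)


class TestSplitCalcified:
    def test_hu_rule_with_inclusive_boundary(self):
        mask = BinaryMask(np.ones((1, 3), dtype=int))
        hu = np.array([[400.0, 50.0, 100.0]])
        calc = split_calcified(mask, hu)
        assert calc.pixels.tolist() == [[1, 0, 1]]

    def test_subset_of_input_mask(self):
        rng = np.random.default_rng(1)
        mask = BinaryMask((rng.random((8, 8)) < 0.5).astype(int))
        hu = rng.uniform(-1000, 1000, (8, 8))
        calc = split_calcified(mask, hu)
        assert np.all(mask.pixels[calc.pixels.astype(bool)] == 1)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(GeometryError):
            split_calcified(BinaryMask(np.zeros((2, 2), dtype=int)), np.zeros((3, 3)))


def test_plaque_quant_conservation_enforced():
    with pytest.raises(ValueError, match="calcified"):
        PlaqueQuant("e", "p", 2, pp_volume_ml=1.0, calc_volume_ml=2.0, source="mip")


class TestQuantifyExam:
    def test_plaque_free_phantom_is_a_negative_control(self, desk_weights):
        vol, _, _ = generate_exam(PhantomSpec.desk(seed=91))
        q = quantify_exam(vol, desk_weights, source="mip")
        assert q.pp_volume_ml < 0.15
        assert q.calc_volume_ml <= q.pp_volume_ml

    def test_calcified_only_phantom(self, desk_weights):
        spec = PhantomSpec.desk(
            seed=92,
            plaque_params=(PlaqueParams(60.0, 120.0, 5.0, 2, 16, calcified=True, side="right"),),
        )
        vol, _, _ = generate_exam(spec)
        q = quantify_exam(vol, desk_weights, source="mip")
        assert q.pp_volume_ml > 0.5
        assert q.calc_volume_ml == pytest.approx(q.pp_volume_ml, rel=0.05)

    def test_native_and_mip_paths_agree_on_boundary_aligned_plaque(self, desk_weights):
        spec = PhantomSpec.desk(
            seed=93,
            plaque_params=(PlaqueParams(30.0, 100.0, 5.0, 5, 10, side="left"),),
        )
        vol, pp, _ = generate_exam(spec)
        q_mip = quantify_exam(vol, desk_weights, source="mip")
        q_nat = quantify_exam(vol, desk_weights, source="native")
        area_ml = pp.pixels.max(axis=0).sum() / 1000.0
        assert abs(q_mip.pp_volume_ml - q_nat.pp_volume_ml) <= 10 * area_ml

    def test_unknown_source_rejected(self, desk_weights):
        vol, _, _ = generate_exam(PhantomSpec.desk(seed=94))
        with pytest.raises(ValueError, match="source"):
            quantify_exam(vol, desk_weights, source="coronal")


def _quant(pid, rnd, v):
    return PlaqueQuant(f"{pid}_r{rnd}", pid, rnd, pp_volume_ml=v, calc_volume_ml=0.0, source="mip")


class TestLongitudinalCompare:
    def test_uniform_seventy_percent_growth(self):
        quants = [
            _quant("a", 2, 10.0), _quant("a", 3, 17.0),
            _quant("b", 2, 4.0), _quant("b", 3, 6.8),
            _quant("c", 2, 2.0), _quant("c", 3, 3.4),
        ]
        res = longitudinal_compare(quants, seed=0)
        assert res.median_percent_increase == pytest.approx(70.0)
        assert res.median_difference_ml == pytest.approx(2.8)

    def test_identical_rounds_are_null(self):
        quants = [_quant("a", 2, 5.0), _quant("a", 3, 5.0),
                  _quant("b", 2, 1.0), _quant("b", 3, 1.0)]
        with pytest.warns(UserWarning):
            res = longitudinal_compare(quants, seed=0)
        assert res.median_difference_ml == 0.0
        assert res.median_percent_increase == 0.0
        assert res.p_value == 1.0

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        quants = []
        for i in range(8):
            v2 = float(rng.uniform(1, 10))
            quants += [_quant(f"p{i}", 2, v2), _quant(f"p{i}", 3, v2 * rng.uniform(1.2, 2.0))]
        a = longitudinal_compare(quants, seed=3)
        rng.shuffle(quants)
        b = longitudinal_compare(quants, seed=3)
        assert a == b

    def test_unpaired_participant_rejected_by_name(self):
        quants = [_quant("a", 2, 1.0), _quant("a", 3, 2.0), _quant("ghost", 2, 1.0)]
        with pytest.raises(ValueError, match="ghost"):
            longitudinal_compare(quants, seed=0)

    def test_zero_baseline_excluded_from_percent_increase(self):
        quants = [
            _quant("a", 2, 0.0), _quant("a", 3, 1.0),
            _quant("b", 2, 2.0), _quant("b", 3, 3.0),
            _quant("c", 2, 4.0), _quant("c", 3, 6.0),
        ]
        res = longitudinal_compare(quants, seed=0)
        assert res.n_excluded_zero_baseline == 1
        assert res.median_percent_increase == pytest.approx(50.0)

    def test_ci_definition_brackets_median(self):
        rng = np.random.default_rng(5)
        quants = []
        for i in range(12):
            v2 = float(rng.uniform(1, 10))
            quants += [_quant(f"p{i}", 2, v2), _quant(f"p{i}", 3, v2 * 1.7 * rng.uniform(0.9, 1.1))]
        res = longitudinal_compare(quants, seed=1)
        lo, hi = res.percent_ci
        assert lo <= res.median_percent_increase <= hi
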