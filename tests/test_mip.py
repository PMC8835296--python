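"""Thin-MIP slabs: counts, max-projection, partial slabs, mL volumetrics."""

import numpy as np
import pytest

from pleuravol import (
    BinaryMask,
    CTVolume,
    PhantomSpec,
    PlaqueParams,
    compute_mip,
    generate_exam,
    native_mask_volume_ml,
    project_mask,
    slab_mask_volume_ml,
)
from pleuravol.ct_io import GeometryError
from pleuravol.mip import read_stack, write_stack


def _vol(voxels, spacing=(1.0, 1.0, 1.0)):
    return CTVolume(np.asarray(voxels, dtype=np.float32), spacing)


def test_300_one_mm_slices_give_60_slabs():
    vol = _vol(np.zeros((300, 8, 8)))
    stack = compute_mip(vol, 5.0)
    assert stack.n_slabs == 60
    assert all(len(g) == 5 for g in stack.slab_to_slices)


def test_every_slice_in_exactly_one_slab():
    vol = _vol(np.zeros((23, 4, 4)))
    stack = compute_mip(vol, 5.0)
    seen = [i for g in stack.slab_to_slices for i in g]
    assert sorted(seen) == list(range(23))
    assert len(stack.slab_to_slices[-1]) == 3  # trailing partial slab kept


def test_identical_slices_project_to_themselves():
    sl = np.random.default_rng(0).normal(size=(6, 6)).astype(np.float32)
    stack = compute_mip(_vol(np.repeat(sl[None], 5, axis=0)), 5.0)
    assert stack.n_slabs == 1
    assert np.array_equal(stack.slabs[0], sl)


def test_pixelwise_maximum():
    col = np.array([-800.0, 50.0, 400.0, -800.0, -800.0])
    vox = np.full((5, 2, 2), -1000.0);  vox[:, 0, 0] = col
    stack = compute_mip(_vol(vox), 5.0)
    assert stack.slabs[0, 0, 0] == 400.0
    # slab pixel equals max over constituents everywhere (invariant)
    assert np.array_equal(stack.slabs[0], vox.max(axis=0))


def test_mip_is_idempotent_in_intensity():
    vol, _, _ = generate_exam(PhantomSpec.desk(seed=2))
    stack = compute_mip(vol, 5.0)
    again = compute_mip(CTVolume(stack.slabs, (stack.slab_thickness, 1.0, 1.0)), stack.slab_thickness)
    assert np.array_equal(again.slabs, stack.slabs)


def test_slab_thinner_than_slice_rejected():
    with pytest.raises(ValueError, match="thinner"):
        compute_mip(_vol(np.zeros((10, 4, 4))), 0.4)


class TestVolumes:
    def test_full_slab_arithmetic(self):
        vol = _vol(np.zeros((5, 40, 25)))
        stack = compute_mip(vol, 5.0)
        mask = BinaryMask(np.ones((1, 40, 25), dtype=int))
        assert slab_mask_volume_ml(mask, stack) == pytest.approx(1000 * 1.0 * 5.0 / 1000.0)

    def test_empty_mask_zero_volume(self):
        stack = compute_mip(_vol(np.zeros((5, 4, 4))), 5.0)
        assert slab_mask_volume_ml(BinaryMask(np.zeros((1, 4, 4), dtype=int)), stack) == 0.0

    def test_partial_trailing_slab_uses_true_thickness(self):
        vol = _vol(np.zeros((7, 4, 4)))
        stack = compute_mip(vol, 5.0)
        mask = BinaryMask(np.ones((2, 4, 4), dtype=int))
        # 16 px * (5 mm + 2 mm) * 1 mm^2
        assert slab_mask_volume_ml(mask, stack) == pytest.approx(16 * 7 / 1000.0)

    def test_native_volume_examples(self):
        vol = _vol(np.zeros((10, 10, 10)))
        m = np.zeros((10, 10, 10), dtype=int);  m.ravel()[:200] = 1
        assert native_mask_volume_ml(BinaryMask(m), vol) == pytest.approx(0.2)
        assert native_mask_volume_ml(BinaryMask(np.ones_like(m)), vol) == pytest.approx(1.0)
        one = np.zeros_like(m);  one[3, 4, 5] = 1
        assert native_mask_volume_ml(BinaryMask(one), vol) == pytest.approx(1e-3)

    def test_volume_monotone_in_positive_pixels(self):
        stack = compute_mip(_vol(np.zeros((5, 6, 6))), 5.0)
        base = np.zeros((1, 6, 6), dtype=int);  base[0, 1, 1] = 1
        more = base.copy();  more[0, 2, 2] = 1
        assert slab_mask_volume_ml(BinaryMask(more), stack) > slab_mask_volume_ml(BinaryMask(base), stack)

    def test_geometry_mismatch_rejected(self):
        stack = compute_mip(_vol(np.zeros((5, 4, 4))), 5.0)
        with pytest.raises(GeometryError):
            slab_mask_volume_ml(BinaryMask(np.zeros((2, 4, 4), dtype=int)), stack)


def test_boundary_aligned_plaque_native_equals_slab_volume():
    """A plaque spanning whole slabs has identical native and slab volumes."""
    spec = PhantomSpec.desk(
        seed=6, plaque_params=(PlaqueParams(30.0, 80.0, 4.0, 5, 10, side="left"),)
    )  # slices 5..14 = slabs 1 and 2 exactly
    vol, pp, _ = generate_exam(spec)
    stack = compute_mip(vol, 5.0)
    slab_gt = project_mask(pp, stack)
    assert slab_mask_volume_ml(slab_gt, stack) == pytest.approx(native_mask_volume_ml(pp, vol))


def test_unaligned_plaque_within_one_boundary_layer():
    spec = PhantomSpec.desk(
        seed=6, plaque_params=(PlaqueParams(30.0, 80.0, 4.0, 3, 9, side="left"),)
    )  # slices 3..11 straddle slab boundaries
    vol, pp, _ = generate_exam(spec)
    stack = compute_mip(vol, 5.0)
    slab_v = slab_mask_volume_ml(project_mask(pp, stack), stack)
    native_v = native_mask_volume_ml(pp, vol)
    per_slice_area_ml = pp.pixels.max(axis=0).sum() * 1.0 * 1.0 / 1000.0
    # discrepancy bounded by one slab's worth of boundary layers (2 cut planes x 4 extra slices)
    assert abs(slab_v - native_v) <= 8 * per_slice_area_ml + 1e-9
    assert slab_v >= native_v  # projection only ever adds partial-slab padding


def test_stack_roundtrip(tmp_path):
    vol, _, _ = generate_exam(PhantomSpec.desk(seed=4))
    stack = compute_mip(vol, 5.0)
    write_stack(stack, tmp_path / "stack.nii.gz")
    back = read_stack(tmp_path / "stack.nii.gz")
    assert np.allclose(back.slabs, stack.slabs)
    assert back.slab_to_slices == stack.slab_to_slices
    assert back.pixel_area == pytest.approx(stack.pixel_area)
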