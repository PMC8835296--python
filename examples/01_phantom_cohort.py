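"""Generate a synthetic thorax exam and inspect its exact ground truth.

The phantom builds an axial chest section from nested ellipses (body, two
lungs, an extrapleural fat lining, rib arcs) and rasterizes crescent-shaped
pleural plaques on the inner chest wall, so the plaque and calcified-plaque
masks are exact by construction.
"""

import numpy as np

from pleuravol import PhantomSpec, PlaqueParams, generate_exam, native_mask_volume_ml

spec = PhantomSpec.desk(
    seed=42,
    plaque_params=(
        PlaqueParams(center_angle_deg=40, arc_extent_deg=100, thickness_mm=4.0,
                     slice_start=2, n_slices=14, calcified=False, side="left"),
        PlaqueParams(center_angle_deg=210, arc_extent_deg=70, thickness_mm=5.0,
                     slice_start=5, n_slices=10, calcified=True, side="right"),
    ),
)
vol, pp, calc = generate_exam(spec)

print(f"volume shape (z, y, x): {vol.voxels.shape}, spacing {vol.spacing} mm")
print(f"plaque voxels:          {pp.count()}  -> {native_mask_volume_ml(pp, vol):.3f} mL")
print(f"calcified voxels:       {calc.count()}  -> {native_mask_volume_ml(calc, vol):.3f} mL")
print(f"plaque HU range:        {vol.voxels[pp.pixels.astype(bool)].min():.0f}"
      f" .. {vol.voxels[pp.pixels.astype(bool)].max():.0f}")
# The calcified mask is a subset of the plaque mask, and its voxels sit at
# or above the 100 HU calcification threshold; soft plaque sits below it.
assert np.all(pp.pixels[calc.pixels.astype(bool)] == 1)
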