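"""Fully automated per-exam quantification: predict -> binarize at 0.5 ->
split calcified at 100 HU -> volumes in mL, on both the MIP and native paths.
"""

import numpy as np

from pleuravol import generate_exam, quantify_exam, sample_spec
from pleuravol.experiments import train_desk_model
from pleuravol.mip import native_mask_volume_ml

weights = train_desk_model(seed=1)
rng = np.random.default_rng(99)
spec = sample_spec(rng, participant_id="demo")
vol, pp, calc = generate_exam(spec)

q_mip = quantify_exam(vol, weights, source="mip")
q_nat = quantify_exam(vol, weights, source="native")
print(f"ground truth:  PP {native_mask_volume_ml(pp, vol):.2f} mL, "
      f"calcified {native_mask_volume_ml(calc, vol):.2f} mL")
print(f"AI (MIP path):    PP {q_mip.pp_volume_ml:.2f} mL, calcified {q_mip.calc_volume_ml:.2f} mL")
print(f"AI (native path): PP {q_nat.pp_volume_ml:.2f} mL, calcified {q_nat.calc_volume_ml:.2f} mL")
# The two paths agree up to partial-slab padding; the calcified volume is
# always a subset of (hence no larger than) the total plaque volume.
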