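"""Construct the three prior-guided views of one synthetic scene.

Shows the prior crop geometry, which jigsaw tiles count as shared with
the prior view (and therefore keep mild transforms), and how much of the
within-instance-negative view is blanked out.
"""

import numpy as np

from priorcon import SceneSpec, build_view_bundle, generate_scene

rec = generate_scene(SceneSpec(seed=7, lesion_class="red_lesion"))
bundle = build_view_bundle(rec.image, crop_side=48, seed=0)

print(f"lesion center (ground truth): {rec.lesion_center}")
print(f"prior box (top,left,bottom,right): {bundle.prior_box.box}")
print(f"prior view shape: {bundle.prior_view.shape}")
print(f"shared tile mask (3x3 grid): {bundle.shared_tile_mask.astype(int).reshape(3, 3)}")
print(f"tile permutation: {bundle.tile_permutation}")
zero_frac = float((bundle.win_view.sum(axis=2) == 0).mean())
print(f"WIN view blanked fraction: {zero_frac:.3f}")
# the prior box is centred on the reddest pixel, so it sits on the lesion;
# tiles it touches stay recognisable while the rest are distorted, and the
# WIN view removes exactly the suspected-pathology region
in_box = (
    bundle.prior_box.box[0] <= rec.lesion_center[0] < bundle.prior_box.box[2]
    and bundle.prior_box.box[1] <= rec.lesion_center[1] < bundle.prior_box.box[3]
)
print(f"lesion center inside prior box: {in_box}")
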