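"""Convert weak box annotations to pixel masks with the fallback segmenter.

Shows the conversion quality (per-instance IoU against ground truth) for
tight boxes and for sloppy random boxes, mirroring a careful vs a hurried
annotator.
"""

import numpy as np

from allinsam.annotate import conversion_instance_iou, convert_boxes
from allinsam.synthdata import derive_boxes, render_patch

img, inst = render_patch(128, 128, n_per_class=[5, 5], noise_sd=0.05, seed=7)

tight = derive_boxes(inst, "tight")
sloppy = derive_boxes(inst, "random", jitter_px=5, seed=1)

ann = convert_boxes(img, tight)
print(f"converted masks: class 1 {ann.masks[1].sum()} px, class 2 {ann.masks[2].sum()} px "
      f"(provenance: {ann.provenance})")

iou_tight = np.mean(conversion_instance_iou(img, inst, tight))
iou_sloppy = np.mean(conversion_instance_iou(img, inst, sloppy))
print(f"mean per-instance IoU, tight boxes:  {iou_tight:.3f}")
print(f"mean per-instance IoU, jittered 5px: {iou_sloppy:.3f}")
# Tight prompts recover nuclei almost exactly; jittered prompts degrade
# gracefully - the converted masks are what the network trains on.
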