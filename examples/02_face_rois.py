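"""Facial regions of interest from 79 fiducial points.

Renders the schematic face (landmarks are exact by construction),
builds the seven circular regions plus the lip and whole-face
polygons, and reports their pixel footprints and the structural
radius/distance ratios.
"""

import numpy as np

import facecolor as fc

image, landmarks, _, _ = fc.render_synthetic_face()
masks = fc.build_masks(landmarks)

print("region pixel counts (256 x 256 render):")
for name, mask in masks.masks.items():
    print(f"  {name:18s} {int(mask.sum()):6d} px")

rois = {r.name: r for r in fc.circle_rois(landmarks)}
for name, anchor, ratio in [("nose", 31, 1.4), ("forehead", 22, 0.7),
                            ("chin", 58, 0.8)]:
    d = np.hypot(*(rois[name].center - landmarks.pt(anchor)))
    print(f"{name}: radius / distance-to-pt{anchor} = {rois[name].radius / d:.3f}"
          f"  (structural constant {ratio})")

overlap = masks.masks["whole_face"] & masks.masks["lip"]
print("whole-face mask excludes the lip:", not overlap.any())
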