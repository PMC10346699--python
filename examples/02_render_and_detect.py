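"""Render a probe image with ground truth and run the rule-based detector.

A detected section is "thick" when it is wider than 60 px on the image and
its mean color sits in the yellow/brown hue band; otherwise "thin".
"""

import numpy as np
from PIL import Image

from rhizoprobe import (SceneConfig, generate_root_system,
                        generate_sampling_plan, render_root_image, sense_roots)
from rhizoprobe.root_detection import analyze_root_image

scene = SceneConfig(n_tunnels=20, viewpoints_per_tunnel=10)
system = generate_root_system(scene, "control", plant_seed=42)
plan = generate_sampling_plan(scene, seed=1)
visible = sense_roots(plan, system, scene.sense_radius)

i = next(k for k in range(plan.n_viewpoints) if len(visible[k]) >= 1)
segments = [system.segments[int(j)] for j in visible[i]]
img = render_root_image(plan.coords[i], segments, seed=7, viewpoint_id=i)
Image.fromarray(img.pixels).save("example_probe_image.png")

print(f"viewpoint {i} at {np.round(plan.coords[i], 1)} mm sees "
      f"{len(segments)} segment(s); image saved to example_probe_image.png")
print("ground truth:", img.ground_truth)
for det, color in analyze_root_image(img.pixels, image_id=i):
    print(f"detected {det.klass:5s} box={det.box} width={det.thickness_px:.0f}px "
          f"hue={color.H:.0f} deg V={color.V:.2f} score={det.score:.2f}")
# The detection box should match the ground-truth box, and the class should
# agree with the generated segment's true class.
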