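"""Generate deterministic labeled scenes and inspect their annotations.

Renders a single-animal and a two-animal toy scene, prints the exact
ground-truth keypoints, and writes a small dataset in the native layout.
"""

import numpy as np

import adpt

# one 64x64 scene with the default 5-keypoint rodent skeleton
frame = adpt.generate_scene(adpt.SceneSpec(seed=1))
print(f"scene: {frame.width}x{frame.height}, {len(frame.instances)} animal(s)")
for inst in frame.instances:
    print(f"  identity {inst.identity}:")
    for name, (x, y) in zip(adpt.MOUSE5.names, inst.keypoints):
        print(f"    {name:10s} at ({x:6.2f}, {y:6.2f})")

# a two-animal scene uses a larger arena so the bodies stay separable
pair = adpt.generate_scene(adpt.SceneSpec(image_size=(96, 96), n_animals=2, seed=2))
centers = [i.keypoints[adpt.MOUSE5.center_index] for i in pair.instances]
sep = np.linalg.norm(centers[0] - centers[1])
print(f"\npair scene: identities {[i.identity for i in pair.instances]}, "
      f"center separation {sep:.1f} px")

# persist a tiny dataset in the native layout (images/ + annotations.csv)
frames = [adpt.generate_scene(adpt.SceneSpec(seed=s)) for s in range(4)]
adpt.write_labeled_dataset("scratch/example_dataset", frames, adpt.MOUSE5)
back = adpt.read_labeled_dataset("scratch/example_dataset", adpt.Config())
print(f"\nwrote and re-read {len(back)} frames; coordinates survive the "
      f"round trip exactly.")
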