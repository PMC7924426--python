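"""Extract the representative 2D slice of a single synthetic organ volume.

Builds one thorax phantom on an anisotropic grid, reconstructs the
isotropic volume, finds its plane of best bilateral symmetry, and samples
the 224x224 representative image lying on that plane.
"""

import numpy as np

from symslice import (
    PhantomSpec,
    PipelineConfig,
    extract_representative,
    generate_phantom,
)

vol, true_plane = generate_phantom(PhantomSpec(class_id="thorax", seed=42))
print(f"phantom grid {vol.shape} at spacing {vol.spacing} mm/voxel")

result = extract_representative(vol, PipelineConfig())

n = result.plane.plane.n
angle = np.degrees(np.arccos(min(1.0, abs(float(n @ np.asarray(true_plane.n))))))
print(f"Otsu band: [{result.thresholds.t_low:.1f}, {result.thresholds.t_high:.1f}]")
print(f"estimated normal {np.round(n, 3)}, offset {result.plane.plane.offset:.2f} voxels")
print(f"angle to the built-in mirror plane: {angle:.2f} degrees")
print(f"registration residual: {result.plane.residual_rms:.2f} voxels")
print(f"representative image: {result.image.pixels.shape}, "
      f"intensity range [{result.image.pixels.min()}, {result.image.pixels.max()}]")

result.image.to_png("thorax_representative.png")
print("wrote thorax_representative.png")
# The angle should be well under a degree or two: the estimator recovered
# the anatomical mirror plane, and the PNG shows the cross-section lying
# on it -- the orientation-stable stand-in for the whole 3D volume.
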