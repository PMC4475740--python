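"""Round-trip regional extraction through a toy labeled 4D image.

Paints known regional series into a voxel grid (each region = a block of
voxels carrying its series plus independent noise), then recovers the
regional means by label-wise averaging — the extraction stage used when
inputs arrive as a 4D image + integer label image instead of tables.
Run:  python examples/04_image_extraction.py
"""

import numpy as np

from connectograph import (
    CohortConfig,
    default_atlas,
    extract_regional_series,
    render_toy_image,
    simulate_subject,
)

atlas = default_atlas()
cfg = CohortConfig(group_sizes={"NC": 1}, n_timepoints=100)
ts = simulate_subject(np.eye(atlas.n_regions), cfg, np.random.default_rng(0))

for noise_sd, voxels in [(0.0, 3), (0.5, 3), (0.5, 25)]:
    image, labels = render_toy_image(
        ts, atlas, voxels_per_region=voxels, noise_sd=noise_sd,
        rng=np.random.default_rng(1),
    )
    out = extract_regional_series(image, labels, atlas)
    err = np.sqrt(np.mean((out.values - ts.values) ** 2))
    print(f"noise sd={noise_sd:.1f}, voxels/region={voxels:>2}: "
          f"extraction RMS error = {err:.4f}")
# With no noise the planted series come back exactly; with noise the error
# shrinks as 1/sqrt(voxels), the variance reduction of voxel averaging.
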