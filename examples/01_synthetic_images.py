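"""Generate a seeded two-class texture image set and inspect its contrast.

The generator scatters dark elliptical blobs (nuclei proxies) on a noisy
pink background; the OSCC class has ~4x the blob density and larger blobs,
so texture descriptors have a real signal to pick up.
"""

import numpy as np
from skimage.measure import label

from oralfuse import SyntheticImageConfig, generate_image_dataset
from oralfuse.texture import to_grayscale

cfg = SyntheticImageConfig(seed=42)
ds = generate_image_dataset(n_per_class=25, cfg=cfg)
print(f"{len(ds)} images of shape {ds.images.shape[1:]}, labels: "
      f"{dict(zip(*np.unique(ds.labels, return_counts=True)))}")

for cls in ("healthy", "OSCC"):
    imgs = ds.images[ds.labels == cls]
    comps = [label(to_grayscale(im) < 150).max() for im in imgs]
    print(f"{cls:8s}: mean dark-component count {np.mean(comps):5.1f}")
# The component counts differ by roughly the configured density ratio —
# that contrast is what every downstream feature extractor must detect.
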