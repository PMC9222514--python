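"""Frozen SqueezeNet-style features from synthetic patches.

Generates a few patches per class, runs them through the randomly
initialised (seeded, frozen) convolutional trunk, and shows that the
global-average-pool feature rows already separate the three texture classes.
"""

import numpy as np

from osteosae import build_network, default_spec, extract_features
from osteosae.synthetic import ImageGenSpec, generate_images

patches = generate_images(ImageGenSpec(n_per_class=(5, 5, 5), patch_size=64, seed=1))
net = build_network(default_spec(input_size=64), seed=0)
print(f"network parameters: {net.parameter_count():,} "
      f"(vs ~60,000,000 for an AlexNet-scale model)")

fm = extract_features(patches, net)
print(f"feature matrix: {fm.values.shape[0]} samples x {fm.feature_dim} features")

labels = np.array([p.label for p in patches])
for cls in ("VT", "NVT", "NT"):
    mu = fm.values[labels == cls].mean()
    print(f"  mean activation {cls}: {mu:.4f}")
print()
print("Per-class mean activations differ because the three texture regimes")
print("(dense nuclei, sparse necrotic blobs, smooth background) excite the")
print("random convolutional filters differently — enough signal for the")
print("downstream classifier even without pretrained weights.")
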