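"""Edge-preserving pre-filtering of a histology-like patch.

Builds one synthetic textured patch, smooths it with the pure Gaussian and
the self-guided bilateral filter, and compares how much each blurs the
patch's edges.  The bilateral filter should reduce noise while keeping the
gradient energy (edge content) much closer to the original.
"""

import numpy as np

from osteosae import BilateralParams, bilateral_filter, enhance_contrast, gaussian_filter
from osteosae.synthetic import ImageGenSpec, generate_images

patch = generate_images(ImageGenSpec(n_per_class=(1, 0, 0), patch_size=64, seed=0))[0]

gauss = gaussian_filter(patch, sigma_s=2.0)
bilat = bilateral_filter(patch, params=BilateralParams(sigma_s=2.0, sigma_r=0.1))
enhanced = enhance_contrast(bilat, "clahe")


def grad_energy(px):
    gy, gx = np.gradient(px)
    return float(np.mean(gy**2 + gx**2))


print(f"original  gradient energy: {grad_energy(patch.pixels):.6f}")
print(f"gaussian  gradient energy: {grad_energy(gauss.pixels):.6f}")
print(f"bilateral gradient energy: {grad_energy(bilat.pixels):.6f}")
print(f"CLAHE output range: [{enhanced.pixels.min():.3f}, {enhanced.pixels.max():.3f}]")
print()
print("The bilateral filter keeps more gradient energy than the Gaussian at")
print("the same spatial scale: it smooths within regions but not across edges.")
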