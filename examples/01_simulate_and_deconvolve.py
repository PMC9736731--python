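"""Render a synthetic trichrome tile and recover its stain densities.

Generates one thin-linear-fiber tile (the COL11A1+-like ECM phenotype),
separates the RGB image into aniline-blue and Biebrich-scarlet density
channels by color deconvolution, and compares against the generator's
exact ground truth.
"""

import numpy as np

from stromatex import FiberTileSpec, generate_fiber_tile, od_to_density, rgb_to_od

tile = generate_fiber_tile(FiberTileSpec.thin_linear(seed=0, noise_sd=0.0))
recovered = od_to_density(rgb_to_od(tile.rgb))

rmse_blue = np.sqrt(np.mean((recovered.blue - tile.truth.blue) ** 2))
rmse_red = np.sqrt(np.mean((recovered.red - tile.truth.red) ** 2))

print(f"tile: {tile.rgb.shape[0]}x{tile.rgb.shape[1]} px, "
      f"{tile.spec.n_fibers} fibers, {100 * tile.fiber_mask.mean():.1f}% fiber cover")
print(f"blue-density recovery RMSE: {rmse_blue:.4f} OD")
print(f"red-density recovery RMSE:  {rmse_red:.4f} OD")
print("RMSE is the per-pixel error between deconvolved and true stain density;")
print("values well below 0.02 OD mean the Beer-Lambert inversion is faithful.")
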