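"""Generate a synthetic temporal-bone volume and classify its materials.

Builds the default two-macula phantom (bony shell at skull HU, water-like
lumen fluid, CaCO3 aggregates at 189 +/- 38.4 HU), then thresholds it with
the built-in material table.
"""

import numpy as np

from otolithct import default_config, generate_phantom, get_material, material_mask

volume, truth = generate_phantom(default_config(seed=1))
print(f"volume shape {volume.shape}, spacing {volume.spacing_mm} mm")

caco3 = get_material("CaCO3")
skull = get_material("skull")
m_caco3 = material_mask(volume, caco3)
m_skull = material_mask(volume, skull)
print(f"CaCO3 range {caco3.low}-{caco3.high} HU -> {m_caco3.count()} voxels")
print(f"skull range {skull.low}-{skull.high} HU -> {m_skull.count()} voxels")

for blob in truth.blobs:
    inside = m_caco3.data[blob.mask.data].mean()
    print(f"{blob.label}: {100 * inside:.1f}% of truth voxels fall in the CaCO3 range")

# With HU noise at the published SD (38.4), roughly 84% of aggregate voxels
# stay inside the closed 140-250 HU range; the rest are noise drop-outs the
# segmentation stage has to survive.
print(f"fraction of CaCO3 voxels inside the shell lumen: "
      f"{(m_caco3.data & truth.lumen_mask.data).sum() / max(m_caco3.count(), 1):.2f}")
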