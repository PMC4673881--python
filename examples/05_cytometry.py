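"""Nuclei segmentation and the Voronoi cell lattice (SCN / ASCS).

Renders a stained-nuclei SAM section, segments the nuclei, tessellates the
mask into cells and prints SAM cell number, average cell size and the
conservation identity, then runs the two-way ANOVA on a small simulated
class design.
"""

import numpy as np
import pandas as pd

from samgwas.config import SimConfig
from samgwas.cytometry import scn_ascs_model, segment_nuclei, tessellate
from samgwas.synthgen import gen_nuclei_image

cfg = SimConfig(seed=5)
h, r = 90.0, 70.0
mean_cell_area = (4 / 3) * h * r / 60  # target ~60 cells
img, mask, truth = gen_nuclei_image(h, r, mean_cell_area, cfg)

cents = segment_nuclei(img, mask)
lattice = tessellate(cents, mask)
print(f"placed {len(truth)} nuclei, segmented {lattice.scn} (SCN)")
print(f"ASCS = {lattice.ascs:.1f} µm² (generator target {mean_cell_area:.1f})")
print(f"sum of cell areas {lattice.cell_areas_um2.sum():.1f} = mask area {mask.area_um2:.1f}")

# two-way ANOVA: does genotype class predict SCN beyond SAM volume?
rng = np.random.default_rng(1)
rows = []
for k in range(24):
    cls = "ALT" if k % 2 else "COM"
    vol = rng.uniform(5e5, 1.5e6)
    scn = 0.8 * vol / 1e4 + (25 if cls == "ALT" else 0) + rng.normal(0, 5)
    rows.append({"genotype_class": cls, "volume": vol, "scn": scn})
anova = scn_ascs_model(pd.DataFrame(rows), response="scn")
print("\ntwo-way ANOVA (sequential SS), SCN ~ genotype + volume + interaction:")
print(anova.round(4).to_string())
print("\nBoth the genotype class and SAM volume rows should be significant"
      "\nhere: the class shifts cell number independently of dome size.")
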