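"""Trait extraction from segmented masks into the analysis matrix.

Extracts height, width, and size (bounding-box extents and foreground area,
scaled by the physical pixel size) from a series of masks and assembles the
per-plant, per-day records into a plants x days matrix with explicit
missingness for days a plant was not imaged.
"""

import numpy as np

from phenofda import PixelScale, TraitRecord, assemble_trait_matrix, extract_pheno

scale = PixelScale(Xsize=1.5, Ysize=2.0)  # mm per pixel, horizontal / vertical

records = []
rng = np.random.default_rng(0)
for plant, genotype in [("p1", "g1"), ("p2", "g2")]:
    # each plant imaged on its own (irregular) schedule
    days = [1.0, 3.0, 6.0] if plant == "p1" else [1.0, 6.0, 8.0]
    for i, day in enumerate(days):
        mask = np.zeros((100, 80), dtype=bool)
        h, w = 10 + 8 * i, 6 + 5 * i  # the plant grows between imaging days
        mask[80 - h : 80, 40 - w // 2 : 40 + w // 2] = True
        height, width, size = extract_pheno(mask, scale)
        records.append(TraitRecord(plant, genotype, "b1", day, height, width, size))
        print(f"{plant} day {day:>3}: height {height:6.1f} mm, width {width:5.1f} mm, size {size:7.1f} mm^2")

Y = assemble_trait_matrix(records, trait="size")
print(f"\nunion day grid: {list(Y.days)}")
print(f"matrix shape:   {Y.values.shape} with {np.isnan(Y.values).sum()} missing cells")
print(Y.values)
# Each row is one plant's size trajectory on the union grid; NaN marks days
# that plant was not imaged (days 3 and 8 here, observed by only one plant).
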