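"""Fit a habitat model on a phantom cohort and map one patient.

Runs windowing + entropy filtering + SLIC + population clustering (with
the habitat count fixed at the five planted tissue classes), assigns a
habitat map, and prints each habitat's volume share and mean HU — the
lowest-numbered habitat is the most aerated tissue (parenchyma), the
highest the densest (consolidation).
"""

import numpy as np

from habitatct import PhantomParams, generate_cohort
from habitatct.habitat import (
    assign_habitats,
    fit_population_clusters,
    oversegment,
    superpixel_features,
)
from habitatct.preprocess import make_composite

cohort = generate_cohort(3, 3, PhantomParams(), seed=5)
tables, spmaps = [], []
for case in cohort.cases:
    comp = make_composite(case.volume, case.mask, entropy_radius=2)
    sp = oversegment(comp, case.mask, n_superpixels=700)
    spmaps.append(sp)
    tables.append(superpixel_features(comp, sp))

model = fit_population_clusters(tables, k_range=(2, 8), seed=5, k=5)
print(f"habitat model: K={model.K}, fit on {model.n_rows_fit} pooled superpixels\n")

case = cohort.cases[0]
hmap = assign_habitats(spmaps[0], tables[0], model)
for h in range(1, model.K + 1):
    sel = hmap == h
    share = sel.sum() / case.mask.sum()
    mean_hu = case.volume[sel].mean() if sel.any() else float("nan")
    print(f"habitat SR{h}: volume share {share:5.2f}   mean {mean_hu:7.1f} HU")

print(
    "\nVolume shares are the MSI volume features; mean HU rises from "
    "aerated parenchyma (SR1) to consolidation (SR5).  On small cohorts "
    "two habitats may both be parenchyma-like (lesion-adjacent parenchyma "
    "forms its own texture phenotype); the dense habitats remain distinct."
)
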