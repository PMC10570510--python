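"""Extract the 88 multiregional spatial interaction features of one phantom.

Computes the MSI vector of a unilateral (pneumonia-like) and a bilateral
(pneumonitis-like) phantom and prints the features that differ most —
expected to be the left/right symmetric-difference block, which measures
how unevenly each habitat and its interactions are distributed between
the lungs.
"""

import numpy as np
import pandas as pd

from habitatct import PhantomParams, generate_cohort
from habitatct.habitat import (
    assign_habitats,
    fit_population_clusters,
    oversegment,
    superpixel_features,
)
from habitatct.msi import feature_dictionary, full_msi
from habitatct.preprocess import make_composite, split_lungs

cohort = generate_cohort(2, 2, PhantomParams(matched_composition=True), seed=3)
tables, spmaps = [], []
for case in cohort.cases:
    comp = make_composite(case.volume, case.mask, entropy_radius=2)
    sp = oversegment(comp, case.mask, 700)
    spmaps.append(sp)
    tables.append(superpixel_features(comp, sp))
model = fit_population_clusters(tables, seed=3, k=5)

vectors = []
for i, case in enumerate(cohort.cases):
    hmap = assign_habitats(spmaps[i], tables[i], model)
    left, right = split_lungs(case.mask)
    vectors.append(full_msi(hmap, left, right))
msi = pd.DataFrame(vectors, index=[c.patient_id for c in cohort.cases])
print(f"feature matrix: {msi.shape[0]} patients x {msi.shape[1]} MSI features")

# contrast the asymmetry (ΔSym) block between the two conditions
dsym = msi[[f"MSI{i}" for i in range(45, 89)]]
pneumonia = dsym.iloc[:2].mean()
pneumonitis = dsym.iloc[2:].mean()
ratio = (pneumonia + 1e-12) / (pneumonitis + 1e-12)
names = feature_dictionary()
print("\nasymmetry features most elevated in the unilateral (pneumonia) phantoms:")
for name in ratio.sort_values(ascending=False).head(5).index:
    print(f"  {name:6s} x{ratio[name]:8.1f}   {names[name]}")
print(
    "\nLarge ratios show the ΔSym block firing on unilateral disease while "
    "staying near zero for mirrored disease."
)
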