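import warnings

import numpy as np
import pytest

from habitatct.habitat import fit_population_clusters, oversegment, superpixel_features
from habitatct.phantoms import CohortBundle, PhantomCase, PhantomParams, generate_cohort
from habitatct.preprocess import make_composite

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """A 2+2 phantom cohort with composites, superpixel maps, and feature tables."""
    cohort = generate_cohort(2, 2, PhantomParams(), seed=7)
    comps, sps, tables = [], [], []
    for case in cohort.cases:
        comp = make_composite(case.volume, case.mask, entropy_radius=2)
        sp = oversegment(comp, case.mask, 700, 0.1)
        comps.append(comp)
        sps.append(sp)
        tables.append(superpixel_features(comp, sp))
    return {"cohort": cohort, "composites": comps, "spmaps": sps, "tables": tables}


@pytest.fixture(scope="session")
def habitat_model5(small_cohort):
    """Habitat model fit on the small cohort with K fixed at the planted count."""
    return fit_population_clusters(small_cohort["tables"], (2, 8), gap_refs=8, seed=7, k=5)


def label_only_cohort(labels) -> CohortBundle:
    """A cohort shell carrying only patient ids and labels (for clinical tables)."""
    empty = np.zeros((0, 0, 0))
    cases = [
        PhantomCase(f"P{i:03d}", empty, empty.astype(bool), empty.astype(np.int8), int(l))
        for i, l in enumerate(labels)
    ]
    return CohortBundle(cases, PhantomParams(), seed=0)
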