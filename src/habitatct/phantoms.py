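"""Synthetic CT lung phantoms with planted tissue habitats.

Real chest CT of the study population (AML patients on checkpoint
inhibitors who developed pneumonia or pneumonitis) is not publicly
available, so every downstream stage of the pipeline is exercised on
phantoms: two ellipsoidal lung fields filled with aerated parenchyma and
planted lesions of four classes — two grades of parenchyma-to-GGO
transition, ground-glass opacity (GGO), and consolidation — with
class-dependent left/right symmetry.  Pneumonia-like phantoms
(``condition=0``) carry predominantly unilateral consolidation cores with
transition rims; pneumonitis-like phantoms (``condition=1``) carry
bilateral, near-mirror-symmetric GGO.  The left/right symmetry knob is the
main discriminating signal between the two conditions.

A paired clinical/blood table generator emulates the covariate schema of
the study cohort (symptoms at two timepoints, age, sex, and five blood
measurements), with class-conditional medians.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhantomParams",
    "ClinicalEffectConfig",
    "PhantomCase",
    "CohortBundle",
    "TISSUE_CLASSES",
    "generate_phantom",
    "generate_cohort",
    "generate_clinical_table",
    "CLINICAL_COLUMNS",
]

HU_MIN, HU_MAX = -1024.0, 3071.0

#: truth-map codes; 0 is outside the lungs
PARENCHYMA, TRANSITION_LOW, GGO, CONSOLIDATION, TRANSITION_HIGH = 1, 2, 3, 4, 5
TISSUE_CLASSES = {
    PARENCHYMA: "parenchyma",
    TRANSITION_LOW: "transition_low",
    GGO: "ggo",
    CONSOLIDATION: "consolidation",
    TRANSITION_HIGH: "transition_high",
}


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, attenuation, and noise settings for one phantom.

    HU class means are plausible radiological conventions: aerated
    parenchyma near -850 HU, GGO near -450 HU, consolidation near
    soft-tissue (+20 HU), and two transition grades in between.  The
    default slice thickness of 2.5 mm with ~1 mm in-plane spacing mirrors
    a typical diagnostic chest CT protocol.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 16)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 2.5)
    hu_parenchyma: float = -870.0
    hu_ggo: float = -350.0
    hu_consolidation: float = 20.0
    hu_transition: tuple[float, float] = (-670.0, -460.0)
    noise_sd: float = 20.0
    #: per-class multipliers of noise_sd — the texture signature of each
    #: tissue (indexed by truth class code - 1: parenchyma, transition-low,
    #: GGO, consolidation, transition-high).  Parenchyma is quiet,
    #: consolidation homogeneous; the low-grade transition is a coarse
    #: reticular pattern (strongly textured), the high-grade transition a
    #: smooth haze, GGO in between — each class is distinct in both
    #: attenuation and texture, as the five habitats are on real CT
    texture_multipliers: tuple[float, float, float, float, float] = (0.5, 6.0, 3.5, 1.0, 0.7)
    #: sub-solid tissue never reaches soft-tissue attenuation; draws above
    #: this HU ceiling are truncated for all classes except consolidation
    hu_subsolid_ceiling: float = -180.0
    lesion_count_range: tuple[int, int] = (1, 2)
    #: probability that each planted blob is mirrored into the other lung
    symmetry_pneumonia: float = 0.0
    symmetry_pneumonitis: float = 1.0
    #: when True, both conditions use the same lesion recipe (consolidation
    #: cores + rims + GGO) so left/right symmetry is the only class signal
    matched_composition: bool = False
    seed: int = 0

    def class_means(self) -> dict[int, float]:
        return {
            PARENCHYMA: self.hu_parenchyma,
            TRANSITION_LOW: self.hu_transition[0],
            GGO: self.hu_ggo,
            CONSOLIDATION: self.hu_consolidation,
            TRANSITION_HIGH: self.hu_transition[1],
        }

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) < 16 for s in self.grid_shape):
            raise ValueError("grid_shape must be a triple with all dims >= 16")
        for hu in (*self.class_means().values(),):
            if not (HU_MIN <= hu <= HU_MAX):
                raise ValueError(f"class mean {hu} HU outside [{HU_MIN}, {HU_MAX}]")
        lo, hi = self.hu_transition
        if not (self.hu_parenchyma < lo <= hi < self.hu_ggo):
            raise ValueError("transition means must lie between parenchyma and GGO")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        a, b = self.lesion_count_range
        if not (1 <= a <= b):
            raise ValueError("lesion_count_range must be an increasing pair >= 1")
        for s in (self.symmetry_pneumonia, self.symmetry_pneumonitis):
            if not (0.0 <= s <= 1.0):
                raise ValueError("symmetry must be in [0, 1]")


@dataclass
class PhantomCase:
    patient_id: str
    volume: np.ndarray  # HU, float
    mask: np.ndarray  # bool lung mask
    truth: np.ndarray  # int8 tissue classes
    label: int  # 0 pneumonia, 1 pneumonitis


@dataclass
class CohortBundle:
    cases: list[PhantomCase]
    params: PhantomParams
    seed: int

    @property
    def labels(self) -> np.ndarray:
        return np.array([c.label for c in self.cases], dtype=int)

    def __len__(self) -> int:
        return len(self.cases)


def _lung_fields(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Two disjoint ellipsoidal lungs, mirror-symmetric about the x midline."""
    nx, ny, nz = shape
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
    rx, ry, rz = nx * 0.16, ny * 0.30, nz * 0.42
    cx_left = (nx - 1) * 0.28
    cx_right = (nx - 1) - cx_left  # exact mirror partner on the grid

    def ellipsoid(cx: float) -> np.ndarray:
        return (
            ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
        ) <= 1.0

    left, right = ellipsoid(cx_left), ellipsoid(cx_right)
    if not left.any() or not right.any() or (left & right).any():
        raise ValueError("grid too small to fit two disjoint lung fields")
    return left, right


def _mirror(m: np.ndarray) -> np.ndarray:
    """Reflect a voxel set across the x midline (axis 0)."""
    return m[::-1, :, :]


def _ellipsoid(shape, center, radii) -> np.ndarray:
    x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((x - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((z - center[2]) / radii[2]) ** 2
    ) <= 1.0


#: lesion blobs per class per "lesion unit", by condition.  Pneumonia is
#: consolidation-dominant; pneumonitis is GGO-dominant with small
#: consolidation foci (organizing-pneumonia-like component).
_RECIPES = {
    0: ((CONSOLIDATION, 2), (GGO, 1), (TRANSITION_HIGH, 1), (TRANSITION_LOW, 1)),
    1: ((GGO, 2), (TRANSITION_HIGH, 1), (TRANSITION_LOW, 1), (CONSOLIDATION, 1)),
}


def _place_lesions(
    primary: np.ndarray,
    recipe,
    n_units: int,
    rng: np.random.Generator,
    shape,
    max_overlap: float = 0.15,
) -> list[tuple[int, np.ndarray]]:
    """Plant mostly non-overlapping ellipsoidal lesion patches in one lung.

    Each patch is a single tissue class; overlapping candidates are
    rejected so every lesion site carries one coherent process.
    """
    lesioned = np.zeros(shape, dtype=bool)
    blobs: list[tuple[int, np.ndarray]] = []
    for cls, per_unit in recipe:
        target = per_unit * n_units
        placed = tries = 0
        while placed < target and tries < 30 * target:
            tries += 1
            radii = (
                rng.uniform(9, 13),
                rng.uniform(9, 13),
                rng.uniform(3.0, 5.0),
            )
            # centers confined to the anterior half so each lesion and its
            # posterior-reflected partner occupy disjoint territory
            y_cap = (shape[1] - 1) / 2.0 - radii[1]
            cand = primary & ~lesioned
            cand[:, int(np.ceil(y_cap)) + 1 :, :] = False
            free = np.argwhere(cand)
            if len(free) == 0:
                break
            center = free[rng.integers(len(free))]
            b = _ellipsoid(shape, center, radii) & primary
            if b.sum() == 0 or (b & lesioned).sum() > max_overlap * b.sum():
                continue
            b &= ~lesioned
            blobs.append((cls, b))
            lesioned |= b
            placed += 1
    return blobs


def generate_phantom(
    params: PhantomParams, condition: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate one phantom: ``(volume HU, lung mask, tissue truth map)``.

    ``condition`` 0 (pneumonia-like) plants a consolidation-dominant
    lesion mix predominantly in one lung; ``condition`` 1
    (pneumonitis-like) plants a GGO-dominant mix mirrored across both
    lungs (the symmetry knob sets the per-lesion mirroring probability).
    Each lesion patch is a single tissue class; voxel HU are the class
    mean plus class-textured Gaussian noise, truncated below soft-tissue
    attenuation for all sub-solid classes.  Deterministic given
    ``params`` (including ``params.seed``).
    """
    params.validate()
    if condition not in (0, 1):
        raise ValueError("condition must be 0 (pneumonia) or 1 (pneumonitis)")
    rng = np.random.default_rng(params.seed)
    left, right = _lung_fields(params.grid_shape)
    mask = left | right

    symmetry = params.symmetry_pneumonia if condition == 0 else params.symmetry_pneumonitis
    recipe = _RECIPES[0] if (condition == 0 or params.matched_composition) else _RECIPES[1]
    primary = left if rng.random() < 0.5 else right
    n_units = int(rng.integers(params.lesion_count_range[0], params.lesion_count_range[1] + 1))

    blobs = _place_lesions(primary, recipe, n_units, rng, params.grid_shape)
    # volume-preserving symmetry: every lesion gets a same-class partner —
    # mirrored into the contralateral lung with probability ``symmetry``,
    # otherwise planted elsewhere in the same lung.  Total lesion burden is
    # therefore independent of the symmetry setting; only the left/right
    # arrangement differs between conditions.
    partners: list[tuple[int, np.ndarray]] = []
    for c, b in blobs:
        if rng.random() < symmetry:
            partners.append((c, _mirror(b) & mask))  # contralateral mirror
        else:
            # same-lung anterior-posterior reflection: the lung field is
            # symmetric in y, so the partner has identical clipping geometry
            partners.append((c, b[:, ::-1, :] & mask))
    blobs += partners

    truth = np.zeros(params.grid_shape, dtype=np.int8)
    truth[mask] = PARENCHYMA
    for c, b in blobs:
        truth[b & mask & (truth == PARENCHYMA)] = c

    # guarantee every lesion class occupies >= 1 voxel; the anchor pair
    # follows the same symmetry semantics as regular lesions
    lesion_classes = (TRANSITION_LOW, GGO, CONSOLIDATION, TRANSITION_HIGH)
    anchor = np.argwhere(primary).mean(axis=0).astype(int)
    for j, c in enumerate(lesion_classes):
        if not (truth == c).any():
            center = anchor + np.array([0, (j - 1.5) * 5, 0], dtype=int)
            b = _ellipsoid(params.grid_shape, center, (4, 4, 2)) & mask
            if not b.any():
                b = _ellipsoid(params.grid_shape, anchor, (4, 4, 2)) & mask
            partner = _mirror(b) if rng.random() < symmetry else (b[:, ::-1, :] & mask)
            truth[(b | partner) & mask] = c

    means = params.class_means()
    volume = np.full(params.grid_shape, 40.0)  # soft-tissue background
    for c, mu in means.items():
        sel = truth == c
        vals = np.full(int(sel.sum()), mu)
        if params.noise_sd > 0:
            vals = vals + params.noise_sd * params.texture_multipliers[c - 1] * rng.standard_normal(
                vals.size
            )
        if c != CONSOLIDATION:
            vals = np.minimum(vals, params.hu_subsolid_ceiling)
        volume[sel] = vals
    volume = np.clip(volume, HU_MIN, HU_MAX)
    return volume, mask, truth


def generate_cohort(
    n_pneumonia: int,
    n_pneumonitis: int,
    params: PhantomParams | None = None,
    seed: int = 0,
) -> CohortBundle:
    """A labelled cohort of phantoms with per-patient derived seeds."""
    if n_pneumonia < 1 or n_pneumonitis < 1:
        raise ValueError("both class counts must be >= 1")
    params = params or PhantomParams()
    n = n_pneumonia + n_pneumonitis
    labels = np.array([0] * n_pneumonia + [1] * n_pneumonitis)
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)
    cases = []
    for i, (lab, s) in enumerate(zip(labels, seeds)):
        p = dataclasses.replace(params, seed=int(s))
        vol, mask, truth = generate_phantom(p, int(lab))
        cases.append(PhantomCase(f"P{i:03d}", vol, mask, truth, int(lab)))
    return CohortBundle(cases, params, seed)


# --------------------------------------------------------------------------
# clinical / blood covariates


def _pair(a: float, b: float) -> tuple[float, float]:
    return (a, b)


@dataclass(frozen=True)
class ClinicalEffectConfig:
    """Class-conditional distributions (pneumonia, pneumonitis) per covariate.

    Defaults echo the cohort characteristics of the study population:
    pneumonitis patients are slightly older, more often female, and have
    lower median platelet and WBC counts at the time of syndrome.  Blood
    counts are drawn log-normally (positive, right-skewed), parameterized
    by their median.
    """

    age_mean: tuple[float, float] = _pair(64.0, 69.1)
    age_sd: float = 10.0
    female_rate: tuple[float, float] = _pair(0.38, 0.59)
    cough_baseline: tuple[float, float] = _pair(0.23, 0.21)
    fever_baseline: tuple[float, float] = _pair(0.19, 0.24)
    dyspnea_baseline: tuple[float, float] = _pair(0.23, 0.28)
    cough_syndrome: tuple[float, float] = _pair(0.74, 0.66)
    fever_syndrome: tuple[float, float] = _pair(0.79, 0.72)
    dyspnea_syndrome: tuple[float, float] = _pair(0.65, 0.76)
    # medians of log-normal draws
    wbc_baseline: tuple[float, float] = _pair(2.5, 2.3)
    wbc_syndrome: tuple[float, float] = _pair(2.4, 1.4)
    anc_baseline: tuple[float, float] = _pair(23.0, 19.0)
    anc_syndrome: tuple[float, float] = _pair(22.0, 30.0)
    alc_baseline: tuple[float, float] = _pair(40.0, 40.1)
    alc_syndrome: tuple[float, float] = _pair(25.0, 25.0)
    platelets_baseline: tuple[float, float] = _pair(34.0, 29.0)
    platelets_syndrome: tuple[float, float] = _pair(22.0, 14.0)
    blasts_baseline: tuple[float, float] = _pair(20.0, 15.0)
    lognormal_sigma: float = 0.6

    @classmethod
    def zero_effects(cls) -> "ClinicalEffectConfig":
        """Both classes drawn from the pooled (averaged) distributions."""
        kwargs = {}
        for f in dataclasses.fields(cls):
            if isinstance(f.default, tuple):
                m = (f.default[0] + f.default[1]) / 2.0
                kwargs[f.name] = (m, m)
        return cls(**kwargs)

    def validate(self) -> None:
        if self.age_sd <= 0 or self.lognormal_sigma <= 0:
            raise ValueError("scale parameters must be > 0")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple) and (v[0] < 0 or v[1] < 0):
                raise ValueError(f"negative location for {f.name}")


CLINICAL_COLUMNS = [
    "patient_id",
    "label",
    "age",
    "sex",
    "cough_baseline",
    "fever_baseline",
    "dyspnea_baseline",
    "cough_syndrome",
    "fever_syndrome",
    "dyspnea_syndrome",
    "wbc_baseline",
    "wbc_syndrome",
    "anc_baseline",
    "anc_syndrome",
    "alc_baseline",
    "alc_syndrome",
    "platelets_baseline",
    "platelets_syndrome",
    "blasts_baseline",
]

_BINARY_RATE_COLS = [
    "cough_baseline",
    "fever_baseline",
    "dyspnea_baseline",
    "cough_syndrome",
    "fever_syndrome",
    "dyspnea_syndrome",
]
_LOGNORMAL_COLS = [
    "wbc_baseline",
    "wbc_syndrome",
    "anc_baseline",
    "anc_syndrome",
    "alc_baseline",
    "alc_syndrome",
    "platelets_baseline",
    "platelets_syndrome",
    "blasts_baseline",
]


def generate_clinical_table(
    cohort: CohortBundle,
    effect_config: ClinicalEffectConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One row of clinical/blood covariates per cohort patient.

    Binary symptoms at two timepoints, age, sex (1=female), and nine blood
    measurements; class-conditional parameters come from ``effect_config``.
    """
    cfg = effect_config or ClinicalEffectConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for case in cohort.cases:
        g = case.label
        row = {"patient_id": case.patient_id, "label": g}
        row["age"] = float(np.clip(rng.normal(cfg.age_mean[g], cfg.age_sd), 18, 100))
        row["sex"] = int(rng.random() < cfg.female_rate[g])
        for col in _BINARY_RATE_COLS:
            row[col] = int(rng.random() < getattr(cfg, col)[g])
        for col in _LOGNORMAL_COLS:
            median = getattr(cfg, col)[g]
            row[col] = float(rng.lognormal(np.log(max(median, 1e-9)), cfg.lognormal_sigma))
        rows.append(row)
    return pd.DataFrame(rows, columns=CLINICAL_COLUMNS)
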