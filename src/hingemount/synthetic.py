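"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a 514-patient orthognathic-surgery cohort as a
three-component Gaussian mixture over the mounting triple (alpha, AxV, AxH),
with per-cluster sample sizes, sex compositions, age distributions and
cephalometric variables matching the published per-phenotype summaries.
Variables are independent Gaussians within a cluster (within-cluster
covariances are unpublished); positive-valued quantities are truncated by
resampling, never clipping, to avoid point masses at the bound.

Nine cephalometric variables are generated with all three cluster means
separated (the discriminative set); the other thirteen use a synthetic
two-clusters-equal pattern so that the all-pairs selection rule excludes
them, mirroring the 9-of-22 structure of the source cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import (
    CephLandmarks,
    FacebowSpec,
    InfeasibleFacebowError,
    LandmarkLayout,
    MountingValues,
    invert_mounting,
)

__all__ = [
    "VariableSpec",
    "ClusterSpec",
    "GeneratorSpec",
    "default_generator_spec",
    "generate_cohort",
    "generate_landmark_cohort",
    "generate_registry_fixture",
    "DISCRIMINATIVE_CEPH_VARS",
    "OVERLAPPING_CEPH_VARS",
]


@dataclass(frozen=True)
class VariableSpec:
    mean: float
    sd: float
    lower: float | None = None  # truncation bound (resampled, open interval)

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class ClusterSpec:
    """One mixture component: sizes, sex split, and per-variable Gaussians."""

    name: str
    n: int
    n_female: int
    n_male: int
    mounting: dict[str, VariableSpec]  # alpha_deg, axv_mm, axh_mm
    age_by_sex: dict[str, VariableSpec]  # female, male
    ceph: dict[str, VariableSpec] = field(default_factory=dict)

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("cluster n must be > 0")
        if self.n_female + self.n_male != self.n:
            raise ValueError("sex counts must sum to n")
        for key in ("alpha_deg", "axv_mm", "axh_mm"):
            if key not in self.mounting:
                raise ValueError(f"mounting spec missing {key}")


@dataclass(frozen=True)
class GeneratorSpec:
    clusters: tuple[ClusterSpec, ...]
    seed: int = 20230521

    @property
    def n_total(self) -> int:
        return sum(c.n for c in self.clusters)


# The nine cephalometric variables whose means separate all three phenotypes
# (balanced, vertical_II, horizontal_III).  The relative maxillary-to-
# mandibular length ratio is printed to one decimal in the source summaries,
# which collapses the balanced and horizontal clusters onto the same value;
# the defaults below use 1.42/1.32/1.38, consistent with that rounding and
# with all three pairwise differences being significant.
DISCRIMINATIVE_CEPH_VARS: dict[str, list[VariableSpec]] = {
    "facial_axis": [VariableSpec(89.1, 5.7), VariableSpec(85.7, 5.9), VariableSpec(91.8, 6.5)],
    "facial_depth": [VariableSpec(89.5, 4.8), VariableSpec(85.7, 5.0), VariableSpec(92.1, 5.3)],
    "snb": [VariableSpec(80.2, 5.6), VariableSpec(76.0, 5.2), VariableSpec(82.4, 6.4)],
    "rel_mand_length": [VariableSpec(118.7, 10.0), VariableSpec(106.3, 9.0), VariableSpec(114.0, 9.2)],
    "sna": [VariableSpec(82.4, 4.3), VariableSpec(79.9, 4.3), VariableSpec(81.1, 4.9)],
    "convexity_point_a": [VariableSpec(1.3, 4.8), VariableSpec(2.8, 5.0), VariableSpec(-2.8, 4.6)],
    "rel_max_mand_ratio": [VariableSpec(1.42, 0.1), VariableSpec(1.32, 0.1), VariableSpec(1.38, 0.1)],
    "sagittal_molar_distance": [VariableSpec(20.4, 4.8), VariableSpec(16.9, 4.2), VariableSpec(19.1, 4.5)],
    "lower_lip_e_line": [VariableSpec(-2.2, 3.6), VariableSpec(-1.3, 3.0), VariableSpec(-3.3, 3.3)],
}

# Thirteen synthetic variables with two cluster means equal, so they separate
# only two of the three clusters and the selection rule drops them.  Values
# are plausible cephalometric magnitudes, not measurements of any cohort.
OVERLAPPING_CEPH_VARS: dict[str, list[VariableSpec]] = {
    "mandibular_plane": [VariableSpec(26.0, 5.0), VariableSpec(26.0, 5.5), VariableSpec(21.5, 5.0)],
    "inner_gonion_angle": [VariableSpec(72.0, 6.0), VariableSpec(72.0, 6.0), VariableSpec(76.0, 6.0)],
    "maxillary_position": [VariableSpec(61.0, 3.5), VariableSpec(59.0, 3.5), VariableSpec(61.0, 3.5)],
    "palatal_plane": [VariableSpec(1.0, 3.5), VariableSpec(3.0, 3.5), VariableSpec(1.0, 3.5)],
    "rel_max_length": [VariableSpec(92.0, 6.0), VariableSpec(88.0, 6.0), VariableSpec(92.0, 6.0)],
    "lower_facial_height": [VariableSpec(45.0, 4.5), VariableSpec(45.0, 4.5), VariableSpec(41.0, 4.0)],
    "lower_incisor_position": [VariableSpec(2.0, 2.2), VariableSpec(2.0, 2.2), VariableSpec(4.0, 2.2)],
    "lower_incisor_inclination": [VariableSpec(25.0, 6.0), VariableSpec(25.0, 6.0), VariableSpec(29.0, 6.0)],
    "upper_incisor_position": [VariableSpec(6.5, 2.5), VariableSpec(6.5, 2.5), VariableSpec(8.5, 2.5)],
    "upper_incisor_inclination": [VariableSpec(29.0, 7.0), VariableSpec(33.0, 7.0), VariableSpec(29.0, 7.0)],
    "inter_incisor_angle": [VariableSpec(125.0, 10.0), VariableSpec(120.0, 10.0), VariableSpec(125.0, 10.0)],
    "vertical_molar_distance": [VariableSpec(23.0, 2.5), VariableSpec(23.0, 2.5), VariableSpec(24.5, 2.5)],
    "upper_lip_drape": [VariableSpec(92.0, 8.0), VariableSpec(88.0, 8.0), VariableSpec(92.0, 8.0)],
}


def default_generator_spec(seed: int = 20230521) -> GeneratorSpec:
    """The three-phenotype mixture matching the published cluster summaries.

    Cluster sizes 128/204/182, sex splits 36+92 / 171+33 / 116+66, mounting
    Gaussians (alpha, AxV, AxH) = (7.8+-3.4, 36.2+-4.6, 98.9+-5.5),
    (11.1+-3.3, 26.5+-3.8, 88.1+-5.4) and (2.4+-4.0, 35.9+-4.5, 85.6+-5.6),
    plus per-sex age distributions and the 22 cephalometric variables.
    """
    mounting = [
        {"alpha_deg": VariableSpec(7.8, 3.4),
         "axv_mm": VariableSpec(36.2, 4.6, lower=0.0),
         "axh_mm": VariableSpec(98.9, 5.5, lower=0.0)},
        {"alpha_deg": VariableSpec(11.1, 3.3),
         "axv_mm": VariableSpec(26.5, 3.8, lower=0.0),
         "axh_mm": VariableSpec(88.1, 5.4, lower=0.0)},
        {"alpha_deg": VariableSpec(2.4, 4.0),
         "axv_mm": VariableSpec(35.9, 4.5, lower=0.0),
         "axh_mm": VariableSpec(85.6, 5.6, lower=0.0)},
    ]
    age = [
        {"female": VariableSpec(26.3, 9.2, lower=10.0), "male": VariableSpec(28.8, 9.0, lower=10.0)},
        {"female": VariableSpec(26.0, 7.9, lower=10.0), "male": VariableSpec(27.6, 7.0, lower=10.0)},
        {"female": VariableSpec(26.3, 9.7, lower=10.0), "male": VariableSpec(26.9, 7.9, lower=10.0)},
    ]
    sizes = [(128, 36, 92), (204, 171, 33), (182, 116, 66)]
    names = ["balanced", "vertical_II", "horizontal_III"]
    clusters = []
    for i, (name, (n, nf, nm)) in enumerate(zip(names, sizes)):
        ceph = {
            **{k: v[i] for k, v in DISCRIMINATIVE_CEPH_VARS.items()},
            **{k: v[i] for k, v in OVERLAPPING_CEPH_VARS.items()},
        }
        clusters.append(
            ClusterSpec(
                name=name, n=n, n_female=nf, n_male=nm,
                mounting=mounting[i], age_by_sex=age[i], ceph=ceph,
            )
        )
    return GeneratorSpec(clusters=tuple(clusters), seed=seed)


def _draw(rng: np.random.Generator, spec: VariableSpec, size: int) -> np.ndarray:
    """Sample a truncated Gaussian by resampling values at/below the bound."""
    x = rng.normal(spec.mean, spec.sd, size=size)
    if spec.lower is not None:
        bad = x <= spec.lower
        while bad.any():
            x[bad] = rng.normal(spec.mean, spec.sd, size=int(bad.sum()))
            bad = x <= spec.lower
    return x


def generate_cohort(spec: GeneratorSpec | None = None, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort table; ``true_cluster`` carries the ground-truth label.

    Columns: patient_id, true_cluster, sex, age, alpha_deg, axv_mm, axh_mm
    and every cephalometric variable in the spec.  Deterministic per seed.
    """
    spec = spec or default_generator_spec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    frames = []
    pid = 0
    for ci, cl in enumerate(spec.clusters):
        data = {
            "patient_id": [f"P{pid + j:04d}" for j in range(cl.n)],
            "true_cluster": [cl.name] * cl.n,
            "sex": ["female"] * cl.n_female + ["male"] * cl.n_male,
        }
        pid += cl.n
        age = np.empty(cl.n)
        age[: cl.n_female] = _draw(rng, cl.age_by_sex["female"], cl.n_female)
        age[cl.n_female:] = _draw(rng, cl.age_by_sex["male"], cl.n_male)
        data["age"] = age
        for key in ("alpha_deg", "axv_mm", "axh_mm"):
            data[key] = _draw(rng, cl.mounting[key], cl.n)
        for key, vs in cl.ceph.items():
            data[key] = _draw(rng, vs, cl.n)
        frames.append(pd.DataFrame(data))
    out = pd.concat(frames, ignore_index=True)
    # shuffle rows so cluster membership is not positional
    order = rng.permutation(len(out))
    return out.iloc[order].reset_index(drop=True)


def generate_landmark_cohort(
    spec: GeneratorSpec | None = None,
    facebow: FacebowSpec = FacebowSpec(d_ns_mm=23.0),
    layout: LandmarkLayout = LandmarkLayout(),
    randomize_pose: bool = True,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, CephLandmarks], int]:
    """Cohort plus per-patient landmark sets realising each mounting triple.

    Each patient's landmarks reproduce their generated (alpha, AxV, AxH)
    under :func:`hingemount.geometry.compute_mounting`.  Infeasible triples
    are resampled; the count of resamples is returned.  With
    ``randomize_pose`` every set gets a random rigid pose (the mounting is
    invariant to it).
    """
    spec = spec or default_generator_spec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    cohort = generate_cohort(spec)
    rng = np.random.default_rng(spec.seed + 1)
    by_name = {cl.name: cl for cl in spec.clusters}
    landmarks: dict[str, CephLandmarks] = {}
    n_resampled = 0
    for idx, row in cohort.iterrows():
        triple = (row["alpha_deg"], row["axv_mm"], row["axh_mm"])
        cl = by_name[row["true_cluster"]]
        while True:
            try:
                values = MountingValues(*triple)
                pose = layout
                if randomize_pose:
                    pose = replace(
                        layout,
                        rotation_deg=float(rng.uniform(-20, 20)),
                        translation_mm=tuple(rng.uniform(-30, 30, size=2)),
                    )
                lm = invert_mounting(values, facebow, pose)
                break
            except (ValueError, InfeasibleFacebowError):
                n_resampled += 1
                triple = tuple(
                    float(_draw(rng, cl.mounting[k], 1)[0])
                    for k in ("alpha_deg", "axv_mm", "axh_mm")
                )
                cohort.loc[idx, ["alpha_deg", "axv_mm", "axh_mm"]] = triple
        landmarks[row["patient_id"]] = lm
    return cohort, landmarks, n_resampled


def generate_registry_fixture(
    n_eligible: int = 568,
    n_excluded: int = 37,
    n_second_plans: int = 17,
    seed: int = 20230521,
) -> pd.DataFrame:
    """A raw planning registry with exclusion and duplicate-plan structure.

    ``n_eligible`` counts plan rows; ``n_second_plans`` patients contribute
    two rows each, and ``n_excluded`` single-plan rows carry an exclusion
    reason, so the inclusion filter yields
    ``n_eligible - n_excluded - n_second_plans`` cases.
    """
    if n_excluded < 0 or n_second_plans < 0:
        raise ValueError("counts must be nonnegative")
    if n_excluded + n_second_plans > n_eligible:
        raise ValueError("excluded + second plans cannot exceed eligible rows")
    n_patients = n_eligible - n_second_plans
    if n_excluded > n_patients - n_second_plans:
        raise ValueError("not enough single-plan rows to exclude")
    rng = np.random.default_rng(seed)
    twice = rng.choice(n_patients, size=n_second_plans, replace=False)
    singles = np.setdiff1d(np.arange(n_patients), twice)
    excluded = set(rng.choice(singles, size=n_excluded, replace=False).tolist()) if n_excluded else set()
    mixture = default_generator_spec().clusters
    weights = np.array([cl.n for cl in mixture], dtype=float)
    weights /= weights.sum()
    rows = []
    for i in range(n_patients):
        cl = mixture[int(rng.choice(len(mixture), p=weights))]
        n_plans = 2 if i in set(twice.tolist()) else 1
        for plan in range(1, n_plans + 1):
            rows.append(
                {
                    "patient_id": f"R{i:04d}",
                    "plan_index": plan,
                    "excluded_reason": "exclusion criterion" if i in excluded else "",
                    "alpha_deg": float(_draw(rng, cl.mounting["alpha_deg"], 1)[0]),
                    "axv_mm": float(_draw(rng, cl.mounting["axv_mm"], 1)[0]),
                    "axh_mm": float(_draw(rng, cl.mounting["axh_mm"], 1)[0]),
                }
            )
    df = pd.DataFrame(rows)
    return df.sample(frac=1.0, random_state=int(seed) % (2**32 - 1)).reset_index(drop=True)
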