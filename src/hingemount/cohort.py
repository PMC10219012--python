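"""Cohort assembly and k-means phenotype clustering of mounting triples.

The clustering pipeline mirrors routine practice for phenotype discovery:
z-score the three mounting variables, fit k-means over a range of k, pick k
by the elbow criterion on the within-cluster sum of squares (WSS) curve, and
attach anatomical phenotype labels to the k = 3 solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "MOUNTING_VARS",
    "PHENOTYPES",
    "DEFAULT_SEED",
    "DEFAULT_RESTARTS",
    "FilterReport",
    "ScalingParams",
    "ClusterModel",
    "LabellingAmbiguityError",
    "RegistryValidationError",
    "filter_registry",
    "scale_variables",
    "kmeans_fit",
    "wss_curve",
    "elbow_select",
    "label_clusters",
    "cluster_mounting_cohort",
]

MOUNTING_VARS = ["alpha_deg", "axv_mm", "axh_mm"]
PHENOTYPES = ["balanced", "vertical_II", "horizontal_III"]
DEFAULT_SEED = 20230521
DEFAULT_RESTARTS = 25


class RegistryValidationError(ValueError):
    """Registry rows carry contradictory inclusion/exclusion flags."""


class LabellingAmbiguityError(ValueError):
    """The phenotype labelling rules collide on one cluster."""


@dataclass(frozen=True)
class FilterReport:
    """Inclusion accounting for a planning registry."""

    n_eligible: int
    n_excluded: int
    n_duplicate_plans_removed: int
    n_included: int


@dataclass(frozen=True)
class ScalingParams:
    """Per-variable mean/SD retained to map cluster centers back to raw units."""

    variables: list[str]
    means: np.ndarray
    sds: np.ndarray

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        return np.asarray(scaled) * self.sds + self.means


@dataclass
class ClusterModel:
    """A fitted k-means phenotype model."""

    k: int
    centers_scaled: np.ndarray
    centers_raw: np.ndarray
    assignments: np.ndarray
    wss: float
    wss_curve: np.ndarray  # total WSS for k = 1..kmax
    scaling: ScalingParams
    seed: int
    phenotype_labels: dict[int, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k": int(self.k),
            "seed": int(self.seed),
            "variables": list(self.scaling.variables),
            "centers_scaled": self.centers_scaled.tolist(),
            "centers_raw": self.centers_raw.tolist(),
            "wss": float(self.wss),
            "wss_curve": [float(w) for w in self.wss_curve],
            "phenotype_labels": {str(i): l for i, l in self.phenotype_labels.items()},
            "assignments": [int(a) for a in self.assignments],
        }


def filter_registry(registry: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the inclusion rules to a raw planning registry.

    Rows with a non-empty ``excluded_reason`` are dropped first; then, for
    every patient planned more than once, only the latest plan (largest
    ``plan_index``) is kept.  An ``is_excluded`` flag, when present, must
    agree with ``excluded_reason``.
    """
    df = registry.copy()
    n_eligible = len(df)
    if n_eligible == 0:
        empty = df.copy()
        return empty, FilterReport(0, 0, 0, 0)
    if "patient_id" not in df.columns:
        raise ValueError("registry requires a patient_id column")
    reason = (
        df["excluded_reason"].fillna("").astype(str).str.strip()
        if "excluded_reason" in df.columns
        else pd.Series("", index=df.index)
    )
    excluded_mask = reason != ""
    if "is_excluded" in df.columns:
        flag = df["is_excluded"].fillna(False).astype(bool)
        if (flag != excluded_mask).any():
            bad = df.loc[flag != excluded_mask, "patient_id"].tolist()
            raise RegistryValidationError(
                f"is_excluded contradicts excluded_reason for patients {bad}"
            )
    n_excluded = int(excluded_mask.sum())
    kept = df.loc[~excluded_mask].copy()
    if "plan_index" in kept.columns:
        kept = kept.sort_values(["patient_id", "plan_index"], kind="stable")
    before = len(kept)
    kept = kept.drop_duplicates(subset="patient_id", keep="last")
    n_dup = before - len(kept)
    kept = kept.sort_index().reset_index(drop=True)
    return kept, FilterReport(n_eligible, n_excluded, n_dup, len(kept))


def scale_variables(
    cohort: pd.DataFrame, variables: list[str] | None = None
) -> tuple[np.ndarray, ScalingParams]:
    """Z-score the clustering variables (SD with n-1 denominator)."""
    variables = list(variables or MOUNTING_VARS)
    if len(cohort) < 2:
        raise ValueError("need at least 2 patients to scale variables")
    X = cohort[variables].to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    for name, sd in zip(variables, sds):
        if sd == 0:
            raise ValueError(f"variable {name!r} has zero variance")
    Z = (X - means) / sds
    return Z, ScalingParams(variables=variables, means=means, sds=sds)


def kmeans_fit(
    Z: np.ndarray,
    k: int,
    seed: int = DEFAULT_SEED,
    n_restarts: int = DEFAULT_RESTARTS,
) -> KMeans:
    """Lloyd's k-means with k-means++ seeding, best of ``n_restarts`` by WSS."""
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n (k={k}, n={n})")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        algorithm="lloyd",
        random_state=seed,
    )
    km.fit(Z)
    return km


def wss_curve(
    Z: np.ndarray,
    kmax: int = 10,
    seed: int = DEFAULT_SEED,
    n_restarts: int = DEFAULT_RESTARTS,
) -> np.ndarray:
    """Total within-cluster sum of squares for k = 1..kmax."""
    return np.array(
        [kmeans_fit(Z, k, seed=seed, n_restarts=n_restarts).inertia_
         for k in range(1, kmax + 1)]
    )


def elbow_select(wss: np.ndarray) -> int:
    """Pick k at the elbow of the WSS curve.

    Operationalised as the k maximising the perpendicular distance from
    (k, WSS_k) to the chord joining the curve's endpoints; ties break toward
    the smallest k.  The result is invariant to rescaling the curve by a
    positive constant.
    """
    wss = np.asarray(wss, dtype=float)
    if len(wss) < 3:
        raise ValueError("need a WSS curve over at least k = 1..3")
    if np.any(np.diff(wss) > 1e-9 * max(wss[0], 1.0)):
        warnings.warn("WSS curve is not non-increasing", stacklevel=2)
    ks = np.arange(1, len(wss) + 1, dtype=float)
    x1, y1, x2, y2 = ks[0], wss[0], ks[-1], wss[-1]
    dist = np.abs((y2 - y1) * ks - (x2 - x1) * wss + x2 * y1 - y2 * x1)
    return int(ks[int(np.argmax(dist))])


def label_clusters(centers_raw: np.ndarray) -> dict[int, str]:
    """Attach phenotype labels to k = 3 raw-unit centers (alpha, AxV, AxH).

    balanced: largest AxH; vertical_II: smallest AxV; horizontal_III:
    smallest alpha.  Raises :class:`LabellingAmbiguityError` if the rules
    pick the same cluster twice.
    """
    C = np.asarray(centers_raw, dtype=float)
    if C.shape != (3, 3):
        raise ValueError("labelling requires exactly 3 clusters of 3 variables")
    i_bal = int(np.argmax(C[:, 2]))
    i_vert = int(np.argmin(C[:, 1]))
    i_horiz = int(np.argmin(C[:, 0]))
    if len({i_bal, i_vert, i_horiz}) != 3:
        raise LabellingAmbiguityError(
            f"phenotype rules collide on centers:\n{C}"
        )
    return {i_bal: "balanced", i_vert: "vertical_II", i_horiz: "horizontal_III"}


def cluster_mounting_cohort(
    cohort: pd.DataFrame,
    k: int | None = None,
    kmax: int = 10,
    seed: int = DEFAULT_SEED,
    n_restarts: int = DEFAULT_RESTARTS,
) -> ClusterModel:
    """Full clustering pass: scale, elbow-select k (unless given), fit, label."""
    Z, scaling = scale_variables(cohort)
    curve = wss_curve(Z, kmax=kmax, seed=seed, n_restarts=n_restarts)
    k = k if k is not None else elbow_select(curve)
    km = kmeans_fit(Z, k, seed=seed, n_restarts=n_restarts)
    centers_raw = scaling.inverse(km.cluster_centers_)
    model = ClusterModel(
        k=k,
        centers_scaled=km.cluster_centers_,
        centers_raw=centers_raw,
        assignments=km.labels_.astype(int),
        wss=float(km.inertia_),
        wss_curve=curve,
        scaling=scaling,
        seed=seed,
    )
    if k == 3:
        model.phenotype_labels = label_clusters(centers_raw)
    return model
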