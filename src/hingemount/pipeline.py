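"""End-to-end analysis: filter, cluster, characterise, derive, preset.

`run_full_analysis` wires the stages together the way the planning study is
organised: inclusion filtering of the registry, optional landmark-level
mounting extraction, z-scoring and k-means with elbow selection, phenotype
labelling, cluster statistics (sex association, ANOVA/Tukey variable
selection, Mann-Whitney sex comparisons), Bonwill/Balkwill norm comparison,
and rounded per-phenotype mounting presets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (
    MOUNTING_VARS,
    ClusterModel,
    FilterReport,
    cluster_mounting_cohort,
    filter_registry,
)
from .geometry import MountingValues, derive_articulator_values, round_presets
from .io import RunConfig, config_hash, write_json, write_mounting_csv
from .stats import (
    ClusterSummary,
    anova_tukey,
    bonwill_balkwill_report,
    chi_square_cramers_v,
    mann_whitney,
    select_discriminative_variables,
    summarize_clusters,
)

__all__ = ["ReportBundle", "add_derived_columns", "run_full_analysis"]

_NON_CEPH = {
    "patient_id", "plan_index", "true_cluster", "sex", "age",
    "alpha_deg", "axv_mm", "axh_mm", "ie_ax_mm", "balkwill_deg",
    "excluded_reason", "is_excluded",
}


@dataclass
class ReportBundle:
    """Everything a full analysis run produces."""

    config: RunConfig
    filter_report: FilterReport | None
    cohort: pd.DataFrame
    model: ClusterModel
    summary: ClusterSummary
    sex_association: dict | None
    sex_mounting_tests: dict[str, dict]
    tukey_mounting: dict[str, dict]
    ceph_kept: list[str]
    ceph_excluded: list[str]
    bonwill_balkwill: pd.DataFrame
    presets: dict[str, tuple[int, int, int]]
    log: dict = field(default_factory=dict)


def add_derived_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach per-patient Ie-Ax and Balkwill columns."""
    out = cohort.copy()
    derived = [
        derive_articulator_values(
            MountingValues(r.alpha_deg, max(r.axv_mm, 0.0), r.axh_mm)
        )
        for r in cohort.itertuples()
    ]
    out["ie_ax_mm"] = [d.ie_ax_mm for d in derived]
    out["balkwill_deg"] = [d.balkwill_deg for d in derived]
    return out


def _tukey_summary(groups, alpha):
    res = anova_tukey(groups, alpha=alpha)
    return res, {
        "F": res.f_statistic,
        "anova_p": res.anova_p,
        "pairs": [
            {"pair": list(p), "mean_diff": d, "p_adj": padj}
            for p, d, padj in res.pairs
        ],
        "all_pairs_significant": res.all_pairs_significant,
    }


def run_full_analysis(
    config: RunConfig,
    cohort: pd.DataFrame,
    is_registry: bool = False,
    out_dir: str | Path | None = None,
) -> ReportBundle:
    """Run the whole pipeline on a cohort (or raw registry) table.

    When ``out_dir`` is given, writes ``cohort_mounting.csv``,
    ``cluster_model.json``, ``cluster_summary.csv``, ``phenotype_stats.json``,
    ``bonwill_balkwill.csv``, ``presets.json`` and ``run_log.json``; reruns
    with the same config and input are byte-identical.
    """
    filter_report = None
    if is_registry:
        cohort, filter_report = filter_registry(cohort)
    if len(cohort) == 0:
        raise ValueError("empty cohort: nothing to analyse")
    cohort = add_derived_columns(cohort)

    model = cluster_mounting_cohort(
        cohort, kmax=config.kmax, seed=config.seed, n_restarts=config.n_restarts
    )
    labels = model.phenotype_labels
    assignments = model.assignments

    ceph_vars = [c for c in cohort.columns if c not in _NON_CEPH]
    summary = summarize_clusters(
        cohort, assignments, MOUNTING_VARS + ["age"] * ("age" in cohort) + ceph_vars
    )

    sex_association = None
    sex_tests: dict[str, dict] = {}
    if "sex" in cohort.columns and cohort["sex"].nunique() == 2:
        table = summary.sex_counts[["female", "male"]].to_numpy().T
        cont = chi_square_cramers_v(table)
        sex_association = {
            "observed": cont.observed.tolist(),
            "chi_square": cont.chi_square,
            "df": cont.df,
            "p_value": cont.p_value,
            "cramers_v": cont.cramers_v,
        }
        f = cohort["sex"] == "female"
        for var in (["age"] if "age" in cohort.columns else []) + MOUNTING_VARS:
            r = mann_whitney(cohort.loc[f, var], cohort.loc[~f, var])
            sex_tests[var] = {"U": r.u, "z": r.z, "p_value": r.p_value}

    groups_by_cluster = lambda var: [
        cohort.loc[assignments == c, var].to_numpy()
        for c in sorted(set(assignments))
    ]
    tukey_mounting = {}
    for var in MOUNTING_VARS:
        _, s = _tukey_summary(groups_by_cluster(var), config.alpha_level)
        tukey_mounting[var] = s
    tukey_ceph = {}
    ceph_json = {}
    for var in ceph_vars:
        res, s = _tukey_summary(groups_by_cluster(var), config.alpha_level)
        tukey_ceph[var] = res
        ceph_json[var] = s
    kept, excluded = select_discriminative_variables(
        tukey_ceph, alpha=config.alpha_level
    )

    bb = bonwill_balkwill_report(cohort, assignments, labels)

    presets = {}
    if labels:
        cluster_means = {}
        for c, lab in labels.items():
            sub = cohort.loc[assignments == c]
            cluster_means[lab] = MountingValues(
                float(sub["alpha_deg"].mean()),
                float(sub["axv_mm"].mean()),
                float(sub["axh_mm"].mean()),
            )
        presets = round_presets(cluster_means)

    log = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "n_patients": int(len(cohort)),
        "k_selected": int(model.k),
    }
    if filter_report is not None:
        log["filter_report"] = {
            "n_eligible": filter_report.n_eligible,
            "n_excluded": filter_report.n_excluded,
            "n_duplicate_plans_removed": filter_report.n_duplicate_plans_removed,
            "n_included": filter_report.n_included,
        }

    bundle = ReportBundle(
        config=config,
        filter_report=filter_report,
        cohort=cohort,
        model=model,
        summary=summary,
        sex_association=sex_association,
        sex_mounting_tests=sex_tests,
        tukey_mounting=tukey_mounting,
        ceph_kept=sorted(kept),
        ceph_excluded=sorted(excluded),
        bonwill_balkwill=bb,
        presets=presets,
        log=log,
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir), ceph_json)
    return bundle


def _write_bundle(bundle: ReportBundle, out_dir: Path, ceph_json: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = bundle.cohort.copy()
    cohort["cluster"] = bundle.model.assignments
    cohort["phenotype"] = [
        bundle.model.phenotype_labels.get(int(c), "") for c in bundle.model.assignments
    ]
    write_mounting_csv(cohort, out_dir / "cohort_mounting.csv")
    write_json(bundle.model.to_dict(), out_dir / "cluster_model.json")
    bundle.summary.variables.reset_index().to_csv(
        out_dir / "cluster_summary.csv", index=False
    )
    stats_payload = {
        "sex_association": bundle.sex_association,
        "sex_mounting_tests": bundle.sex_mounting_tests,
        "tukey_mounting": bundle.tukey_mounting,
        "tukey_cephalometric": ceph_json,
        "cephalometric_kept": bundle.ceph_kept,
        "cephalometric_excluded": bundle.ceph_excluded,
    }
    write_json(stats_payload, out_dir / "phenotype_stats.json")
    bundle.bonwill_balkwill.to_csv(out_dir / "bonwill_balkwill.csv", index=False)
    write_json(
        {lab: list(p) for lab, p in bundle.presets.items()}, out_dir / "presets.json"
    )
    write_json(bundle.log, out_dir / "run_log.json")
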