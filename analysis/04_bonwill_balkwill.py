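#!/usr/bin/env python
"""Compare the per-cluster Ie-Ax distance and Balkwill angle to the
articulator norms (Bonwill arm 101.6 mm, Balkwill range 18-25 deg).

Reads the clustered cohort (runs 01 and 02 first), writes
results/bonwill_balkwill.csv and prints the table with in/out-of-norm flags.
"""

import json
from pathlib import Path

import pandas as pd

from hingemount.pipeline import add_derived_columns
from hingemount.stats import bonwill_balkwill_report

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = add_derived_columns(pd.read_csv(OUT / "cohort.csv"))
    model = json.loads((OUT / "cluster_model.json").read_text(encoding="utf-8"))
    assignments = model["assignments"]
    labels = {int(k): v for k, v in model["phenotype_labels"].items()}

    report = bonwill_balkwill_report(cohort, assignments, labels)
    report.to_csv(OUT / "bonwill_balkwill.csv", index=False)
    for _, row in report.iterrows():
        print(
            f"{row['phenotype']:>14s} (n={row['n']:3d}): "
            f"Ie-Ax {row['ie_ax_mean']:6.1f} +- {row['ie_ax_sd']:.1f} mm "
            f"(norm {row['ie_ax_norm_mm']}, dev {row['ie_ax_dev_from_norm']:+5.1f}); "
            f"Balkwill {row['balkwill_mean']:5.1f} +- {row['balkwill_sd']:.1f} deg "
            f"[{row['balkwill_flag']}]"
        )


if __name__ == "__main__":
    main()
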