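#!/usr/bin/env python
"""Round the cluster means to integer mounting presets and emit the 3D
mounting scene (rigid transform + hinge-axis line) for each phenotype.

Reads results/cluster_model.json, writes results/presets.json and
results/mounting_scenes.json.
"""

import json
from pathlib import Path

from hingemount.geometry import MountingValues, round_presets
from hingemount.io import write_json
from hingemount.mounting3d import build_mounting_transform

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    model = json.loads((OUT / "cluster_model.json").read_text(encoding="utf-8"))
    labels = {int(k): v for k, v in model["phenotype_labels"].items()}
    centers = model["centers_raw"]

    means = {
        labels[i]: MountingValues(*centers[i]) for i in range(len(centers))
    }
    presets = round_presets(means)
    write_json({k: list(v) for k, v in presets.items()}, OUT / "presets.json")

    scenes = {}
    for label, (alpha, axv, axh) in presets.items():
        scene = build_mounting_transform(MountingValues(alpha, axv, axh))
        scenes[label] = {
            "preset": [alpha, axv, axh],
            "transform": [float(v) for v in scene.transform.flatten()],
            "hinge_axis_point": scene.hinge_axis_point.tolist(),
            "hinge_axis_direction": scene.hinge_axis_direction.tolist(),
        }
        print(
            f"{label:>14s}: alpha {alpha:3d} deg, AxV {axv:3d} mm, AxH {axh:3d} mm; "
            f"hinge axis through ({scene.hinge_axis_point[0]:.1f}, "
            f"{scene.hinge_axis_point[1]:.1f}, {scene.hinge_axis_point[2]:.1f}) mm"
        )
    write_json(scenes, OUT / "mounting_scenes.json")


if __name__ == "__main__":
    main()
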