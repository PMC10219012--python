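"""Readers/writers and run configuration.

CSV dialect: comma-separated, UTF-8, '.' decimal, header required.
Landmark coordinates follow the 2D convention x anterior-positive,
y superior-positive (right-lateral view); degrees and mm as stated per
column header.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from .geometry import CephLandmarks, FacebowSpec

__all__ = [
    "RunConfig",
    "load_facebow",
    "save_facebow",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "write_mounting_csv",
    "write_json",
    "config_hash",
]

LANDMARK_NAMES = ("Pi", "Ns", "Ie", "Dc", "Ref0", "Ref1")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full analysis run."""

    facebow_path: str | None = None
    kmax: int = 10
    seed: int = 20230521
    n_restarts: int = 25
    alpha_level: float = 0.05
    out_dir: str = "results"
    verbosity: int = 1

    def __post_init__(self):
        if self.kmax < 3:
            raise ValueError("kmax must be >= 3")


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def load_facebow(path: str | Path) -> FacebowSpec:
    """Read a facebow spec from YAML or JSON keyed d_ns_mm / ax_offset_*_mm."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return FacebowSpec(
        d_ns_mm=float(data["d_ns_mm"]),
        ax_offset_along_mm=float(data.get("ax_offset_along_mm", 0.0)),
        ax_offset_perp_mm=float(data.get("ax_offset_perp_mm", 0.0)),
    )


def save_facebow(spec: FacebowSpec, path: str | Path) -> None:
    path = Path(path)
    data = {
        "d_ns_mm": spec.d_ns_mm,
        "ax_offset_along_mm": spec.ax_offset_along_mm,
        "ax_offset_perp_mm": spec.ax_offset_perp_mm,
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


def read_landmarks_csv(
    path: str | Path, ref_distance_mm: float
) -> dict[str, CephLandmarks]:
    """Read per-patient landmarks from a long-format CSV.

    Columns: patient_id, landmark, x, y; the scaling pair's physical span is
    the sidecar ``ref_distance_mm``.  Coordinates are taken as raw (pixel)
    values; calibrate before measuring.
    """
    df = pd.read_csv(path)
    required = {"patient_id", "landmark", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"landmark CSV requires columns {sorted(required)}")
    out: dict[str, CephLandmarks] = {}
    for pid, grp in df.groupby("patient_id", sort=False):
        pts = {row["landmark"]: (row["x"], row["y"]) for _, row in grp.iterrows()}
        missing = [n for n in LANDMARK_NAMES if n not in pts]
        if missing:
            raise ValueError(f"patient {pid}: missing landmarks {missing}")
        out[str(pid)] = CephLandmarks(
            **{n: pts[n] for n in LANDMARK_NAMES},
            ref_distance_mm=ref_distance_mm,
            calibrated=False,
        )
    return out


def write_landmarks_csv(
    landmarks: dict[str, CephLandmarks], path: str | Path
) -> None:
    rows = [
        {"patient_id": pid, "landmark": name, "x": p[0], "y": p[1]}
        for pid, lm in landmarks.items()
        for name, p in lm.points().items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_mounting_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-patient mounting table (alpha/AxV/AxH plus derived)."""
    cols = [
        "patient_id",
        "alpha_deg",
        "axv_mm",
        "axh_mm",
        "ie_ax_mm",
        "balkwill_deg",
    ]
    table[[c for c in cols if c in table.columns]].to_csv(path, index=False)


def write_json(data: dict, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).write_text(
        json.dumps(data, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )
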