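"""Readers/writers, coordinate transposition and pipeline orchestration.

File conventions: CSV tables with headers, times in seconds, durations in
milliseconds, pixel coordinates 0-based from the top-left corner. Dense
arrays (attention maps, feature stacks) are stored as ``.npy`` files with
a JSON sidecar describing shape, dtype and provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import DisplaySpec, Trajectory
from .maps import AttentionMap, FixationSet

__all__ = [
    "FIXATION_COLUMNS",
    "TRAJECTORY_COLUMNS",
    "RecordFormatError",
    "load_records",
    "save_records",
    "transpose_to_analysis_space",
    "save_map",
    "load_map",
    "config_hash",
    "run_pipeline",
]

FIXATION_COLUMNS = ["subject_id", "image_id", "t_s", "x_px", "y_px",
                    "duration_ms"]
TRAJECTORY_COLUMNS = ["subject_id", "image_id", "t_s", "x_px", "y_px"]


class RecordFormatError(ValueError):
    """Malformed record file."""


def save_records(records: list[FixationSet | Trajectory], path: Path) -> None:
    """Write fixation sets or trajectories to a single CSV."""
    rows = []
    for rec in records:
        if isinstance(rec, FixationSet):
            for i in range(len(rec)):
                rows.append((rec.subject_id, rec.image_id,
                             rec.onsets_s[i], rec.xs[i], rec.ys[i],
                             rec.durations_ms[i]))
        else:
            for i in range(len(rec)):
                rows.append((rec.subject_id, rec.image_id,
                             rec.sample_times[i], rec.xs[i], rec.ys[i],
                             np.nan))
    pd.DataFrame(rows, columns=FIXATION_COLUMNS).to_csv(path, index=False)


def load_records(path: Path, kind: str) -> list[FixationSet | Trajectory]:
    """Load fixation sets (``kind='fixations'``) or trajectories
    (``kind='trajectory'``) from CSV, one record per (subject, image).

    Rows must carry strictly increasing timestamps within each record;
    violations are rejected with the offending row number.
    """
    if kind not in ("fixations", "trajectory"):
        raise ValueError("kind must be 'fixations' or 'trajectory'")
    need = FIXATION_COLUMNS if kind == "fixations" else TRAJECTORY_COLUMNS
    df = pd.read_csv(path)
    missing = set(need) - set(df.columns)
    if missing:
        raise RecordFormatError(f"{path}: missing columns {sorted(missing)}")
    for col in ("t_s", "x_px", "y_px"):
        bad = df.index[~np.isfinite(df[col].to_numpy(dtype=float))]
        if len(bad):
            raise RecordFormatError(
                f"{path}: non-numeric {col} at row {bad[0] + 2}")
    out: list[FixationSet | Trajectory] = []
    for (sid, iid), g in df.groupby(["subject_id", "image_id"], sort=False):
        t = g["t_s"].to_numpy(dtype=float)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            row = int(g.index[np.argmax(np.diff(t) <= 0) + 1]) + 2
            raise RecordFormatError(
                f"{path}: non-monotone timestamps for ({sid}, {iid}) "
                f"at row {row}")
        if kind == "fixations":
            out.append(FixationSet(
                g["x_px"].to_numpy(float), g["y_px"].to_numpy(float),
                t, g["duration_ms"].to_numpy(float),
                subject_id=str(sid), image_id=str(iid)))
        else:
            out.append(Trajectory(
                t, g["x_px"].to_numpy(float), g["y_px"].to_numpy(float),
                subject_id=str(sid), image_id=str(iid)))
    return out


def transpose_to_analysis_space(record: FixationSet | Trajectory,
                                source_size: tuple[int, int],
                                analysis_raster: tuple[int, int]
                                ) -> FixationSet | Trajectory:
    """Affinely map device coordinates into the analysis raster.

    The source frame (width, height) is scaled uniformly to the largest
    size that fits the analysis raster (height, width) and centered — the
    same maximize-and-letterbox rule used to present the pictures. Aspect
    ratio is preserved; the frame center maps to the raster center.
    """
    sw, sh = source_size
    ah, aw = analysis_raster
    scale = min(aw / sw, ah / sh)
    ox = (aw - sw * scale) / 2.0
    oy = (ah - sh * scale) / 2.0

    def fx(x: np.ndarray) -> np.ndarray:
        return x * scale + ox

    def fy(y: np.ndarray) -> np.ndarray:
        return y * scale + oy

    if isinstance(record, FixationSet):
        return FixationSet(fx(record.xs), fy(record.ys), record.onsets_s,
                           record.durations_ms, subject_id=record.subject_id,
                           image_id=record.image_id, method=record.method)
    return Trajectory(record.sample_times, fx(record.xs), fy(record.ys),
                      display=record.display, subject_id=record.subject_id,
                      image_id=record.image_id,
                      under_threshold=record.under_threshold)


def save_map(amap: AttentionMap, path: Path) -> None:
    """Write an attention map as .npy plus a JSON sidecar."""
    path = Path(path)
    np.save(path, amap.grid)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "shape": list(amap.grid.shape), "dtype": str(amap.grid.dtype),
        "n_subjects": amap.n_subjects, "method": amap.method,
        "image_id": amap.image_id, "constant": amap.constant,
    }, indent=2))


def load_map(path: Path) -> AttentionMap:
    path = Path(path)
    grid = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return AttentionMap(grid, n_subjects=meta["n_subjects"],
                        method=meta["method"], image_id=meta["image_id"],
                        constant=meta["constant"])


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def export_heatmap_png(amap: AttentionMap, path: Path) -> None:
    """8-bit grayscale PNG export of a map, for visual inspection."""
    from PIL import Image

    img = (np.clip(amap.grid, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(img).save(path)


def run_pipeline(config: dict, out_dir: Path, seed: int = 0) -> dict:
    """Simulate a scenario and run maps -> reliability -> scores over it.

    ``config`` keys (all optional): raster [h, w], n_scenes, mode,
    bandwidth_px, profiles (list of {name, n_subjects, eyes_preference,
    lateral_bias}). Outputs a results tree with per-image group maps,
    reliability CSV, score CSV and a provenance sidecar; returns a summary
    dict. An empty config produces an empty-but-valid results tree.
    """
    from . import clinical, reliability, synth

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = {"seed": seed, "config_hash": config_hash(config),
                  "config": config}
    summary: dict = {"images": [], "statistics": []}

    n_scenes = int(config.get("n_scenes", 0))
    if n_scenes > 0:
        raster = tuple(config.get("raster", [128, 160]))
        bandwidth = float(config.get("bandwidth_px",
                                     30.0 * raster[1] / 1280.0))
        mode = config.get("mode", "digit")
        profiles = []
        for p in config.get("profiles", [{"name": "neurotypical",
                                          "n_subjects": 5}]):
            prefs = dict(synth.NEUROTYPICAL.role_preferences)
            if "eyes_preference" in p:
                prefs["eyes"] = float(p["eyes_preference"])
            profiles.append(synth.PopulationProfile(
                name=p.get("name", "group"),
                role_preferences=prefs,
                lateral_bias=p.get("lateral_bias"),
                n_subjects=int(p.get("n_subjects", 5))))
        rng = np.random.default_rng(seed)
        scenes = [synth.make_scene(raster, seed=rng.integers(2 ** 31),
                                   image_id=f"img{j:03d}")
                  for j in range(n_scenes)]
        cfg = synth.ExplorerConfig(mode=mode)
        ds = synth.make_population(profiles, scenes, cfg, seed=rng)
        maps = synth.maps_for_dataset(ds, bandwidth_px=bandwidth)

        from .maps import group_map
        stats_rows = []
        for iid, by_subject in maps.items():
            summary["images"].append(iid)
            gmap = group_map(list(by_subject.values()))
            save_map(gmap, out_dir / f"group_{iid}.npy")
            if len(by_subject) >= 2:
                isc = reliability.inter_subject_correlation(
                    list(by_subject.values()))
                stats_rows.append((iid, mode, "isc", isc))
        pd.DataFrame(stats_rows,
                     columns=["image_id", "method", "statistic", "value"]
                     ).to_csv(out_dir / "reliability.csv", index=False)
        summary["statistics"] = stats_rows
        save_records(ds.records, out_dir / "records.csv")

    (out_dir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, default=str))
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, default=str))
    return summary
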