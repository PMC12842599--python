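"""End-to-end orchestration: file-based runs and quality-detection pairing.

The pipeline stages mirror the analysis workflow: quality scoring of every
image variant, Q-index construction, per-image detection scoring, mixed-set
construction, and finally the pairing of quality with detection outcomes.
Every stage writes plain CSV/JSON artifacts so downstream figures can be
rendered from the exported tables, and every artifact is re-derivable from
the intermediate files (no hidden state).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from uweval import det_io, iqa, mixedset, perimage, qindex

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_variant_images",
    "run_quality",
    "run_detection_eval",
    "quality_detection_pairs",
    "run_all",
]


@dataclass
class RunConfig:
    """Configuration of a file-based run.

    ``root`` must contain the manifest (default ``manifest.yaml``) whose
    variant entries name detection files and, optionally, per-variant image
    directories laid out as ``<variant_name>/<image_id>.<ext>``.
    """

    root: Path
    out_dir: Path
    manifest: str = "manifest.yaml"
    weights: tuple[float, float, float, float] | None = None
    n_bins: int = 10
    perturbation: float = 0.25
    interpolation: str = "coco101"
    seed: int = 0

    def __post_init__(self) -> None:
        self.root = Path(self.root)
        self.out_dir = Path(self.out_dir)
        if not self.root.exists():
            raise FileNotFoundError(f"run root {self.root} does not exist")


_IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg")


def load_variant_images(root: Path, manifest: dict):
    """Yield ``(image_id, variant_id, image, variant_name)`` from image dirs."""
    from PIL import Image

    for entry in manifest["variants"]:
        subdir = entry.get("images")
        if subdir is None:
            continue
        directory = Path(root) / subdir
        if not directory.is_dir():
            raise FileNotFoundError(f"variant image directory {directory} does not exist")
        for path in sorted(directory.iterdir()):
            if path.suffix.lower() not in _IMAGE_EXTENSIONS:
                continue
            with Image.open(path) as img:
                arr = np.asarray(img.convert("RGB"))
            yield path.stem, int(entry["variant_id"]), arr, entry["name"]


def run_quality(config: RunConfig):
    """Quality stage: metrics, Q-index, deltas, sensitivity and bins.

    Writes ``quality.csv``, ``quality_summary.csv``, ``qindex.csv``,
    ``delta_qindex.csv``, ``sensitivity.csv``, ``bins.csv`` and returns the
    in-memory table alongside the artifact paths.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)
    manifest = det_io.read_manifest(config.root / config.manifest)
    records, summary, errors = iqa.score_collection(load_variant_images(config.root, manifest))
    for image_id, variant_id, message in errors:
        logger.warning("skipped image %s variant %s: %s", image_id, variant_id, message)

    raw = pd.DataFrame(
        {
            "image_id": [r.image_id for r in records],
            "variant_id": [r.variant_id for r in records],
            "variant_name": [r.variant_name for r in records],
            **{m: [getattr(r, m) for r in records] for m in qindex.METRICS},
        }
    )
    paths = {"quality": config.out_dir / "quality.csv", "summary": config.out_dir / "quality_summary.csv"}
    raw.to_csv(paths["quality"], index=False)
    summary.to_csv(paths["summary"])

    table = qindex.build_qindex_table(records, config.weights)
    outlier_counts = {}
    for _, _, metric in table.excluded:
        outlier_counts[metric] = outlier_counts.get(metric, 0) + 1
    logger.info("outliers removed per metric: %s", outlier_counts or "none")

    paths["qindex"] = config.out_dir / "qindex.csv"
    table.records.to_csv(paths["qindex"], index=False)

    single_variant = table.records["variant_id"].nunique() < 2 or not (
        (table.records["variant_id"] == 0).any() and (table.records["variant_id"] > 0).any()
    )
    deltas = (
        pd.DataFrame(columns=["image_id", "variant_id", "variant_name", "delta"])
        if single_variant
        else qindex.delta_qindex(table)
    )
    paths["delta"] = config.out_dir / "delta_qindex.csv"
    deltas.to_csv(paths["delta"], index=False)

    sensitivity = qindex.weight_sensitivity(table, config.perturbation)
    paths["sensitivity"] = config.out_dir / "sensitivity.csv"
    sensitivity.to_csv(paths["sensitivity"], index=False)

    bins = qindex.bin_by_quality(table, config.n_bins)
    paths["bins"] = config.out_dir / "bins.csv"
    bins.to_csv(paths["bins"], index=False)

    dist = qindex.distribution_summary(table)
    paths["distribution"] = config.out_dir / "distribution_summary.csv"
    dist.to_csv(paths["distribution"], index=False)

    return {"table": table, "deltas": deltas, "summary": summary, "outliers": outlier_counts, "paths": paths}


def run_detection_eval(config: RunConfig):
    """Detection stage: score matrix, mixed set, comparison and composition."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    manifest = det_io.read_manifest(config.root / config.manifest)
    gt = det_io.read_ground_truth(config.root / manifest["ground_truth"])
    det_sets = [
        det_io.read_detections(
            config.root / entry["detections"], entry["variant_id"], gt, variant_name=entry["name"]
        )
        for entry in manifest["variants"]
    ]
    matrix = perimage.score_matrix(det_sets, gt, config.interpolation)
    if matrix.undefined_images:
        logger.info("images without ground truth (excluded from means): %s", matrix.undefined_images)

    selection = mixedset.build_mixed_set(matrix)
    comparison = mixedset.compare_sets(matrix, selection)
    composition = mixedset.composition_stats(selection)

    paths = {
        "matrix": config.out_dir / "score_matrix.csv",
        "selection": config.out_dir / "mixed_selection.csv",
        "comparison": config.out_dir / "comparison.csv",
        "composition": config.out_dir / "composition.json",
    }
    matrix.values.to_csv(paths["matrix"])
    pd.DataFrame(
        {"image_id": list(selection.selections), "variant_id": list(selection.selections.values())}
    ).to_csv(paths["selection"], index=False)
    comparison.to_csv(paths["comparison"], index=False)
    with open(paths["composition"], "w") as fh:
        json.dump(
            {
                "fractions": {str(k): v for k, v in composition["fractions"].items()},
                "original_plurality": composition["original_plurality"],
                "mixed_mean": selection.mixed_mean,
                "n_images": selection.n_images,
            },
            fh,
            indent=2,
        )
    return {"matrix": matrix, "selection": selection, "comparison": comparison,
            "composition": composition, "paths": paths}


def _safe_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(Pearson, Spearman), NaN with a warning for degenerate variance."""
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("correlation undefined: fewer than 2 points or zero variance", stacklevel=2)
        return float("nan"), float("nan")
    return float(stats.pearsonr(x, y)[0]), float(stats.spearmanr(x, y)[0])


def quality_detection_pairs(table: qindex.QIndexTable, matrix: perimage.ScoreMatrix,
                            n_bins: int = 10):
    """Pair quality with detection outcomes at variant and image level.

    Returns a dict with:

    * ``variant_pairs`` — per variant, the mean of each rescaled metric and
      the mean per-image mAP, plus descriptive Pearson/Spearman coefficients
      between each metric mean and the mAP means across variants;
    * ``image_pairs`` — per image, the original's qindex, per-image mAP of
      the original, the best enhanced mAP and the delta;
    * ``improvement_by_bin`` — per original-quality bin, the fraction of
      images whose best enhanced variant beats the original (the
      improvement-frequency stratification).

    Correlations are descriptive only; no significance testing is attached.
    """
    df = table.records
    if "qindex" not in df.columns:
        raise ValueError("qindex not computed")
    values = matrix.values if isinstance(matrix, perimage.ScoreMatrix) else matrix
    # image ids in the quality table are strings when they came from files
    values = values.copy()
    values.index = values.index.map(str)
    q_by_key = df.set_index(["image_id", "variant_id"])

    shared = sorted(set(values.index) & set(df["image_id"].astype(str)))
    if not shared:
        raise ValueError("quality table and score matrix share no image ids")

    variant_rows = []
    for variant_id in values.columns:
        mean_map = float(np.nanmean(values[variant_id].to_numpy(dtype=float)))
        sub = df[df["variant_id"] == variant_id]
        row = {"variant_id": variant_id, "mean_map5095": mean_map}
        for m in qindex.METRICS + ("qindex",):
            row[f"mean_{m}"] = float(sub[m].mean()) if len(sub) else float("nan")
        variant_rows.append(row)
    variant_pairs = pd.DataFrame(variant_rows)

    correlations = {}
    maps = variant_pairs["mean_map5095"].to_numpy()
    for m in qindex.METRICS + ("qindex",):
        x = variant_pairs[f"mean_{m}"].to_numpy()
        ok = ~np.isnan(x) & ~np.isnan(maps)
        pear, spear = _safe_corr(x[ok], maps[ok])
        correlations[m] = {"pearson": pear, "spearman": spear}

    image_rows = []
    original_col = values.columns[0]
    enhanced_cols = [c for c in values.columns if c != original_col]
    for image_id in shared:
        try:
            q0 = float(q_by_key.loc[(image_id, 0), "qindex"])
        except KeyError:
            continue
        map0 = float(values.at[image_id, original_col])
        if np.isnan(map0):
            continue
        best_enh = float(np.nanmax(values.loc[image_id, enhanced_cols])) if enhanced_cols else float("nan")
        image_rows.append(
            {
                "image_id": image_id,
                "qindex_original": q0,
                "map_original": map0,
                "map_best_enhanced": best_enh,
                "delta_map": best_enh - map0 if enhanced_cols else float("nan"),
                "improved": bool(enhanced_cols) and best_enh > map0,
            }
        )
    image_pairs = pd.DataFrame(image_rows)

    if len(image_pairs):
        bin_idx = np.minimum((image_pairs["qindex_original"].to_numpy() * n_bins).astype(int), n_bins - 1)
        image_pairs["bin"] = bin_idx
        improvement_by_bin = (
            image_pairs.groupby("bin")["improved"].agg(["mean", "count"])
            .rename(columns={"mean": "improvement_fraction", "count": "n_images"})
            .reindex(range(n_bins), fill_value=0)
        )
        improvement_by_bin["improvement_fraction"] = improvement_by_bin["improvement_fraction"].astype(float)
    else:
        improvement_by_bin = pd.DataFrame(columns=["improvement_fraction", "n_images"])

    return {
        "variant_pairs": variant_pairs,
        "correlations": correlations,
        "image_pairs": image_pairs,
        "improvement_by_bin": improvement_by_bin,
    }


def run_all(config: RunConfig):
    """Quality stage, detection stage and the quality-detection pairing."""
    quality = run_quality(config)
    detection = run_detection_eval(config)
    pairs = quality_detection_pairs(quality["table"], detection["matrix"], config.n_bins)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    pairs["variant_pairs"].to_csv(config.out_dir / "variant_pairs.csv", index=False)
    pairs["image_pairs"].to_csv(config.out_dir / "image_pairs.csv", index=False)
    pairs["improvement_by_bin"].to_csv(config.out_dir / "improvement_by_bin.csv")
    with open(config.out_dir / "correlations.json", "w") as fh:
        json.dump(pairs["correlations"], fh, indent=2)
    return {"quality": quality, "detection": detection, "pairs": pairs}
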