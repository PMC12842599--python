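"""Mixed-set oracle upper bound for selective enhancement.

For each image n with per-image scores mAP_{n,v} over the original (v = 0)
and V enhanced variants, the mixed set keeps the best-scoring version::

    v*_n = argmax_v mAP_{n,v}
    S_mix = {(n, v*_n)}
    mean mAP_mix = (1/N) sum_n mAP_{n, v*_n}

Ties are broken in favor of the original and then the lowest variant index:
enhancement is an intervention, applied only when it strictly helps. Rows
whose per-image score is undefined (no ground truth) are excluded from N.

The mixed mean dominates every single-variant column mean by construction;
the gap quantifies what a perfect per-image enhancement selector could
recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from uweval.perimage import ScoreMatrix

__all__ = [
    "MixedSelection",
    "select_best_variant",
    "build_mixed_set",
    "composition_stats",
    "compare_sets",
    "relative_improvement",
]


@dataclass
class MixedSelection:
    """Per-image best-variant choices and the resulting mixed-set statistics.

    ``selections`` maps image_id to the chosen variant v*; ``mixed_mean`` is
    the mean per-image mAP of the mixed set over the N images with defined
    scores; ``composition`` gives the fraction of images drawn from each
    variant (sums to 1).
    """

    selections: dict[int, int]
    mixed_mean: float
    composition: dict[int, float]
    n_images: int
    excluded_images: list[int]


def select_best_variant(row) -> int:
    """Index of the maximum score in a per-image row of variant scores.

    Ties prefer the original (position 0), then the lowest index. NaN entries
    are ignored; a row of all-NaN raises.
    """
    values = np.asarray(row, dtype=float)
    if values.size == 0 or np.all(np.isnan(values)):
        raise ValueError("select_best_variant needs at least one defined score")
    best = np.nanmax(values)
    for idx, v in enumerate(values):
        if not math.isnan(v) and v == best:
            return idx
    raise AssertionError("unreachable")  # pragma: no cover


def build_mixed_set(matrix: ScoreMatrix | pd.DataFrame) -> MixedSelection:
    """Build the mixed set from a per-image score matrix.

    Accepts a :class:`~uweval.perimage.ScoreMatrix` or a plain DataFrame
    (rows = images, columns = variant ids, column 0 = original). Rows with no
    defined score are excluded and listed in ``excluded_images``.
    """
    values = matrix.values if isinstance(matrix, ScoreMatrix) else matrix
    if isinstance(values, np.ndarray):
        values = pd.DataFrame(values)
    if values.shape[0] == 0 or values.shape[1] == 0:
        raise ValueError("score matrix is empty")
    variant_ids = list(values.columns)
    selections: dict[int, int] = {}
    chosen_scores: list[float] = []
    excluded: list[int] = []
    for image_id, row in values.iterrows():
        arr = row.to_numpy(dtype=float)
        if np.all(np.isnan(arr)):
            excluded.append(image_id)
            continue
        pos = select_best_variant(arr)
        selections[image_id] = variant_ids[pos]
        chosen_scores.append(float(arr[pos]))
    if not selections:
        raise ValueError("no image has a defined per-image score")
    counts = {v: 0 for v in variant_ids}
    for v in selections.values():
        counts[v] += 1
    n = len(selections)
    composition = {v: c / n for v, c in counts.items()}
    return MixedSelection(
        selections=selections,
        mixed_mean=float(np.mean(chosen_scores)),
        composition=composition,
        n_images=n,
        excluded_images=excluded,
    )


def composition_stats(selection: MixedSelection) -> dict:
    """Composition fractions plus whether the original is the plurality source."""
    if selection.n_images == 0:
        raise ValueError("empty selection")
    fractions = dict(selection.composition)
    best = max(fractions.values())
    original_share = fractions.get(0, 0.0)
    return {
        "fractions": fractions,
        "original_plurality": bool(original_share == best),
        "original_fraction": original_share,
    }


def relative_improvement(original_mean: float, mixed_mean: float):
    """(mixed - original) / original * 100, or None when the baseline is 0."""
    if original_mean == 0:
        return None
    return (mixed_mean - original_mean) / original_mean * 100.0


def compare_sets(matrix: ScoreMatrix | pd.DataFrame, selection: MixedSelection) -> pd.DataFrame:
    """Comparison table of original, per-variant and mixed set means.

    One row per set with the mean per-image mAP (over images with defined
    scores), plus the absolute and relative improvement of the mixed set over
    the original column. The relative improvement is reported at full
    precision and integer-rounded; it is undefined (NaN) when the original
    mean is 0.
    """
    values = matrix.values if isinstance(matrix, ScoreMatrix) else matrix
    if isinstance(values, np.ndarray):
        values = pd.DataFrame(values)
    rows = []
    original_mean = float(np.nanmean(values[values.columns[0]].to_numpy(dtype=float)))
    for variant in values.columns:
        mean = float(np.nanmean(values[variant].to_numpy(dtype=float)))
        rows.append({"set": "original" if variant == values.columns[0] else f"variant_{variant}",
                     "variant_id": variant, "mean_map5095": mean})
    rel = relative_improvement(original_mean, selection.mixed_mean)
    rows.append(
        {
            "set": "mixed",
            "variant_id": -1,
            "mean_map5095": selection.mixed_mean,
            "abs_improvement": selection.mixed_mean - original_mean,
            "rel_improvement_pct": float("nan") if rel is None else rel,
            "rel_improvement_pct_rounded": float("nan") if rel is None else float(round(rel)),
        }
    )
    return pd.DataFrame(rows)
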