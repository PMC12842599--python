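"""Composite Q-index construction from raw quality records.

The Q-index turns the four raw metric scales into a single bounded indicator
per (image, variant) pair. It is an analytical tool for distribution-level
reasoning — not a new perceptual quality metric — and is built in exactly
three steps:

1. **outlier removal** — per metric, pooled over all variants, values more
   than three scaled MADs from the median are dropped;
2. **global rescaling** — min-max normalization of each metric with bounds
   taken jointly over all variants (original included), outliers excluded;
3. **equal-weight aggregation** — the four rescaled metrics are averaged
   (weights configurable, default equal).

ΔQ-index of an enhanced variant is its Q-index minus the Q-index of the
original variant of the same image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from uweval.iqa import QualityRecord

__all__ = [
    "METRICS",
    "MAD_SCALE",
    "MAD_THRESHOLD",
    "QIndexTable",
    "remove_outliers",
    "global_rescale",
    "aggregate_qindex",
    "build_qindex_table",
    "delta_qindex",
    "weight_sensitivity",
    "bin_by_quality",
    "distribution_summary",
]

#: Metric column order used throughout the pipeline.
METRICS = ("uiqm", "uciqe", "ccf", "entropy")
#: Consistency constant making the MAD an estimator of the normal sigma.
MAD_SCALE = 1.4826
#: Number of scaled MADs beyond which a value is an outlier.
MAD_THRESHOLD = 3.0


@dataclass
class QIndexTable:
    """Rescaled metrics and Q-index values for a collection of records.

    Attributes
    ----------
    records : pandas.DataFrame
        One row per retained (image, variant) pair with columns ``image_id``,
        ``variant_id``, the four rescaled metric columns (values in [0, 1])
        and, once aggregated, ``qindex``.
    weights : dict
        Aggregation weights per metric; nonnegative, summing to 1.
    rescale_bounds : dict
        Per-metric ``(min, max)`` used for normalization; allows rescaling
        held-out values later.
    excluded : list of (image_id, variant_id, metric)
        Values removed as outliers. A record losing any metric is dropped
        from aggregation entirely (no imputation) and appears here.
    """

    records: pd.DataFrame
    weights: dict[str, float]
    rescale_bounds: dict[str, tuple[float, float]]
    excluded: list[tuple[str, int, str]] = field(default_factory=list)

    def rescale_value(self, metric: str, value: float, clip: bool = True) -> float:
        """Rescale a held-out raw value with the stored bounds."""
        lo, hi = self.rescale_bounds[metric]
        out = (value - lo) / (hi - lo)
        return float(np.clip(out, 0.0, 1.0)) if clip else float(out)


class DegenerateScaleError(ValueError):
    """A metric had max == min over the pooled collection; rescaling is undefined."""


class MissingBaselineError(ValueError):
    """Enhanced records lack a variant-0 original for some image ids."""


def _normalize_weights(weights) -> dict[str, float]:
    if weights is None:
        return {m: 0.25 for m in METRICS}
    if isinstance(weights, dict):
        vec = [float(weights[m]) for m in METRICS]
    else:
        vec = [float(w) for w in weights]
        if len(vec) != 4:
            raise ValueError("weights must have exactly four entries")
    if any(w < 0 for w in vec):
        raise ValueError(f"weights must be nonnegative, got {vec}")
    total = sum(vec)
    if total <= 0:
        raise ValueError("weights must not all be zero")
    return {m: w / total for m, w in zip(METRICS, vec)}


def remove_outliers(values) -> tuple[np.ndarray, np.ndarray]:
    """Flag values more than three scaled MADs from the median.

    A value ``x`` is removed when ``|x - median| > 3 * 1.4826 * MAD`` with
    ``MAD = median(|x - median|)``. The median itself always survives, so the
    kept set is never empty.

    Returns ``(kept_values, removed_mask)`` with the mask aligned to the
    input order (``True`` = removed).
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("remove_outliers requires at least one value")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    removed = np.abs(x - med) > MAD_THRESHOLD * MAD_SCALE * mad
    return x[~removed], removed


def global_rescale(records: list[QualityRecord]) -> QIndexTable:
    """Steps 1-2: pooled outlier removal, then global min-max rescaling.

    Outliers are flagged per metric over the pooled set of all variants; the
    min/max bounds are then taken over the surviving values only, jointly
    across original and enhanced variants. Records that lost any metric are
    dropped (listed in ``excluded``) rather than imputed.
    """
    if not records:
        raise ValueError("global_rescale requires at least one record")
    df = pd.DataFrame(
        {
            "image_id": [r.image_id for r in records],
            "variant_id": [r.variant_id for r in records],
            "variant_name": [r.variant_name for r in records],
            **{m: [getattr(r, m) for r in records] for m in METRICS},
        }
    )
    excluded: list[tuple[str, int, str]] = []
    keep = np.ones(len(df), dtype=bool)
    bounds: dict[str, tuple[float, float]] = {}
    for metric in METRICS:
        kept_vals, removed = remove_outliers(df[metric].to_numpy())
        if kept_vals.size < 2:
            raise ValueError(f"need at least 2 surviving values to rescale {metric!r}")
        lo, hi = float(kept_vals.min()), float(kept_vals.max())
        if hi <= lo:
            raise DegenerateScaleError(
                f"metric {metric!r} is constant (min == max == {lo}); "
                "min-max rescaling is undefined"
            )
        bounds[metric] = (lo, hi)
        for i in np.flatnonzero(removed):
            excluded.append((df.at[i, "image_id"], int(df.at[i, "variant_id"]), metric))
        keep &= ~removed
    out = df[keep].reset_index(drop=True).copy()
    for metric in METRICS:
        lo, hi = bounds[metric]
        out[metric] = (out[metric] - lo) / (hi - lo)
    return QIndexTable(records=out, weights=_normalize_weights(None), rescale_bounds=bounds, excluded=excluded)


def aggregate_qindex(table: QIndexTable, weights=None) -> QIndexTable:
    """Step 3: weighted aggregation of the rescaled metrics into ``qindex``.

    Weights default to equal (0.25 each) and are normalized internally to sum
    to 1; negative weights are rejected.
    """
    w = _normalize_weights(weights)
    records = table.records.copy()
    records["qindex"] = sum(w[m] * records[m] for m in METRICS)
    return QIndexTable(
        records=records, weights=w, rescale_bounds=dict(table.rescale_bounds), excluded=list(table.excluded)
    )


def build_qindex_table(records: list[QualityRecord], weights=None) -> QIndexTable:
    """Run the full three-step pipeline on raw records."""
    return aggregate_qindex(global_rescale(records), weights)


def delta_qindex(table: QIndexTable, on_missing: str = "raise") -> pd.DataFrame:
    """ΔQ-index per enhanced record: qindex(variant) - qindex(original).

    Every enhanced record must have a variant-0 original for its image;
    originals can go missing when outlier removal dropped them. By default
    this raises :class:`MissingBaselineError` listing the affected image ids;
    ``on_missing="skip"`` silently drops those enhanced records instead.
    Returns a DataFrame with columns ``image_id``, ``variant_id``,
    ``variant_name``, ``delta``.
    """
    df = table.records
    if "qindex" not in df.columns:
        raise ValueError("qindex not computed; call aggregate_qindex first")
    originals = df[df["variant_id"] == 0].set_index("image_id")["qindex"]
    enhanced = df[df["variant_id"] > 0]
    missing = sorted(set(enhanced["image_id"]) - set(originals.index))
    if missing:
        if on_missing == "skip":
            enhanced = enhanced[enhanced["image_id"].isin(set(originals.index))]
        else:
            raise MissingBaselineError(
                f"no original (variant 0) record for image ids: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
    out = enhanced[["image_id", "variant_id", "variant_name"]].copy()
    out["delta"] = enhanced["qindex"].to_numpy() - originals.loc[enhanced["image_id"]].to_numpy()
    return out.reset_index(drop=True)


def weight_sensitivity(table: QIndexTable, perturbation: float = 0.25) -> pd.DataFrame:
    """Effect of single-weight perturbations of ±``perturbation`` on the Q-index.

    For each metric m and each sign, the weight of m is scaled by
    ``1 ± perturbation``, the weight vector re-normalized, and the per-variant
    median qindex and median ΔQ-index recomputed. The report also carries the
    maximum absolute qindex change versus the equal-weight baseline.
    """
    if not 0 <= perturbation < 1:
        raise ValueError(f"perturbation must lie in [0, 1), got {perturbation}")
    if "qindex" not in table.records.columns:
        raise ValueError("qindex not computed; call aggregate_qindex first")
    base = table.records
    rows = []

    def _summaries(tab: QIndexTable, label: str, metric: str, sign: float) -> None:
        med = tab.records.groupby("variant_id")["qindex"].median()
        deltas = delta_qindex(tab) if (tab.records["variant_id"] > 0).any() and (
            tab.records["variant_id"] == 0
        ).any() else None
        max_change = float(np.abs(tab.records["qindex"].to_numpy() - base["qindex"].to_numpy()).max())
        for variant_id, q_med in med.items():
            d_med = float("nan")
            if deltas is not None and variant_id > 0:
                d_med = float(deltas[deltas["variant_id"] == variant_id]["delta"].median())
            rows.append(
                {
                    "scenario": label,
                    "metric": metric,
                    "sign": sign,
                    "variant_id": int(variant_id),
                    "median_qindex": float(q_med),
                    "median_delta": d_med,
                    "max_abs_change": max_change,
                }
            )

    _summaries(table, "baseline", "", 0.0)
    for metric in METRICS:
        for sign in (+1.0, -1.0):
            w = dict(table.weights)
            w[metric] = w[metric] * (1.0 + sign * perturbation)
            perturbed = aggregate_qindex(table, w)
            _summaries(perturbed, f"{metric}{'+' if sign > 0 else '-'}", metric, sign)
    return pd.DataFrame(rows)


def bin_by_quality(table: QIndexTable, n_bins: int = 10) -> pd.DataFrame:
    """Assign each record to an equal-width quality bin on [0, 1].

    Bins are left-closed right-open, except the last which is right-closed so
    that qindex 1.0 falls in bin ``n_bins - 1``. Returns the records with a
    ``bin`` column; per-bin counts (including empty bins) are attached as
    ``result.attrs['bin_counts']``.
    """
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    df = table.records
    if "qindex" not in df.columns:
        raise ValueError("qindex not computed; call aggregate_qindex first")
    q = df["qindex"].to_numpy()
    idx = np.minimum((q * n_bins).astype(int), n_bins - 1)
    out = df[["image_id", "variant_id", "qindex"]].copy()
    out["bin"] = idx
    counts = pd.Series(np.bincount(idx, minlength=n_bins), name="count")
    counts.index.name = "bin"
    out.attrs["bin_counts"] = counts
    out.attrs["bin_edges"] = np.linspace(0.0, 1.0, n_bins + 1)
    return out


def distribution_summary(table: QIndexTable) -> pd.DataFrame:
    """Per-variant distribution summary of qindex and ΔQ-index.

    For each variant: median and quartiles of qindex; for enhanced variants
    additionally the median delta and the fraction of records with positive
    delta. A 20-bin histogram of qindex per variant, suitable for violin-style
    plotting, is attached as ``result.attrs['histograms']``.
    """
    df = table.records
    if "qindex" not in df.columns:
        raise ValueError("qindex not computed; call aggregate_qindex first")
    deltas = (
        delta_qindex(table)
        if (df["variant_id"] == 0).any() and (df["variant_id"] > 0).any()
        else None
    )
    rows = []
    hists = {}
    edges = np.linspace(0.0, 1.0, 21)
    for variant_id, grp in df.groupby("variant_id"):
        q = grp["qindex"].to_numpy()
        row = {
            "variant_id": int(variant_id),
            "n": len(grp),
            "median_qindex": float(np.median(q)),
            "q1_qindex": float(np.percentile(q, 25)),
            "q3_qindex": float(np.percentile(q, 75)),
        }
        if deltas is not None and variant_id > 0:
            d = deltas[deltas["variant_id"] == variant_id]["delta"].to_numpy()
            row["median_delta"] = float(np.median(d))
            row["q1_delta"] = float(np.percentile(d, 25))
            row["q3_delta"] = float(np.percentile(d, 75))
            row["positive_fraction"] = float(np.mean(d > 0))
        rows.append(row)
        hists[int(variant_id)] = np.histogram(q, bins=edges)[0]
    out = pd.DataFrame(rows)
    out.attrs["histograms"] = hists
    out.attrs["histogram_edges"] = edges
    return out
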