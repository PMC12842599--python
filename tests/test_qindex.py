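"""Q-index pipeline tests: outlier removal, rescaling, aggregation, binning."""

import numpy as np
import pandas as pd
import pytest

from uweval import qindex
from uweval.iqa import QualityRecord
from uweval.qindex import (
    DegenerateScaleError,
    MissingBaselineError,
    QIndexTable,
    aggregate_qindex,
    bin_by_quality,
    build_qindex_table,
    delta_qindex,
    distribution_summary,
    global_rescale,
    remove_outliers,
    weight_sensitivity,
)


def make_records(metric_rows, variant_ids=None, image_ids=None):
    """Build QualityRecords from rows of (uiqm, uciqe, ccf, entropy)."""
    out = []
    for k, row in enumerate(metric_rows):
        out.append(
            QualityRecord(
                image_id=image_ids[k] if image_ids else f"img{k}",
                variant_id=variant_ids[k] if variant_ids else 0,
                uiqm=row[0], uciqe=row[1], ccf=row[2], entropy=row[3],
            )
        )
    return out


def table_from_rescaled(rows, weights=None):
    """QIndexTable directly from already-rescaled metric values."""
    df = pd.DataFrame(
        [
            {"image_id": image_id, "variant_id": variant_id, "variant_name": "",
             "uiqm": m[0], "uciqe": m[1], "ccf": m[2], "entropy": m[3]}
            for image_id, variant_id, m in rows
        ]
    )
    bounds = {m: (0.0, 1.0) for m in qindex.METRICS}
    table = QIndexTable(records=df, weights={m: 0.25 for m in qindex.METRICS}, rescale_bounds=bounds)
    return aggregate_qindex(table, weights)


class TestRemoveOutliers:
    def test_hand_computed_example(self):
        kept, removed = remove_outliers([1, 2, 3, 4, 100])
        assert list(kept) == [1, 2, 3, 4]
        assert list(removed) == [False, False, False, False, True]

    def test_constant_values_keep_everything(self):
        kept, removed = remove_outliers([5, 5, 5, 5])
        assert list(kept) == [5, 5, 5, 5]
        assert not removed.any()

    def test_singleton_kept(self):
        kept, removed = remove_outliers([7])
        assert list(kept) == [7]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers([])

    def test_median_always_survives(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(1, 30)) * rng.uniform(0.1, 50)
            kept, removed = remove_outliers(x)
            assert kept.size >= 1
            # the value(s) closest to the median can never be flagged
            closest = np.argmin(np.abs(x - np.median(x)))
            assert not removed[closest]


class TestGlobalRescale:
    def test_endpoints_map_to_zero_and_one(self):
        rows = [(2, 10, 100, 1), (4, 20, 200, 2), (6, 30, 300, 3)]
        table = global_rescale(make_records(rows))
        assert list(table.records["uiqm"]) == pytest.approx([0.0, 0.5, 1.0])
        for m in qindex.METRICS:
            assert table.records[m].min() == 0.0
            assert table.records[m].max() == 1.0

    def test_monotone_order_preserved(self, rng):
        vals = np.sort(rng.uniform(0, 50, size=12))
        rows = [(v, v + 1, v + 2, min(v / 10, 8)) for v in vals]
        table = global_rescale(make_records(rows))
        assert (np.diff(table.records["uiqm"]) > 0).all()

    def test_outliers_do_not_set_bounds(self):
        # uiqm column [1,2,3,4,100]: 100 excluded, so 4 rescales to 1.0
        rows = [(1, 10, 100, 1), (2, 11, 105, 2), (3, 12, 110, 3),
                (4, 13, 115, 4), (100, 14, 120, 5)]
        table = global_rescale(make_records(rows))
        assert table.rescale_bounds["uiqm"] == (1.0, 4.0)
        assert table.records["uiqm"].max() == pytest.approx(1.0)
        assert ("img4", 0, "uiqm") in table.excluded
        # the record carrying the outlier is dropped entirely, not imputed
        assert "img4" not in set(table.records["image_id"])

    def test_degenerate_metric_raises_naming_the_metric(self):
        rows = [(1, 5, 100, 2), (2, 5, 105, 3), (3, 5, 110, 4)]
        with pytest.raises(DegenerateScaleError, match="uciqe"):
            global_rescale(make_records(rows))

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            global_rescale([])


class TestAggregate:
    def test_equal_weights_arithmetic_mean(self):
        table = table_from_rescaled([("a", 0, (0.2, 0.4, 0.6, 0.8))])
        assert table.records["qindex"].iloc[0] == pytest.approx(0.5)

    def test_uniform_metrics_are_a_fixed_point_for_any_weights(self, rng):
        table_rows = [("a", 0, (0.3, 0.3, 0.3, 0.3)), ("b", 0, (0.9, 0.9, 0.9, 0.9))]
        for _ in range(5):
            w = rng.uniform(0.1, 2.0, size=4)
            table = table_from_rescaled(table_rows, weights=w)
            assert list(table.records["qindex"]) == pytest.approx([0.3, 0.9])

    def test_basis_vector_weighting(self):
        table = table_from_rescaled([("a", 0, (1.0, 0.0, 0.0, 0.0))], weights=(0.4, 0.2, 0.2, 0.2))
        assert table.records["qindex"].iloc[0] == pytest.approx(0.4)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            table_from_rescaled([("a", 0, (0.5, 0.5, 0.5, 0.5))], weights=(-1, 1, 1, 1))

    def test_qindex_in_unit_interval_and_monotone(self, rng):
        rows = [(f"i{k}", 0, tuple(rng.uniform(0, 1, size=4))) for k in range(30)]
        table = table_from_rescaled(rows)
        q = table.records["qindex"]
        assert ((0 <= q) & (q <= 1)).all()
        # increasing one rescaled metric never decreases qindex
        bumped = [(f"i{k}", 0, (min(m[0] + 0.1, 1.0), m[1], m[2], m[3])) for (_, _, m), k in
                  zip(rows, range(len(rows)))]
        q2 = table_from_rescaled(bumped).records["qindex"]
        assert (q2.to_numpy() >= q.to_numpy() - 1e-12).all()

    def test_equal_weights_permutation_invariant(self):
        a = table_from_rescaled([("a", 0, (0.1, 0.5, 0.7, 0.9))])
        b = table_from_rescaled([("a", 0, (0.9, 0.7, 0.5, 0.1))])
        assert a.records["qindex"].iloc[0] == pytest.approx(b.records["qindex"].iloc[0])


class TestDelta:
    def test_identity_enhancement_gives_zero(self):
        table = table_from_rescaled([("a", 0, (0.4,) * 4), ("a", 1, (0.4,) * 4)])
        deltas = delta_qindex(table)
        assert deltas["delta"].iloc[0] == pytest.approx(0.0)

    def test_direct_subtraction(self):
        table = table_from_rescaled([("a", 0, (0.45,) * 4), ("a", 1, (0.60,) * 4)])
        assert delta_qindex(table)["delta"].iloc[0] == pytest.approx(0.15)

    def test_missing_original_raises_with_image_ids(self):
        table = table_from_rescaled([("a", 1, (0.5,) * 4)])
        with pytest.raises(MissingBaselineError, match="a"):
            delta_qindex(table)

    def test_cohort_with_constant_shift_recovers_shift(self, rng):
        rows = []
        for k in range(40):
            q0 = rng.uniform(0.1, 0.5)
            rows.append((f"i{k}", 0, (q0,) * 4))
            rows.append((f"i{k}", 1, (q0 + 0.2,) * 4))
        deltas = delta_qindex(table_from_rescaled(rows))
        assert deltas["delta"].median() == pytest.approx(0.2, abs=1e-9)


class TestWeightSensitivity:
    def test_zero_perturbation_matches_baseline(self):
        table = table_from_rescaled([("a", 0, (0.2, 0.4, 0.6, 0.8)), ("a", 1, (0.3, 0.5, 0.7, 0.9))])
        report = weight_sensitivity(table, perturbation=0.0)
        assert report["max_abs_change"].max() == pytest.approx(0.0, abs=1e-12)

    def test_uniform_records_unchanged_under_perturbation(self):
        table = table_from_rescaled([("a", 0, (0.6,) * 4), ("b", 0, (0.2,) * 4)])
        report = weight_sensitivity(table, perturbation=0.25)
        assert report["max_abs_change"].max() == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_perturbed_qindex(self):
        # single record (1, 0, 0, 0); +25% on the first weight:
        # weights (0.3125, 0.25, 0.25, 0.25) / 1.0625 -> qindex = 0.3125/1.0625
        table = table_from_rescaled([("a", 0, (1.0, 0.0, 0.0, 0.0))])
        report = weight_sensitivity(table, perturbation=0.25)
        row = report[(report["scenario"] == "uiqm+")]
        assert row["median_qindex"].iloc[0] == pytest.approx(0.3125 / 1.0625)

    def test_invalid_perturbation_rejected(self):
        table = table_from_rescaled([("a", 0, (0.5,) * 4)])
        with pytest.raises(ValueError):
            weight_sensitivity(table, perturbation=1.5)


class TestBins:
    def test_direct_placement(self):
        table = table_from_rescaled([("a", 0, (0.55,) * 4)])
        assert bin_by_quality(table)["bin"].iloc[0] == 5

    def test_right_closure_of_last_bin(self):
        table = table_from_rescaled([("a", 0, (1.0,) * 4)])
        assert bin_by_quality(table)["bin"].iloc[0] == 9

    def test_uniform_grid_counts(self):
        rows = [(f"i{k}", 0, ((k + 0.5) / 100,) * 4) for k in range(100)]
        table = table_from_rescaled(rows)
        binned = bin_by_quality(table)
        assert list(binned.attrs["bin_counts"]) == [10] * 10

    def test_empty_bins_reported(self):
        table = table_from_rescaled([("a", 0, (0.95,) * 4)])
        counts = bin_by_quality(table).attrs["bin_counts"]
        assert counts.sum() == 1 and counts[9] == 1 and (counts[:9] == 0).all()

    def test_invalid_n_bins_rejected(self):
        table = table_from_rescaled([("a", 0, (0.5,) * 4)])
        with pytest.raises(ValueError):
            bin_by_quality(table, n_bins=0)


class TestDistributionSummary:
    def test_all_positive_deltas(self):
        rows = [("a", 0, (0.2,) * 4), ("a", 1, (0.4,) * 4),
                ("b", 0, (0.3,) * 4), ("b", 1, (0.5,) * 4)]
        summary = distribution_summary(table_from_rescaled(rows))
        enh = summary[summary["variant_id"] == 1]
        assert enh["positive_fraction"].iloc[0] == 1.0

    def test_symmetric_deltas(self):
        rows = [("a", 0, (0.5,) * 4), ("a", 1, (0.6,) * 4),
                ("b", 0, (0.5,) * 4), ("b", 1, (0.4,) * 4)]
        summary = distribution_summary(table_from_rescaled(rows))
        enh = summary[summary["variant_id"] == 1]
        assert enh["median_delta"].iloc[0] == pytest.approx(0.0)
        assert enh["positive_fraction"].iloc[0] == 0.5


def test_full_pipeline_produces_bounded_qindex(metric_corpus):
    """End to end on real metric values: all qindex values lie in [0, 1]."""
    from uweval import iqa

    records = []
    for k, img in enumerate(metric_corpus):
        records.append(iqa.score_image(f"img{k % 10}", k // 10, img))
    table = build_qindex_table(records)
    q = table.records["qindex"]
    assert ((0.0 <= q) & (q <= 1.0)).all()
    assert table.weights == {m: 0.25 for m in qindex.METRICS}
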