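import math

import numpy as np
import pandas as pd
import pytest

from pocusalign import (
    ReadingTable,
    compute_report,
    majority_vote,
    mean_accuracy,
    mean_discrepancy,
    mae,
    pooled_pearson,
    reference_angulation,
)
from pocusalign.study import NO_FRACTURE, load_bundled_gt_labels


def pearson_by_covariance(x, y):
    """Independent cross-check via the raw covariance formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return cov / (x.std() * y.std())


class TestReferenceAngulation:
    def test_printed_rows(self, readings):
        refs = reference_angulation(readings)
        assert refs[3] == pytest.approx(8.7)
        assert refs[10] == pytest.approx(10.4)
        assert refs[0] == pytest.approx(3.9)
        assert refs[4] == pytest.approx(9.3)

    def test_no_fracture_samples_marked(self, readings):
        refs = reference_angulation(readings)
        for s in (1, 2, 6, 8):
            assert refs[s] is NO_FRACTURE

    def test_participant_permutation_invariant(self, readings):
        df = readings.readings.copy()
        remap = {1: 2, 2: 3, 3: 1}
        df["participant"] = df["participant"].map(remap)
        permuted = ReadingTable(df, readings.accuracies)
        assert reference_angulation(permuted) == reference_angulation(readings)


class TestMae:
    def test_all_six_printed_values(self, readings):
        maes = mae(readings)
        assert maes[(1, "POCUS")] == 4.4
        assert maes[(2, "POCUS")] == 3.7
        assert maes[(3, "POCUS")] == 5.0
        assert maes[(1, "X-ray")] == 2.8
        assert maes[(2, "X-ray")] == 1.8
        assert maes[(3, "X-ray")] == 2.0

    def test_identical_readings_zero(self, readings):
        refs = reference_angulation(readings)
        df = readings.readings.copy()
        for i, row in df.iterrows():
            r = refs.get(row["sample"])
            df.loc[i, "angle_deg"] = np.nan if r is NO_FRACTURE else r
        tbl = ReadingTable(df)
        for v in mae(tbl).values():
            assert v == 0.0


class TestDiscrepancy:
    def test_printed_mean_discrepancy(self, readings):
        assert mean_discrepancy(mae(readings)) == 2.2

    def test_identical_maes_zero(self):
        maes = {(p, m): 3.0 for p in (1, 2, 3) for m in ("POCUS", "X-ray")}
        assert mean_discrepancy(maes) == 0.0

    def test_constant_gap(self):
        maes = {}
        for p in (1, 2, 3):
            maes[(p, "POCUS")] = 3.0
            maes[(p, "X-ray")] = 1.0
        assert mean_discrepancy(maes) == 2.0

    def test_missing_entry_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            mean_discrepancy({(1, "POCUS"): 1.0})


class TestPearson:
    def test_printed_value_and_covariance_cross_check(self, readings):
        r = pooled_pearson(readings)
        assert round(r, 2) == 0.18
        # independent recomputation of the same pooled vectors
        refs = reference_angulation(readings)
        frac = [s for s, v in refs.items() if v is not NO_FRACTURE]
        errs, rv = [], []
        for p in (1, 2, 3):
            for s in frac:
                a = readings.angle(s, p, "POCUS")
                errs.append(abs((0.0 if a is None else a) - refs[s]))
                rv.append(refs[s])
        assert r == pytest.approx(pearson_by_covariance(errs, rv), abs=1e-12)

    def test_unit_rescaling_invariance(self, readings):
        # Pearson r is affine-invariant; the one-decimal reference rounding
        # perturbs the pooled pairs slightly when the unit changes, so the
        # check carries a small tolerance
        df10 = readings.readings.copy()
        df10["angle_deg"] = df10["angle_deg"] * 10.0
        r10 = pooled_pearson(ReadingTable(df10))
        assert r10 == pytest.approx(pooled_pearson(readings), abs=0.02)

    def test_constant_errors_rejected(self, readings):
        refs = reference_angulation(readings)
        df = readings.readings.copy()
        mask = df["modality"] == "POCUS"
        for i, row in df[mask].iterrows():
            r = refs.get(row["sample"])
            if r is not NO_FRACTURE:
                df.loc[i, "angle_deg"] = r + 1.0  # constant error of 1 degree
        with pytest.raises(ValueError, match="variance"):
            pooled_pearson(ReadingTable(df))

    def test_proportional_errors_give_unit_correlation(self, readings):
        refs = reference_angulation(readings)
        df = readings.readings.copy()
        mask = df["modality"] == "POCUS"
        for i, row in df[mask].iterrows():
            r = refs.get(row["sample"])
            if r is not NO_FRACTURE:
                df.loc[i, "angle_deg"] = r * 1.5  # error = 0.5 * ref
        assert pooled_pearson(ReadingTable(df)) == pytest.approx(1.0, abs=1e-12)


class TestAccuracy:
    def test_printed_means(self, readings):
        assert mean_accuracy(readings, "POCUS") == 0.76
        assert mean_accuracy(readings, "X-ray") == 0.97

    def test_all_correct(self, readings):
        acc = readings.accuracies.copy()
        acc["accuracy"] = 1.0
        tbl = ReadingTable(readings.readings, acc)
        assert mean_accuracy(tbl, "POCUS") == 1.0

    def test_missing_accuracies_rejected(self, readings):
        tbl = ReadingTable(readings.readings, None)
        with pytest.raises(ValueError, match="accurac"):
            mean_accuracy(tbl, "POCUS")


class TestMajorityVote:
    @pytest.mark.parametrize(
        "labels,expected",
        [(("B", "B", "N"), "B"), (("N", "N", "N"), "N"), (("G", "B", "G"), "G")],
    )
    def test_majorities(self, labels, expected):
        assert majority_vote(labels) == expected

    def test_three_way_tie_rejected(self):
        with pytest.raises(ValueError, match="majority"):
            majority_vote(("B", "G", "N"))

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError):
            majority_vote(("B", "B", "X"))

    def test_bundled_gt_consistency(self):
        labels = load_bundled_gt_labels()
        assert labels["3"] == "G"
        assert sum(1 for v in labels.values() if v == "N") == 4


class TestReport:
    def test_full_report(self, readings):
        rep = compute_report(readings).to_dict()
        assert rep["mean_discrepancy_deg"] == 2.2
        assert rep["pearson_r"] == 0.18
        assert rep["mean_accuracy_pocus"] == 0.76
        assert rep["mean_accuracy_xray"] == 0.97
        assert rep["references_deg"]["1"] is None

    def test_row_order_invariance(self, readings):
        df = readings.readings.sample(frac=1.0, random_state=5).reset_index(drop=True)
        shuffled = ReadingTable(df, readings.accuracies)
        assert compute_report(shuffled).to_dict() == compute_report(readings).to_dict()

    def test_schema_violations_rejected(self):
        with pytest.raises(ValueError):
            ReadingTable(pd.DataFrame({"sample": [0], "angle_deg": [1.0]}))
        df = pd.DataFrame(
            {
                "sample": [0, 0],
                "participant": [1, 1],
                "modality": ["POCUS", "POCUS"],
                "angle_deg": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError):
            ReadingTable(df)
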