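import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from accelxfer import (
    COARSE_LABELS,
    TD_COLUMNS,
    ModelSpec,
    confusion_summary,
    loso_transfer,
    transfer_grid,
    two_proportion_z,
)

#: Printed confusion counts of the same-device TD model (rows = truth in the
#: order clean, computer, throw, walk, run, vacuum).
TABLE_2A = np.array(
    [
        [19, 0, 0, 5, 0, 0],
        [0, 23, 1, 0, 0, 0],
        [0, 2, 18, 2, 0, 0],
        [1, 0, 0, 47, 0, 0],
        [0, 0, 0, 0, 48, 0],
        [0, 0, 0, 0, 0, 24],
    ]
)


def _labels_from_counts(counts):
    truth, pred = [], []
    for i, row in enumerate(counts):
        for j, c in enumerate(row):
            truth += [COARSE_LABELS[i]] * c
            pred += [COARSE_LABELS[j]] * c
    return truth, pred


class TestConfusionSummary:
    def test_published_td_matrix_recalls(self):
        cm = confusion_summary(*_labels_from_counts(TABLE_2A))
        assert cm.per_class_recall["clean"] == 79.2  # 19/24
        assert cm.per_class_recall["walk"] == 97.9  # 47/48
        assert cm.per_class_recall["run"] == 100.0
        assert cm.per_class_recall["vacuum"] == 100.0

    def test_matrix_identities(self):
        cm = confusion_summary(*_labels_from_counts(TABLE_2A))
        assert cm.overall_accuracy == round(
            100 * np.trace(TABLE_2A) / TABLE_2A.sum(), 1
        )
        np.testing.assert_array_equal(cm.counts.sum(axis=1), TABLE_2A.sum(axis=1))
        assert cm.n_correct == int(np.trace(TABLE_2A))

    def test_perfect_predictions(self):
        truth = list(COARSE_LABELS) * 4
        cm = confusion_summary(truth, truth)
        assert cm.overall_accuracy == 100.0
        assert np.all(np.diag(cm.counts) == 4)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            confusion_summary(["walk"], ["jog"])


class TestTwoProportionZ:
    def test_equal_proportions(self):
        assert two_proportion_z(50, 100, 50, 100) == (0.0, 1.0)

    def test_hand_computed_pooled_statistic(self):
        z, p = two_proportion_z(90, 100, 80, 100)
        assert z == pytest.approx(1.980, abs=5e-4)
        assert 0 < p < 0.05

    def test_antisymmetry(self):
        z1, p1 = two_proportion_z(90, 100, 70, 90)
        z2, p2 = two_proportion_z(70, 90, 90, 100)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_pooled_proportion(self):
        assert two_proportion_z(0, 10, 0, 12) == (0.0, 1.0)
        assert two_proportion_z(10, 10, 12, 12) == (0.0, 1.0)

    @pytest.mark.parametrize(
        "k1,n1,k2,n2",
        [(8, 10, 4, 10), (10, 12, 6, 12), (5, 8, 7, 8), (9, 12, 9, 12),
         (6, 10, 9, 12), (3, 6, 5, 6)],
    )
    def test_against_exact_conditional_oracle_small_n(self, k1, n1, k2, n2):
        """Normal-approximation p stays close to the exact conditional
        (hypergeometric) permutation p on small samples.  The comparison is
        on the mid-p scale (half-weight on ties), the standard way to relate
        a continuous approximation to a heavily discrete exact test; the
        documented tolerance is 0.2 at n <= 12."""
        z, p = two_proportion_z(k1, n1, k2, n2)
        K, N = k1 + k2, n1 + n2
        obs = abs(k1 / n1 - k2 / n2)
        support = np.arange(max(0, K - n2), min(K, n1) + 1)
        pmf = hypergeom.pmf(support, N, K, n1)
        diffs = np.abs(support / n1 - (K - support) / n2)
        mid_p = float(
            pmf[diffs > obs + 1e-12].sum()
            + 0.5 * pmf[np.abs(diffs - obs) <= 1e-12].sum()
        )
        assert abs(p - mid_p) < 0.2
        # the statistic agrees in direction
        assert np.sign(z) == np.sign(k1 / n1 - k2 / n2)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_z(5, 4, 1, 10)


def _toy_table(device_id, n_subjects=4, sep=10.0, noise=0.1, seed=0,
               shuffle_labels=False, feature_set="TD"):
    """Trivially separable six-class table: class k sits at mean k*sep."""
    from accelxfer import FD_COLUMNS

    cols = TD_COLUMNS if feature_set == "TD" else FD_COLUMNS
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for k, lab in enumerate(COARSE_LABELS):
            for w in range(3):
                feats = {c: k * sep + rng.normal(0, noise) for c in cols}
                rows.append({"subject_id": f"S{s}", "device_id": device_id,
                             "activity": lab, "window_index": w, **feats})
    df = pd.DataFrame(rows)
    if shuffle_labels:
        df["activity"] = rng.permutation(df["activity"].to_numpy())
    df.attrs["feature_set"] = feature_set
    return df


class TestLosoTransfer:
    def test_separable_classes_reach_full_accuracy(self):
        tbl = _toy_table("A")
        res = loso_transfer(tbl, tbl, ModelSpec(n_trees=50, seed=0))
        assert res.accuracy == 100.0
        assert res.n_total == len(tbl)

    def test_permuted_labels_fall_to_chance(self):
        """With labels destroyed, LOSO accuracy concentrates at the chance
        level implied by the (uniform) class frequencies, 1/6."""
        tbl = _toy_table("A", n_subjects=6, shuffle_labels=True, seed=3)
        res = loso_transfer(tbl, tbl, ModelSpec(n_trees=100, seed=0))
        assert res.accuracy < 40.0  # chance ~16.7%, wide Monte-Carlo margin

    def test_deterministic_given_seed(self):
        tbl = _toy_table("A", noise=3.0)
        r1 = loso_transfer(tbl, tbl, ModelSpec(n_trees=50, seed=7))
        r2 = loso_transfer(tbl, tbl, ModelSpec(n_trees=50, seed=7))
        assert r1.accuracy == r2.accuracy
        np.testing.assert_array_equal(r1.confusion.counts, r2.confusion.counts)

    def test_single_subject_rejected(self):
        tbl = _toy_table("A", n_subjects=1)
        with pytest.raises(ValueError, match="subjects"):
            loso_transfer(tbl, tbl, ModelSpec(n_trees=50))

    def test_feature_set_mismatch_rejected(self):
        tbl = _toy_table("A")
        with pytest.raises(ValueError, match="feature_set"):
            loso_transfer(tbl, tbl, ModelSpec(feature_set="FD", n_trees=50))


class TestTransferGrid:
    def test_identical_device_tables_give_equal_cells(self):
        # same feature values on both devices: every cell is perfect
        tables = {
            (dev, fset): _toy_table(dev, feature_set=fset)
            for dev in ("A", "B")
            for fset in ("TD", "FD")
        }
        grid, results = transfer_grid(tables, "A", "B", ModelSpec(n_trees=50))
        assert set(grid["accuracy_pct"]) == {100.0}
        assert len(results) == 8

    def test_missing_table_rejected(self):
        ta = _toy_table("A")
        with pytest.raises(ValueError, match="missing"):
            transfer_grid({("A", "TD"): ta}, "A", "B",
                          ModelSpec(n_trees=50), feature_sets=("TD",))
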