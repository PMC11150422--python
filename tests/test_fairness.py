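"""Group-fairness metric unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fundusfair.fairness import (
    DisparityReport,
    GroupAPTable,
    GroupedPredictions,
    UndefinedMetricError,
    delta_a,
    delta_d,
    delta_m,
    dpm,
    eom,
    fairness_report,
    pqd,
)


def make_table(values, classes=None, groups=None):
    values = np.asarray(values, dtype=float)
    classes = classes or [f"c{i}" for i in range(values.shape[0])]
    groups = groups or [f"g{j}" for j in range(values.shape[1])]
    return GroupAPTable(classes=classes, groups=groups, values=values)


class TestDeltaD:
    @pytest.mark.parametrize(
        "ap_by_group, expected",
        [
            ({"male": 44.0, "female": 87.8}, 66.46),  # published aneurysms pair
            ({"g1": 55.0, "g2": 55.0}, 0.0),
            ({"g1": 30.0, "g2": 60.0, "g3": 90.0}, 100.0),
            ({"g1": 0.0, "g2": 0.0}, 0.0),  # all-zero: no disparity, not 0/0
        ],
    )
    def test_values(self, ap_by_group, expected):
        assert delta_d(ap_by_group) == pytest.approx(expected, abs=0.005)

    def test_published_pair_prints_one_decimal(self):
        assert round(delta_d({"male": 44.0, "female": 87.8}), 1) == 66.5

    def test_single_group_is_undefined_not_zero(self):
        with pytest.raises(UndefinedMetricError):
            delta_d({"only": 50.0})

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            delta_d({"a": -1.0, "b": 5.0})

    @given(
        vals=st.lists(st.floats(0.1, 100.0), min_size=2, max_size=6),
        c=st.floats(0.01, 0.99),
    )
    @settings(derandomize=True, max_examples=200)
    def test_scale_invariance_and_bounds(self, vals, c):
        base = delta_d(dict(enumerate(vals)))
        scaled = delta_d({i: c * v for i, v in enumerate(vals)})
        assert scaled == pytest.approx(base, rel=1e-9)
        assert 0.0 <= base <= 100.0 * len(vals)  # (max-min)/mean <= n

    def test_two_group_upper_bound_attained(self):
        # {0, x} attains the 2-group supremum of 200
        assert delta_d({"a": 0.0, "b": 73.0}) == pytest.approx(200.0)


class TestPQD:
    @pytest.mark.parametrize(
        "ap_by_group, expected",
        [
            ({"male": 50.0, "female": 100.0}, 50.0),
            ({"a": 70.0, "b": 70.0}, 100.0),
            ({"a": 25.0, "b": 75.0, "c": 100.0}, 25.0),
        ],
    )
    def test_values(self, ap_by_group, expected):
        assert pqd(ap_by_group) == pytest.approx(expected)

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pqd({"a": 0.0, "b": 0.0})


class TestTableSummaries:
    def test_delta_m_is_max_and_delta_a_is_mean(self):
        tab = make_table([[40, 60], [50, 50], [20, 80]])
        dds = [delta_d(dict(zip(tab.groups, row))) for row in tab.values]
        assert delta_m(tab) == pytest.approx(max(dds))
        assert delta_a(tab) == pytest.approx(np.mean(dds))

    def test_single_class_table(self):
        tab = make_table([[40, 60]])
        assert delta_m(tab) == pytest.approx(delta_d({"a": 40, "b": 60}))

    def test_missing_cell_excludes_class_from_both(self):
        tab = make_table([[40, 60], [np.nan, 90], [30, 30]])
        rep = fairness_report(tab)
        assert rep.excluded_classes == ["c1"]
        assert set(rep.per_class_delta_d) == {"c0", "c2"}
        # mean divides by scored classes (2), not nominal count (3)
        assert rep.delta_a == pytest.approx((delta_d({"a": 40, "b": 60}) + 0) / 2)

    def test_all_excluded_is_undefined(self):
        tab = make_table([[np.nan, 60], [np.nan, 90]])
        with pytest.raises(UndefinedMetricError):
            delta_m(tab)

    @given(
        data=st.lists(
            st.lists(st.floats(0.5, 100.0), min_size=3, max_size=3),
            min_size=1,
            max_size=8,
        )
    )
    @settings(derandomize=True, max_examples=200)
    def test_delta_a_never_exceeds_delta_m(self, data):
        tab = make_table(data)
        assert delta_a(tab) <= delta_m(tab) + 1e-9

    @given(
        data=st.lists(
            st.lists(st.floats(0.5, 100.0), min_size=4, max_size=4),
            min_size=2,
            max_size=6,
        ),
        perm_seed=st.integers(0, 1000),
    )
    @settings(derandomize=True, max_examples=100)
    def test_permutation_invariance(self, data, perm_seed):
        tab = make_table(data)
        rng = np.random.default_rng(perm_seed)
        ci = rng.permutation(len(tab.classes))
        gi = rng.permutation(len(tab.groups))
        shuffled = GroupAPTable(
            classes=[tab.classes[i] for i in ci],
            groups=[tab.groups[j] for j in gi],
            values=tab.values[np.ix_(ci, gi)],
        )
        assert delta_m(shuffled) == pytest.approx(delta_m(tab))
        assert delta_a(shuffled) == pytest.approx(delta_a(tab))


def make_preds(scores, labels, groups, threshold=0.5):
    return GroupedPredictions(
        scores=np.asarray(scores, float),
        labels=np.asarray(labels),
        group_of=list(groups),
        threshold=threshold,
    )


class TestDPMandEOM:
    def test_identical_predictions_across_groups_are_parity(self):
        rng = np.random.default_rng(0)
        scores = np.tile(rng.random((10, 3)), (2, 1))
        labels = rng.integers(0, 2, (20, 3))  # labels may differ by group
        groups = ["a"] * 10 + ["b"] * 10
        assert dpm(make_preds(scores, labels, groups)) == pytest.approx(100.0)

    def test_dpm_single_class_rate_ratio(self):
        # group a predicts positive at rate 0.2, group b at 0.4
        scores = np.array([[0.9], [0.1], [0.1], [0.1], [0.1],
                           [0.9], [0.9], [0.1], [0.1], [0.1]])
        labels = np.ones((10, 1))
        groups = ["a"] * 5 + ["b"] * 5
        assert dpm(make_preds(scores, labels, groups)) == pytest.approx(50.0)

    def test_dpm_all_negative_undefined(self):
        scores = np.full((6, 2), 0.1)
        labels = np.ones((6, 2))
        with pytest.raises(UndefinedMetricError):
            dpm(make_preds(scores, labels, ["a"] * 3 + ["b"] * 3))

    def test_eom_perfect_classifier_is_100(self):
        labels = np.array([[1], [0], [1], [0]])
        scores = labels.astype(float) * 0.8 + 0.1
        assert eom(make_preds(scores, labels, ["a", "a", "b", "b"])) == pytest.approx(100.0)

    def test_eom_tpr_ratio(self):
        # group a TPR 0.5, group b TPR 1.0
        scores = np.array([[0.9], [0.1], [0.9], [0.9]])
        labels = np.ones((4, 1))
        assert eom(make_preds(scores, labels, ["a", "a", "b", "b"])) == pytest.approx(50.0)

    def test_eom_excludes_single_group_positive_class(self):
        # class 0 has positives only in group a; class 1 in both
        labels = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        scores = np.full((4, 2), 0.9)
        value, excluded = eom(
            make_preds(scores, labels, ["a", "a", "b", "b"]), return_excluded=True
        )
        assert excluded == ["class_0"]
        assert value == pytest.approx(100.0)


class TestFairnessReport:
    def test_report_composes_individual_metrics(self, rng):
        scores = rng.random((40, 4))
        labels = rng.integers(0, 2, (40, 4))
        groups = ["f"] * 20 + ["m"] * 20
        preds = make_preds(scores, labels, groups)
        rep = fairness_report(preds, attribute="sex")
        from fundusfair.screening import grouped_ap_table

        tab = grouped_ap_table(preds)
        assert rep.delta_m == pytest.approx(delta_m(tab))
        assert rep.delta_a == pytest.approx(delta_a(tab))
        assert rep.dpm == pytest.approx(dpm(preds))
        assert rep.eom == pytest.approx(eom(preds))
        assert rep.group_counts == {"f": 20, "m": 20}

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            DisparityReport(
                per_class_delta_d={"a": 5.0}, delta_m=5.0, delta_a=5.0,
                pqd={}, dpm=None, eom=None, excluded_classes=["a"],
            )
        with pytest.raises(ValueError):
            DisparityReport(
                per_class_delta_d={"a": 5.0}, delta_m=5.0, delta_a=9.0,
                pqd={}, dpm=None, eom=None,
            )

    def test_json_and_markdown_render(self):
        tab = make_table([[40.0, 60.0]])
        rep = fairness_report(tab, attribute="sex")
        assert "delta_m" in rep.to_json()
        assert "dM" in rep.to_markdown()


class TestTableIO:
    def test_round_trip_with_missing_cells(self, tmp_path):
        tab = make_table([[40, 60], [np.nan, 90]])
        path = tmp_path / "t.tsv"
        tab.write(path)
        back = GroupAPTable.read(path)
        assert back.classes == tab.classes
        assert back.groups == tab.groups
        np.testing.assert_allclose(back.values, tab.values)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("disease\ta\tb\nx\t12\toops\n")
        with pytest.raises(ValueError, match="non-numeric"):
            GroupAPTable.read(path)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            make_table([[150.0, 20.0]])
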