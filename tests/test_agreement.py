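"""Partition agreement metrics: confusion tables, dominant agreement,
label-matched pairwise agreement, Cohen's and Fleiss' kappa, outlier raters."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from whistlekit.agreement import (
    Partition,
    RatingTable,
    cohen_kappa,
    confusion_counts,
    dominant_agreement,
    flag_outlier_raters,
    fleiss_kappa,
    heatmap_percentages,
    pairwise_agreement,
)
from whistlekit.errors import InvalidInputError, UndefinedStatisticError


def part(labels):
    return Partition({f"w{k}": l for k, l in enumerate(labels)})


class TestConfusion:
    def test_identical_partitions_are_diagonal(self):
        a = part(list("AABBC"))
        conf = confusion_counts(a, a)
        assert (conf.to_numpy() == np.diag([2, 2, 1])).all()

    def test_split_against_single_label(self):
        a = part(list("AAAAABBBBB"))
        b = part(["X"] * 10)
        conf = confusion_counts(a, b)
        assert conf.shape == (2, 1)
        assert conf["X"].tolist() == [5, 5]

    def test_counts_conserve_n(self, rng):
        a = part(rng.choice(list("ABC"), 30))
        b = part(rng.choice(list("XY"), 30))
        assert confusion_counts(a, b).to_numpy().sum() == 30

    def test_mismatched_universes_rejected(self):
        with pytest.raises(InvalidInputError):
            confusion_counts(part("AB"), Partition({"other": "A", "ids": "B"}))


class TestDominantAgreement:
    @pytest.mark.parametrize(
        "n,splits,expected",
        [
            (407, [186, 50, 171], 46),
            (67, [37, 29, 1], 55),
            (27, [26, 1], 96),
            (6, [2, 4], 67),
            (8, [7, 1], 88),
            (19, [18, 1], 95),
            (11, [9, 2], 82),
            (4, [3, 1], 75),
            (8, [4, 4], 50),
            (6, [3, 3], 50),
        ],
    )
    def test_published_splits(self, n, splits, expected):
        assert dominant_agreement(n, splits) == expected

    @given(st.integers(1, 500))
    def test_single_grouping_is_total(self, n):
        assert dominant_agreement(n, [n]) == 100

    def test_errors(self):
        with pytest.raises(InvalidInputError):
            dominant_agreement(10, [])
        with pytest.raises(InvalidInputError):
            dominant_agreement(10, [5, 4])  # does not sum


class TestHeatmap:
    def test_diagonal_confusion(self):
        a = part(list("AABB"))
        pct = heatmap_percentages(confusion_counts(a, a))
        assert np.allclose(np.diag(pct.to_numpy()), 100.0)

    def test_column_normalization(self):
        a = part(["A", "A", "A", "B"])
        b = part(["X", "X", "X", "X"])
        pct = heatmap_percentages(confusion_counts(a, b))
        assert pct["X"].tolist() == [75.0, 25.0]

    def test_columns_sum_to_100(self, rng):
        for _ in range(10):
            a = part(rng.choice(list("ABCD"), 40))
            b = part(rng.choice(list("WXYZ"), 40))
            pct = heatmap_percentages(confusion_counts(a, b))
            assert np.allclose(pct.sum(axis=0), 100.0, atol=0.01)

    def test_zero_column_dropped_with_warning(self):
        conf = confusion_counts(part("AAB"), part("XXY"))
        conf["Z"] = 0
        with pytest.warns(UserWarning):
            pct = heatmap_percentages(conf)
        assert "Z" not in pct.columns


class TestPairwiseAgreement:
    def test_relabeling_gives_100(self):
        a = part(list("AABBCC"))
        b = part(list("XXYYZZ"))
        assert pairwise_agreement(a, b) == pytest.approx(100.0)

    def test_constructed_70_percent(self):
        a = part(list("AAAAABBBBB"))
        b = part(list("XXXXYYYYXX"))  # best matching covers 4 + 3 = 7 of 10
        assert pairwise_agreement(a, b) == pytest.approx(70.0)

    def test_matches_exhaustive_assignment(self, rng):
        """Hungarian matching equals brute-force best one-to-one label
        assignment on label sets of size <= 4."""
        for _ in range(30):
            a = part(rng.choice(list("ABCD"), 25))
            b = part(rng.choice(list("WXYZ"), 25))
            M = confusion_counts(a, b).to_numpy()
            r, c = M.shape
            s = max(r, c)
            Mp = np.zeros((s, s))
            Mp[:r, :c] = M
            best = max(
                sum(Mp[i, p[i]] for i in range(s))
                for p in itertools.permutations(range(s))
            )
            assert pairwise_agreement(a, b) == pytest.approx(100.0 * best / 25)

    def test_symmetry(self, rng):
        for _ in range(10):
            a = part(rng.choice(list("ABC"), 30))
            b = part(rng.choice(list("XYZW"), 30))
            assert pairwise_agreement(a, b) == pytest.approx(pairwise_agreement(b, a))


class TestCohenKappa:
    def test_perfect_agreement(self):
        a = part(list("AABBCC"))
        assert cohen_kappa(a, a) == pytest.approx(1.0)

    def test_independence_table_gives_zero(self):
        # marginal-product table: [[4, 8], [2, 4]] -> p_o == p_e
        labels_a = ["A"] * 12 + ["B"] * 6
        labels_b = ["A"] * 4 + ["B"] * 8 + ["A"] * 2 + ["B"] * 4
        assert cohen_kappa(part(labels_a), part(labels_b)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_2x2(self):
        # table [[20, 5], [10, 15]]: p_o = 0.7, p_e = 0.5, kappa = 0.4
        la = ["A"] * 25 + ["B"] * 25
        lb = ["A"] * 20 + ["B"] * 5 + ["A"] * 10 + ["B"] * 15
        assert cohen_kappa(part(la), part(lb)) == pytest.approx(0.4, abs=1e-9)

    def test_degenerate_single_label(self):
        with pytest.raises(UndefinedStatisticError):
            cohen_kappa(part(["A"] * 5), part(["A"] * 5))


def rating_table(columns):
    """columns: dict rater -> list of labels (items implicit)."""
    raters = sorted(columns)
    n = len(next(iter(columns.values())))
    items = [f"w{k}" for k in range(n)]
    labels = {(items[k], r): columns[r][k] for r in raters for k in range(n)}
    return RatingTable(items=items, raters=raters, labels=labels)


def fleiss_closed_form(counts):
    """Textbook Fleiss computation, independent of statsmodels."""
    counts = np.asarray(counts, float)
    n_items, _ = counts.shape
    n_raters = counts[0].sum()
    p_j = counts.sum(axis=0) / (n_items * n_raters)
    P_i = ((counts**2).sum(axis=1) - n_raters) / (n_raters * (n_raters - 1))
    P_bar, P_e = P_i.mean(), (p_j**2).sum()
    return (P_bar - P_e) / (1 - P_e)


class TestFleissKappa:
    def test_unanimous_raters(self):
        t = rating_table({"r1": list("ABCAB"), "r2": list("ABCAB"), "r3": list("ABCAB")})
        assert fleiss_kappa(t) == pytest.approx(1.0)

    def test_matches_closed_form_on_5x3_fixture(self):
        cols = {"r1": list("AABBC"), "r2": list("ABBBC"), "r3": list("AABCC")}
        t = rating_table(cols)
        counts = np.zeros((5, 3))
        for k in range(5):
            for r in cols.values():
                counts[k, "ABC".index(r[k])] += 1
        assert fleiss_kappa(t) == pytest.approx(fleiss_closed_form(counts), abs=1e-9)

    def test_two_rater_fleiss_and_cohen_both_defined(self):
        cols = {"r1": list("AABB"), "r2": list("ABBB")}
        t = rating_table(cols)
        fk = fleiss_kappa(t)
        ck = cohen_kappa(t.rater_partition("r1"), t.rater_partition("r2"))
        assert np.isfinite(fk) and np.isfinite(ck)

    def test_incomplete_table_rejected(self):
        t = rating_table({"r1": list("AB"), "r2": list("AB")})
        del t.labels[("w1", "r2")]
        with pytest.raises(InvalidInputError):
            fleiss_kappa(t)


class TestOutlierRaters:
    def test_unanimous_raters_unflagged(self):
        t = rating_table({f"r{k}": list("AABBCC") for k in range(4)})
        assert flag_outlier_raters(t) == []

    def test_lumping_judge_flagged(self):
        base = list("AABBCCDDEE") * 3
        cols = {f"r{k}": base for k in range(5)}
        cols["r5"] = ["X"] * 15 + ["Y"] * 15  # merges everything into 2 labels
        assert flag_outlier_raters(rating_table(cols), threshold=2.0) == ["r5"]

    def test_infinite_threshold_flags_nobody(self):
        cols = {"r1": list("AAB"), "r2": list("ABB"), "r3": list("BBB")}
        assert flag_outlier_raters(rating_table(cols), threshold=np.inf) == []
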