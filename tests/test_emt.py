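"""Quadrant classifier: hand examples, oracle equivalence, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emtquad import (
    ExpressionMatrix,
    MarkerPanel,
    aggregate_marker_score,
    classify_emt_quadrants,
    compare_across_phenotypes,
    phenotype_association_test,
    split_by_median_gene,
)
from emtquad.errors import (
    DegenerateInputError,
    InsufficientCohortError,
    MissingFeatureError,
)

TWO_MARKER_PANEL = MarkerPanel(mesenchymal=("M1",), epithelial=("E1",))


def matrix(samples, **columns):
    return ExpressionMatrix(pd.DataFrame(columns, index=list(samples)))


def from_scores(mes, epi):
    """Expression matrix whose single-marker log2(TPM+1) scores are as given.

    Scores must be >= 0 (they map to TPM = 2^score − 1).
    """
    return matrix([f"S{i}" for i in range(len(mes))],
                  M1=np.exp2(np.asarray(mes, float)) - 1,
                  E1=np.exp2(np.asarray(epi, float)) - 1)


def oracle_classify(mes_scores, epi_scores):
    """Independent brute-force median-split oracle."""
    mes_scores = np.asarray(mes_scores, float)
    epi_scores = np.asarray(epi_scores, float)
    out = []
    for m, e in zip(mes_scores, epi_scores):
        m_top = m > np.median(mes_scores)
        e_top = e > np.median(epi_scores)
        out.append({(True, True): "HighOverlap", (True, False): "Mesenchymal",
                    (False, True): "Epithelial", (False, False): "LowOverlap"
                    }[(m_top, e_top)])
    return out


class TestAggregateScore:
    def test_two_marker_arithmetic(self):
        expr = matrix(["S1"], A=[3.0], B=[1.0])
        score = aggregate_marker_score(expr, ["A", "B"])
        assert score["S1"] == pytest.approx((np.log2(4) + np.log2(2)) / 2)

    def test_single_marker_equals_log2p1(self):
        expr = matrix(["S1", "S2"], A=[7.0, 0.5])
        score = aggregate_marker_score(expr, ["A"])
        np.testing.assert_allclose(score, np.log2(np.array([7.0, 0.5]) + 1))

    def test_all_zero_tpm_scores_zero(self):
        expr = matrix(["S1"], A=[0.0], B=[0.0])
        assert aggregate_marker_score(expr, ["A", "B"])["S1"] == 0.0

    def test_missing_marker_listed(self):
        expr = matrix(["S1"], A=[1.0])
        with pytest.raises(MissingFeatureError, match="NOPE"):
            aggregate_marker_score(expr, ["A", "NOPE"])


class TestClassifier:
    def test_four_corner_example(self):
        expr = from_scores(mes=[10, 1, 10, 1], epi=[10, 10, 1, 1])
        calls = classify_emt_quadrants(expr, TWO_MARKER_PANEL)
        assert list(calls["phenotype"]) == [
            "HighOverlap", "Epithelial", "Mesenchymal", "LowOverlap"]

    def test_identical_samples_all_low_overlap(self):
        expr = from_scores(mes=[2, 2, 2, 2], epi=[3, 3, 3, 3])
        calls = classify_emt_quadrants(expr, TWO_MARKER_PANEL)
        assert (calls["phenotype"] == "LowOverlap").all()

    def test_partition_and_order(self, cohort):
        expr, _, _ = cohort
        calls = classify_emt_quadrants(expr)
        assert list(calls.index) == expr.sample_ids
        assert calls["phenotype"].value_counts().sum() == expr.n_samples
        assert set(calls["phenotype"]) <= {
            "Epithelial", "Mesenchymal", "HighOverlap", "LowOverlap"}

    def test_oracle_equivalence_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(4, 21))
            mes = rng.uniform(0, 6, size=n)
            epi = rng.uniform(0, 6, size=n)
            expr = from_scores(mes, epi)
            calls = classify_emt_quadrants(expr, TWO_MARKER_PANEL)
            assert list(calls["phenotype"]) == oracle_classify(mes, epi)

    def test_score_mode_mean_rank_available(self, cohort):
        expr, _, _ = cohort
        calls = classify_emt_quadrants(expr, score_mode="mean_rank")
        assert calls["phenotype"].value_counts().sum() == expr.n_samples

    def test_too_few_samples(self):
        expr = from_scores(mes=[1, 2], epi=[3, 4])
        with pytest.raises(InsufficientCohortError):
            classify_emt_quadrants(expr, TWO_MARKER_PANEL)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 3).map(lambda x: round(x, 1)),
                    min_size=4, max_size=20),
           st.sampled_from(["cube", "exp", "scale"]))
    def test_monotone_invariance(self, scores, transform):
        """A strictly increasing transform of the scores leaves calls unchanged.

        Scores sit on a 0.1 grid so equal inputs stay exactly tied through
        the TPM round-trip on both sides of the comparison.
        """
        mes = np.asarray(scores)
        epi = np.asarray(scores[::-1])
        f = {"cube": lambda x: x**3 + x, "exp": np.exp,
             "scale": lambda x: 2.5 * x + 7}[transform]
        base = classify_emt_quadrants(from_scores(mes, epi), TWO_MARKER_PANEL)
        fm, fe = f(mes), f(epi)
        fm = fm - fm.min()  # shift back into the valid (>= 0) score range
        fe = fe - fe.min()
        trans = classify_emt_quadrants(from_scores(fm, fe), TWO_MARKER_PANEL)
        assert list(base["phenotype"]) == list(trans["phenotype"])


class TestMedianSplit:
    def test_hand_example(self):
        expr = matrix(["a", "b", "c", "d"], G=[1.0, 2.0, 3.0, 4.0])
        split = split_by_median_gene(expr, "G")
        assert list(split) == ["bottom", "bottom", "top", "top"]

    def test_all_equal_all_bottom(self):
        expr = matrix(["a", "b", "c"], G=[5.0, 5.0, 5.0])
        assert (split_by_median_gene(expr, "G") == "bottom").all()

    def test_two_samples(self):
        expr = matrix(["a", "b"], G=[0.0, 5.0])
        assert list(split_by_median_gene(expr, "G")) == ["bottom", "top"]


class TestPhenotypeAssociation:
    @staticmethod
    def _fast_chi2(pheno_codes, label_codes, n_ph, n_lb):
        table = np.zeros((n_ph, n_lb))
        np.add.at(table, (pheno_codes, label_codes), 1)
        rows = table.sum(1, keepdims=True)
        cols = table.sum(0, keepdims=True)
        exp = rows * cols / table.sum()
        return ((table - exp) ** 2 / exp).sum()

    def test_permutation_oracle_agreement(self, cohort):
        """Asymptotic chi-square p agrees with a label-permutation p-value."""
        expr, clinical, _ = cohort
        calls = classify_emt_quadrants(expr)
        labels = clinical.set_index("sample_id")["histology"]
        res = phenotype_association_test(calls, labels)

        rng = np.random.default_rng(8)
        ph = pd.Categorical(calls["phenotype"]).codes
        lb = pd.Categorical(labels.reindex(calls.index)).codes.copy()
        observed = self._fast_chi2(ph, lb, ph.max() + 1, lb.max() + 1)
        assert observed == pytest.approx(res.statistic, rel=1e-9)
        hits = 0
        for _ in range(2000):
            rng.shuffle(lb)
            if self._fast_chi2(ph, lb, ph.max() + 1, lb.max() + 1) >= observed - 1e-12:
                hits += 1
        perm_p = hits / 2000
        assert perm_p == pytest.approx(res.p, abs=0.02)

    def test_single_level_rejected(self, cohort):
        expr, _, _ = cohort
        calls = classify_emt_quadrants(expr)
        labels = pd.Series("only", index=calls.index)
        with pytest.raises(DegenerateInputError):
            phenotype_association_test(calls, labels)


class TestCompareAcrossPhenotypes:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        expr = from_scores(rng.uniform(0, 6, size=40), rng.uniform(0, 6, size=40))
        calls = classify_emt_quadrants(expr, TWO_MARKER_PANEL)
        # keep only two phenotypes
        keep = calls["phenotype"].isin(["Epithelial", "Mesenchymal"])
        calls = calls[keep]
        values = pd.Series(rng.normal(size=keep.sum()), index=calls.index)
        anova, _ = compare_across_phenotypes(values, calls)
        from emtquad.stats import two_sample_t

        g1 = values[calls["phenotype"] == "Epithelial"]
        g2 = values[calls["phenotype"] == "Mesenchymal"]
        t = two_sample_t(g1, g2)
        assert anova.statistic == pytest.approx(t.statistic**2, rel=1e-9)

    def test_shifted_group_flagged_by_tukey(self, cohort):
        """A value shifted in one phenotype is significant exactly for its pairs."""
        expr, _, _ = cohort
        calls = classify_emt_quadrants(expr)
        rng = np.random.default_rng(2)
        values = pd.Series(rng.normal(size=len(calls)), index=calls.index)
        values[calls["phenotype"] == "HighOverlap"] += 3.0
        anova, tukey = compare_across_phenotypes(values, calls)
        assert anova.p < 1e-6
        for res in tukey:
            pair = res.extra["pair"]
            if "HighOverlap" in pair:
                assert res.p < 0.05, pair
            else:
                assert res.p > 0.05, pair
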