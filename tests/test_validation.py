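"""Validation battery: dispersion, correlations, classification agreement."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trustfuse.errors import DegenerateInputError, InvalidArgumentError, UndefinedStatisticError
from trustfuse.scoring import interrater_kappa
from trustfuse.validation import (
    DEFAULT_THRESHOLDS,
    LEVELS,
    agreement_analysis,
    classify_trust,
    correlation_analysis,
    dispersion_analysis,
    dunn_posthoc,
    epsilon_squared,
    kappa_difference_bootstrap,
    kappa_pvalue,
    tertile_thresholds,
)


def _table(eeg, questionnaire, fused, behavior):
    return pd.DataFrame(
        {"eeg": eeg, "questionnaire": questionnaire, "fused": fused, "behavior": behavior}
    )


def kruskal_bruteforce(groups):
    """Independent H computation: explicit average ranks + tie correction."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size)
    i = 0
    sorted_vals = pooled[order]
    while i < pooled.size:
        j = i
        while j < pooled.size and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average of 1-based ranks i+1..j
        i = j
    n = pooled.size
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


class TestDispersion:
    def test_worked_kruskal_example(self):
        # three spread-out groups of three: H = 7.2 by direct rank arithmetic
        h, _ = stats.kruskal([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert h == pytest.approx(7.2, abs=1e-12)
        assert kruskal_bruteforce([[1, 2, 3], [4, 5, 6], [7, 8, 9]]) == pytest.approx(7.2)

    def test_identical_groups_give_zero_h_and_unit_dunn_p(self):
        groups = {k: np.array([1.0, 2.0, 3.0, 4.0, 5.0]) for k in "abcd"}
        h, _ = stats.kruskal(*groups.values())
        assert h == pytest.approx(0.0, abs=1e-10)
        for res in dunn_posthoc(groups).values():
            assert res.p_value == pytest.approx(1.0)

    def test_h_matches_bruteforce_on_random_data_with_ties(self, rng):
        groups = [np.round(rng.uniform(0, 10, 30), 1) for _ in range(4)]
        h, _ = stats.kruskal(*groups)
        assert h == pytest.approx(kruskal_bruteforce(groups), abs=1e-10)

    def test_rank_invariance_under_monotone_transform(self, rng):
        groups = [rng.normal(loc=m, size=25) for m in (0.0, 0.5, 1.0, 2.0)]
        h0, _ = stats.kruskal(*groups)
        for f in (np.exp, lambda x: x**3, lambda x: 10 * x + 3):
            h1, _ = stats.kruskal(*[f(g) for g in groups])
            assert h1 == pytest.approx(h0, abs=1e-9)

    def test_epsilon_squared_definition(self):
        assert epsilon_squared(16.8, 89) == pytest.approx(16.8 / 88)

    def test_full_battery_structure(self, fused_table):
        out = dispersion_analysis(fused_table)
        assert set(out["variance"]) == {"eeg", "questionnaire", "fused", "behavior"}
        assert len(out["dunn"]) == 6
        assert 0 <= out["kruskal"].p_value <= 1
        assert out["kruskal"].effect_size == pytest.approx(
            out["kruskal"].statistic / (4 * len(fused_table) - 1)
        )

    def test_all_identical_scores_degenerate(self):
        t = _table(*([np.ones(10)] * 4))
        with pytest.raises(DegenerateInputError):
            dispersion_analysis(t)


class TestCorrelation:
    def test_identity_relationship(self):
        x = np.arange(10.0)
        out = correlation_analysis(_table(x, x, x, x))
        for m in out.values():
            assert m["pearson_r"] == pytest.approx(1.0)
            assert m["spearman_rho"] == pytest.approx(1.0)
            assert m["kendall_tau"] == pytest.approx(1.0)

    def test_monotone_nonlinear_relationship(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        out = correlation_analysis(_table(x**3, x**3, x**3, x))
        m = out["eeg"]
        assert m["spearman_rho"] == pytest.approx(1.0)
        assert m["kendall_tau"] == pytest.approx(1.0)
        assert m["pearson_r"] < 1.0

    def test_kendall_matches_exhaustive_pair_counting(self, rng):
        x = rng.integers(0, 6, 25).astype(float)  # heavy ties
        y = rng.integers(0, 6, 25).astype(float)
        n = x.size
        conc = disc = tx = ty = 0
        for i in range(n):
            for j in range(i + 1, n):
                dx, dy = x[i] - x[j], y[i] - y[j]
                if dx == 0 and dy == 0:
                    continue
                if dx == 0:
                    tx += 1
                elif dy == 0:
                    ty += 1
                elif dx * dy > 0:
                    conc += 1
                else:
                    disc += 1
        n0 = n * (n - 1) / 2
        tau_b = (conc - disc) / np.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
        assert stats.kendalltau(x, y).statistic == pytest.approx(tau_b, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            correlation_analysis(_table(np.ones(5), np.arange(5.0), np.arange(5.0), np.arange(5.0)))


def _tie_term(v):
    _, counts = np.unique(v, return_counts=True)
    return float(np.sum(counts * (counts - 1) / 2))


class TestClassification:
    @pytest.mark.parametrize(
        "score,level",
        [(4.0, "Low"), (5.0, "Middle"), (8.0, "High"), (4.5, "Middle"), (7.0, "High"),
         (6.5, "Middle"), (9.0, "High")],
    )
    def test_threshold_labels(self, score, level):
        assert classify_trust(score) == level

    def test_vectorized(self):
        labels = classify_trust(np.array([2.0, 5.0, 9.0]))
        assert list(labels) == ["Low", "Middle", "High"]

    def test_tertile_mode(self, rng):
        scores = rng.uniform(1, 10, 300)
        lo, hi = tertile_thresholds(scores)
        labels = classify_trust(scores, (lo, hi))
        _, counts = np.unique(labels, return_counts=True)
        assert counts.max() - counts.min() <= 3  # near-equal occupancy

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidArgumentError):
            classify_trust(np.nan)


@pytest.fixture(scope="module")
def levels():
    rng = np.random.default_rng(5)
    behavior = rng.choice(LEVELS, size=60, p=(0.4, 0.35, 0.25))

    def noisy(match_p):
        flip = rng.uniform(size=60) > match_p
        out = behavior.copy()
        out[flip] = rng.choice(LEVELS, size=int(flip.sum()))
        return out

    return pd.DataFrame(
        {"eeg": noisy(0.6), "questionnaire": noisy(0.6), "fused": noisy(0.9),
         "behavior": behavior}
    )


class TestAgreement:
    def test_identical_columns_give_unit_kappa(self, levels):
        df = levels.copy()
        df["fused"] = df["behavior"]
        rep = agreement_analysis(df, n_boot=100, seed=0)
        assert rep.kappa_vs_behavior["fused"]["kappa"] == pytest.approx(1.0)

    def test_kappa_from_matrix_equals_kappa_from_labels(self, levels):
        rep = agreement_analysis(levels, n_boot=100, seed=0)
        k_labels = interrater_kappa(levels["eeg"].tolist(), levels["behavior"].tolist())
        assert rep.kappa_vs_behavior["eeg"]["kappa"] == pytest.approx(k_labels, abs=1e-12)

    def test_confusion_rows_sum_to_100(self, levels):
        rep = agreement_analysis(levels, n_boot=100, seed=0)
        sums = rep.confusion_row_pct.sum(axis=1)
        occupied = rep.confusion_counts.sum(axis=1) > 0
        np.testing.assert_allclose(sums[occupied], 100.0, atol=0.1)

    def test_bonferroni_never_lowers_p(self, levels):
        pairs = [("fused", "questionnaire"), ("fused", "eeg"), ("questionnaire", "eeg")]
        rep = agreement_analysis(levels, n_boot=200, seed=0)
        for i, pair in enumerate(pairs):
            raw = kappa_difference_bootstrap(levels, pair, n_boot=200, seed=0 + i)
            adj = rep.pairwise_kappa_p[f"{pair[0]}-{pair[1]}"]
            assert adj == pytest.approx(min(1.0, raw * 3))
            assert adj >= raw - 1e-12

    def test_bootstrap_deterministic_given_seed(self, levels):
        p1 = kappa_difference_bootstrap(levels, ("fused", "eeg"), n_boot=300, seed=9)
        p2 = kappa_difference_bootstrap(levels, ("fused", "eeg"), n_boot=300, seed=9)
        assert p1 == p2

    def test_strong_agreement_small_p(self, levels):
        df = levels.copy()
        df["fused"] = df["behavior"]
        k, p = kappa_pvalue(df["fused"], df["behavior"])
        assert k == pytest.approx(1.0) and p < 1e-6
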