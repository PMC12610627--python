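"""Cross-modality statistical validation.

Given an aligned table of per-event trust scores for the four modalities
(eeg, questionnaire, fused, behavior — behavior is the ground truth), this
module reproduces the analysis battery: per-modality normality and variance,
Kruskal-Wallis dispersion comparison with epsilon-squared effect size and
Dunn-Bonferroni post hoc tests (ANOVA as the parametric complement), the
Pearson/Spearman/Kendall correlation triad against behavior, three-level
trust classification, Cohen's kappa agreement with large-sample p values,
paired-bootstrap kappa comparisons, and the EEG-vs-questionnaire confusion
matrix.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InvalidArgumentError, UndefinedStatisticError
from .scoring import confusion_counts, interrater_kappa, kappa_from_confusion

LEVELS = ("High", "Middle", "Low")  # display order used for confusion matrices
#: Score thresholds separating Low / Middle / High trust on the common scale.
DEFAULT_THRESHOLDS = (4.5, 7.0)
_SCORE_COLUMNS = ("eeg", "questionnaire", "fused", "behavior")


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    effect_size: float | None = None
    posthoc_p: dict[str, float] | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class ClassificationReport:
    kappa_vs_behavior: dict[str, dict[str, float]]
    pairwise_kappa_p: dict[str, float]
    confusion_counts: np.ndarray
    confusion_row_pct: np.ndarray
    levels: tuple[str, ...] = LEVELS

    def to_dict(self) -> dict:
        return {
            "kappa_vs_behavior": self.kappa_vs_behavior,
            "pairwise_kappa_p": self.pairwise_kappa_p,
            "confusion_counts": self.confusion_counts.tolist(),
            "confusion_row_pct": self.confusion_row_pct.tolist(),
            "levels": list(self.levels),
        }


def epsilon_squared(h: float, n_total: int) -> float:
    """Kruskal-Wallis effect size: epsilon² = H / (n - 1)."""
    return h / (n_total - 1)


def dunn_posthoc(groups: dict[str, np.ndarray], *, bonferroni: bool = True) -> dict[str, StatResult]:
    """Dunn's z-tests on pooled mean ranks with tie correction.

    p values are two-sided normal and, by default, Bonferroni-multiplied by
    the number of pairs.
    """
    names = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(data)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in data:
        mean_ranks.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var0 = n_total * (n_total + 1) / 12.0
    m = len(names) * (len(names) - 1) // 2
    out: dict[str, StatResult] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt((var0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0.0:
                raise DegenerateInputError("all pooled observations identical")
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            if bonferroni:
                p = min(1.0, p * m)
            out[f"{names[i]}-{names[j]}"] = StatResult(test="dunn", statistic=float(z), p_value=float(p))
    return out


def dispersion_analysis(table: pd.DataFrame) -> dict:
    """Normality, variances, Kruskal-Wallis (+epsilon², Dunn-Bonferroni), ANOVA."""
    cols = [c for c in _SCORE_COLUMNS if c in table.columns]
    if len(cols) < 2:
        raise InvalidArgumentError("need at least 2 modalities")
    groups = {c: table[c].to_numpy(dtype=float) for c in cols}
    for c, g in groups.items():
        if g.size < 5:
            raise InvalidArgumentError(f"modality {c}: need >= 5 observations")
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0.0:
        raise DegenerateInputError("all scores identical across modalities")
    shapiro = {
        c: StatResult(test="shapiro", statistic=float(r.statistic), p_value=float(r.pvalue))
        for c, r in ((c, stats.shapiro(g)) for c, g in groups.items())
    }
    variances = {c: float(np.var(g, ddof=1)) for c, g in groups.items()}
    try:
        h, p_kw = stats.kruskal(*groups.values())
    except ValueError as exc:  # all identical within scipy's tie correction
        raise DegenerateInputError(str(exc)) from exc
    kruskal = StatResult(
        test="kruskal-wallis",
        statistic=float(h),
        p_value=float(p_kw),
        effect_size=epsilon_squared(float(h), pooled.size),
    )
    f, p_f = stats.f_oneway(*groups.values())
    anova = StatResult(test="anova", statistic=float(f), p_value=float(p_f))
    return {
        "shapiro": shapiro,
        "variance": variances,
        "kruskal": kruskal,
        "dunn": dunn_posthoc(groups),
        "anova": anova,
    }


def correlation_analysis(table: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Pearson r, Spearman rho, Kendall tau-b of each modality against behavior."""
    if "behavior" not in table.columns:
        raise InvalidArgumentError("behavior column (ground truth) is required")
    y = table["behavior"].to_numpy(dtype=float)
    if y.size < 3:
        raise InvalidArgumentError("need >= 3 paired observations")
    out: dict[str, dict[str, float]] = {}
    for c in ("eeg", "questionnaire", "fused"):
        if c not in table.columns:
            continue
        x = table[c].to_numpy(dtype=float)
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            raise UndefinedStatisticError(f"zero variance in {c} or behavior; correlation undefined")
        out[c] = {
            "pearson_r": float(stats.pearsonr(x, y).statistic),
            "spearman_rho": float(stats.spearmanr(x, y).statistic),
            "kendall_tau": float(stats.kendalltau(x, y).statistic),
        }
    return out


def classify_trust(score, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS):
    """Three-level trust label: Low < thresholds[0] <= Middle < thresholds[1] <= High.

    Defaults (4.5, 7.0) place 4 -> Low, 5 and 6.5 -> Middle, 8 -> High,
    matching the narrative use of the labels on the 1-10 scale. Accepts a
    scalar or an array.
    """
    lo, hi = thresholds
    if not lo < hi:
        raise InvalidArgumentError("thresholds must be increasing")
    arr = np.atleast_1d(np.asarray(score, dtype=float))
    if not np.all(np.isfinite(arr)):
        raise InvalidArgumentError("scores must be finite")
    labels = np.where(arr < lo, "Low", np.where(arr < hi, "Middle", "High"))
    return labels[0] if np.isscalar(score) or np.asarray(score).ndim == 0 else labels


def tertile_thresholds(scores) -> tuple[float, float]:
    """Data-driven alternative: thresholds at the pooled 1/3 and 2/3 quantiles."""
    q1, q2 = np.quantile(np.asarray(scores, dtype=float), (1.0 / 3.0, 2.0 / 3.0))
    return float(q1), float(q2)


def kappa_pvalue(labels_a, labels_b) -> tuple[float, float]:
    """Kappa and its large-sample two-sided p value under H0: kappa = 0.

    Uses the asymptotic null standard error from the marginal proportions
    (Fleiss), with z = kappa / se0.
    """
    a, b = list(labels_a), list(labels_b)
    cats = sorted(set(a) | set(b), key=str)
    m = confusion_counts(a, b, cats).astype(float)
    n = m.sum()
    kappa = kappa_from_confusion(m)
    pr = m.sum(axis=1) / n
    pc = m.sum(axis=0) / n
    pe = float(pr @ pc)
    se0 = np.sqrt(max(pe + pe**2 - float(np.sum(pr * pc * (pr + pc))), 0.0)) / ((1.0 - pe) * np.sqrt(n))
    if se0 == 0.0:
        raise UndefinedStatisticError("null standard error of kappa is zero")
    p = 2.0 * stats.norm.sf(abs(kappa / se0))
    return float(kappa), float(p)


def _safe_kappa(a: np.ndarray, b: np.ndarray) -> float:
    cats = sorted(set(a.tolist()) | set(b.tolist()), key=str)
    m = confusion_counts(a.tolist(), b.tolist(), cats).astype(float)
    n = m.sum()
    po = np.trace(m) / n
    pe = float((m.sum(axis=1) / n) @ (m.sum(axis=0) / n))
    return np.nan if pe == 1.0 else (po - pe) / (1.0 - pe)


def kappa_difference_bootstrap(
    levels: pd.DataFrame,
    pair: tuple[str, str],
    *,
    reference: str = "behavior",
    n_boot: int = 2000,
    seed: int = 0,
) -> float:
    """Paired percentile-bootstrap p for kappa(m1, ref) - kappa(m2, ref).

    Rows (observations) are resampled with replacement; both kappas are
    recomputed on each resample and the two-sided p value is the percentile
    position of zero, with the +1 continuity adjustment.
    """
    rng = np.random.default_rng(seed)
    m1, m2 = pair
    ref = levels[reference].to_numpy()
    a = levels[m1].to_numpy()
    b = levels[m2].to_numpy()
    n = ref.size
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        diffs[i] = _safe_kappa(a[idx], ref[idx]) - _safe_kappa(b[idx], ref[idx])
    diffs = diffs[np.isfinite(diffs)]
    nb = diffs.size
    p_lo = (1 + np.sum(diffs <= 0)) / (nb + 1)
    p_hi = (1 + np.sum(diffs >= 0)) / (nb + 1)
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))


def agreement_analysis(
    levels: pd.DataFrame,
    *,
    n_boot: int = 2000,
    seed: int = 0,
) -> ClassificationReport:
    """Kappa of each modality vs behavior, pairwise kappa tests, confusion matrix.

    ``levels`` holds per-observation trust labels in columns eeg,
    questionnaire, fused, behavior. Pairwise kappa differences use a paired
    bootstrap over observations, Bonferroni-corrected for the 3 comparisons;
    the confusion matrix compares EEG (rows) against questionnaire (columns).
    """
    needed = [c for c in ("eeg", "questionnaire", "fused") if c in levels.columns]
    if "behavior" not in levels.columns or len(needed) < 1:
        raise InvalidArgumentError("need behavior plus at least one modality column")
    if len(levels) < 2:
        raise InvalidArgumentError("need >= 2 labelled observations")
    kappas: dict[str, dict[str, float]] = {}
    for c in needed:
        k, p = kappa_pvalue(levels[c], levels["behavior"])
        kappas[c] = {"kappa": k, "p_value": p}
    pairs = [("fused", "questionnaire"), ("fused", "eeg"), ("questionnaire", "eeg")]
    pairwise: dict[str, float] = {}
    present = [p for p in pairs if p[0] in needed and p[1] in needed]
    for i, pr in enumerate(present):
        raw = kappa_difference_bootstrap(levels, pr, n_boot=n_boot, seed=seed + i)
        pairwise[f"{pr[0]}-{pr[1]}"] = min(1.0, raw * len(present))
    counts = confusion_counts(levels["eeg"].tolist(), levels["questionnaire"].tolist(), LEVELS)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row_sums > 0, 100.0 * counts / row_sums, 0.0)
    return ClassificationReport(
        kappa_vs_behavior=kappas,
        pairwise_kappa_p=pairwise,
        confusion_counts=counts,
        confusion_row_pct=pct,
    )
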