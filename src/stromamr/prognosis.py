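"""Master-regulator compound scores, prognostic stratification and survival
statistics.

Per-sample ssGSEA "compound scores" of the mesenchymal and immunoreactive
master-regulator gene sets are dichotomized at the within-dataset median
(strictly above = active; a tie at the median counts as inactive), and the
two activation bits define three prognostic groups:

    immu active, mese inactive  -> 'immu+mese-'  (best outcome)
    immu inactive, mese active  -> 'immu-mese+'  (worst outcome)
    both or neither             -> 'mixed'       (intermediate)

with the double-positive / double-negative subgroups retained for the
both-active versus immu-only contrast. Survival machinery (Kaplan-Meier,
log-rank, univariate proportional hazards with Efron tie handling) is
delegated to lifelines; all tests are two-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .datatypes import ExpressionMatrix, GeneSet, SurvivalTable, bh_adjust
from .enrichment import normalize_scores, ssgsea

logger = logging.getLogger(__name__)

GROUPS = ("immu+mese-", "immu-mese+", "mixed")
SUBGROUPS = ("immu+mese-", "immu-mese+", "immu+mese+", "immu-mese-")


class PrognosisError(ValueError):
    """Invalid input to a survival or stratification operation."""


# ---------------------------------------------------------------------------
# compound scores and stratification


def compound_scores(X: ExpressionMatrix, mese_mrs: GeneSet,
                    immu_mrs: GeneSet, alpha: float = 0.25) -> pd.DataFrame:
    """Raw ssGSEA compound scores of the two MR sets, one row per sample."""
    mese = ssgsea(X, mese_mrs, alpha=alpha)
    immu = ssgsea(X, immu_mrs, alpha=alpha)
    return pd.DataFrame({
        "mese_score": [s.raw for s in mese],
        "immu_score": [s.raw for s in immu],
        "cohort_id": X.dataset_id,
    }, index=pd.Index(X.sample_ids, name="sample_id"))


def dichotomize(scores: pd.Series,
                datasets: pd.Series | None = None) -> pd.Series:
    """True where the score is strictly above its within-dataset median.

    A score equal to the median is assigned low. For even n the median is
    the mean of the two central order statistics, so at most ceil(n/2)
    samples can be high.
    """
    if datasets is None:
        datasets = pd.Series("all", index=scores.index)
    out = pd.Series(False, index=scores.index)
    for _, grp in scores.groupby(datasets):
        if len(grp) < 2:
            raise PrognosisError("need at least 2 samples per dataset "
                                 "to dichotomize")
        if grp.nunique() == 1:
            raise PrognosisError("all scores equal; median split undefined")
        out.loc[grp.index] = grp > grp.median()
    return out


def stratify(mese_active: pd.Series | np.ndarray,
             immu_active: pd.Series | np.ndarray) -> pd.DataFrame:
    """Map the two activation bits to (group, subgroup) per sample."""
    mese = np.asarray(mese_active, dtype=bool)
    immu = np.asarray(immu_active, dtype=bool)
    if mese.shape != immu.shape:
        raise PrognosisError("activation vectors differ in length")
    subgroup = np.where(immu & ~mese, "immu+mese-",
                        np.where(~immu & mese, "immu-mese+",
                                 np.where(immu & mese, "immu+mese+",
                                          "immu-mese-")))
    group = np.where(np.isin(subgroup, ("immu+mese+", "immu-mese-")),
                     "mixed", subgroup)
    index = mese_active.index if isinstance(mese_active, pd.Series) else None
    return pd.DataFrame({"group": group, "subgroup": subgroup}, index=index)


# ---------------------------------------------------------------------------
# survival estimation and tests


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a step table indexed by event/censoring time with columns
    ``survival`` and ``at_risk``. Requires at least one observed event.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise PrognosisError("empty survival input")
    if events.sum() == 0:
        raise PrognosisError("no events observed; KM curve is degenerate")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    out = pd.DataFrame({
        "survival": kmf.survival_function_["KM_estimate"],
        "at_risk": table["at_risk"].reindex(
            kmf.survival_function_.index).ffill(),
    })
    out.index.name = "time"
    return out


def km_median(times, events) -> float:
    kmf = KaplanMeierFitter().fit(np.asarray(times, float),
                                  np.asarray(events, int))
    return float(kmf.median_survival_time_)


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Multi-group log-rank test; returns (chi2, p)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    uniq, counts = np.unique(groups, return_counts=True)
    if uniq.size < 2:
        raise PrognosisError("log-rank needs at least 2 groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def hazard_ratio(times, events, covariate
                 ) -> tuple[float, tuple[float, float], float]:
    """Univariate proportional-hazards fit; returns (HR, CI95, p).

    Partial likelihood with Efron handling of tied event times; HR is per
    unit of the covariate, with a Wald confidence interval and p-value.
    """
    cov = np.asarray(covariate, float)
    if np.ptp(cov) == 0:
        raise PrognosisError("constant covariate; hazard ratio undefined")
    df = pd.DataFrame({"time": np.asarray(times, float),
                       "event": np.asarray(events, int),
                       "x": cov})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:          # lifelines convergence failures
        raise PrognosisError(f"proportional-hazards fit failed: {exc}")
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    p = float(cph.summary.loc["x", "p"])
    ci = (float(np.exp(beta - 1.959963984540054 * se)),
          float(np.exp(beta + 1.959963984540054 * se)))
    return float(np.exp(beta)), ci, p


def forest_table(X: ExpressionMatrix, survival: SurvivalTable,
                 genes) -> pd.DataFrame:
    """Per-gene univariate hazard ratios of z-scored expression."""
    surv = survival.aligned_to(X.sample_ids)
    gidx = X.gene_index()
    rows = []
    for g in genes:
        if g not in gidx:
            continue
        expr = X.values[gidx[g]]
        z = (expr - expr.mean()) / expr.std()
        hr, (lo, hi), p = hazard_ratio(surv["time"], surv["event"], z)
        rows.append((g, hr, lo, hi, p))
    return pd.DataFrame(rows, columns=["gene", "hr", "ci_low", "ci_high",
                                       "p"]).set_index("gene")


# ---------------------------------------------------------------------------
# meta-analysis


@dataclass
class MetaAnalysisResult:
    """Pooled prognostic stratification across cohorts."""

    scores: pd.DataFrame          # per sample: scores, activations, groups
    km_curves: dict[str, pd.DataFrame]
    median_survival: dict[str, float]
    logrank_chi2: float
    logrank_p: float
    contrast_p: float             # immu+mese- vs immu+mese+ log-rank p


def score_and_stratify(X: ExpressionMatrix, mese_mrs: GeneSet,
                       immu_mrs: GeneSet, alpha: float = 0.25
                       ) -> pd.DataFrame:
    """Scores -> per-dataset normalization -> median split -> groups."""
    mese_raw = ssgsea(X, mese_mrs, alpha=alpha)
    immu_raw = ssgsea(X, immu_mrs, alpha=alpha)
    table = pd.DataFrame({
        "mese_score": [s.raw for s in mese_raw],
        "immu_score": [s.raw for s in immu_raw],
        "cohort_id": X.dataset_id,
    }, index=pd.Index(X.sample_ids, name="sample_id"))
    table["mese_norm"] = [s.normalized for s in normalize_scores(mese_raw)]
    table["immu_norm"] = [s.normalized for s in normalize_scores(immu_raw)]
    table["mese_active"] = dichotomize(table["mese_norm"],
                                       table["cohort_id"])
    table["immu_active"] = dichotomize(table["immu_norm"],
                                       table["cohort_id"])
    table = table.join(stratify(table["mese_active"], table["immu_active"]))
    return table


def meta_analyze(cohorts: list[tuple[ExpressionMatrix, SurvivalTable]],
                 mese_mrs: GeneSet, immu_mrs: GeneSet,
                 alpha: float = 0.25) -> MetaAnalysisResult:
    """Pooled three-group survival stratification across >= 2 cohorts.

    Scores are normalized and dichotomized within each cohort, groups are
    pooled, and a single unstratified log-rank test plus pooled per-group
    KM curves are computed, together with the 'immu+mese-' versus
    'immu+mese+' subgroup contrast.
    """
    if len(cohorts) < 2:
        raise PrognosisError("meta-analysis needs at least 2 cohorts")
    frames = []
    for X, surv in cohorts:
        table = score_and_stratify(X, mese_mrs, immu_mrs, alpha=alpha)
        table = table.join(surv.aligned_to(X.sample_ids)
                           .set_index("sample_id")[["time", "event"]])
        frames.append(table.reset_index())
    pooled = pd.concat(frames, ignore_index=True)

    chi2, p = logrank_test(pooled["time"], pooled["event"], pooled["group"])
    km_curves = {}
    medians = {}
    for g, grp in pooled.groupby("group"):
        if grp["event"].sum() > 0:
            km_curves[g] = km_estimate(grp["time"], grp["event"])
        medians[g] = km_median(grp["time"], grp["event"])
    contrast = pooled[pooled["subgroup"].isin(["immu+mese-", "immu+mese+"])]
    if contrast["subgroup"].nunique() == 2:
        _, contrast_p = logrank_test(contrast["time"], contrast["event"],
                                     contrast["subgroup"])
    else:
        contrast_p = float("nan")
    return MetaAnalysisResult(scores=pooled, km_curves=km_curves,
                              median_survival=medians, logrank_chi2=chi2,
                              logrank_p=p, contrast_p=contrast_p)


# ---------------------------------------------------------------------------
# paired/unpaired comparisons and correlations


def compare_scores(scores_a, scores_b, paired: bool
                   ) -> tuple[float, float]:
    """Two-sided comparison of two score samples.

    Paired: Wilcoxon signed-rank with zero differences dropped (all-zero
    differences give p = 1 with a warning). Unpaired: Wilcoxon rank-sum.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if paired:
        if a.size != b.size:
            raise PrognosisError("paired comparison needs equal lengths")
        diffs = a - b
        nonzero = diffs[diffs != 0]
        if nonzero.size == 0:
            logger.warning("all paired differences are zero; p = 1")
            return 0.0, 1.0
        if nonzero.size < 3:
            raise PrognosisError("fewer than 3 non-zero paired differences")
        stat, p = stats.wilcoxon(nonzero, alternative="two-sided")
        return float(stat), float(p)
    if a.size < 3 or b.size < 3:
        raise PrognosisError("need at least 3 observations per group")
    stat, p = stats.ranksums(a, b)
    return float(stat), float(p)


def correlate_score_genes(scores: pd.Series, X: ExpressionMatrix,
                          gene_list) -> pd.DataFrame:
    """Spearman correlation of a compound score with listed genes.

    BH correction across the list; genes with constant expression get
    missing rho/p and are excluded from the correction.
    """
    gidx = X.gene_index()
    missing = [g for g in gene_list if g not in gidx]
    if missing:
        raise PrognosisError(f"genes absent from matrix: {missing[:5]}")
    aligned = scores.loc[list(X.sample_ids)].to_numpy(float)
    rows = []
    for g in gene_list:
        expr = X.values[gidx[g]]
        if np.ptp(expr) == 0:
            rows.append((g, np.nan, np.nan))
            continue
        rho, p = stats.spearmanr(aligned, expr)
        rows.append((g, float(rho), float(p)))
    df = pd.DataFrame(rows, columns=["gene", "rho", "p"]).set_index("gene")
    valid = df["p"].notna()
    df["p_adj"] = np.nan
    df.loc[valid, "p_adj"] = bh_adjust(df.loc[valid, "p"].to_numpy())
    return df
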