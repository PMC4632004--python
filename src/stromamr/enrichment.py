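"""Gene-set enrichment engines: GSEA, single-sample GSEA and stromal/immune
(ESTIMATE-style) scoring.

GSEA here operates on a precomputed signed gene ranking (e.g. a paired
stroma-minus-epithelium difference), with a weighted Kolmogorov-Smirnov
running sum and a gene-label permutation null. ssGSEA scores one sample at a
time from the rank difference of the empirical cumulative distribution of
set members versus the remaining genes, with member ranks weighted by
``rank ** alpha`` (alpha = 0.25 by default, the method's canonical
exponent). Ties in expression are broken by stable gene order so scores are
deterministic across platforms.

Per-dataset score normalization divides by (max - min) of the raw scores
within each dataset, which makes scores comparable before pooling cohorts;
an alternative that also subtracts the minimum is available via ``mode``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSet, bh_adjust

logger = logging.getLogger(__name__)

MIN_OVERLAP = 3


class EnrichmentError(ValueError):
    """Inputs cannot support the requested enrichment computation."""


@dataclass
class EnrichmentResult:
    """Outcome of one GSEA test."""

    es: float
    nes: float
    p: float
    fdr_q: float
    leading_edge: list[str]

    def __post_init__(self) -> None:
        if not -1.0 <= self.es <= 1.0 + 1e-12:
            raise ValueError(f"ES out of range: {self.es}")


@dataclass
class SampleScore:
    """A per-sample gene-set score, raw and (optionally) normalized."""

    sample_id: str
    raw: float
    dataset_id: str
    set_name: str
    normalized: float | None = None


# ---------------------------------------------------------------------------
# GSEA


def _ordered_ranking(ranking: Mapping[str, float] | pd.Series
                     ) -> tuple[list[str], np.ndarray]:
    ser = pd.Series(dict(ranking)) if not isinstance(ranking, pd.Series) \
        else ranking.astype(float)
    ser = ser.iloc[np.lexsort((ser.index, -ser.to_numpy()))]
    return list(ser.index), ser.to_numpy(float)


def _running_es(is_hit: np.ndarray, weights: np.ndarray) -> tuple[float, int]:
    """Max-deviation enrichment score and the peak position."""
    n = is_hit.size
    n_hit = int(is_hit.sum())
    hit_w = np.abs(weights) * is_hit
    denom = hit_w.sum()
    if denom == 0:
        hit_w = is_hit.astype(float)
        denom = float(n_hit)
    steps = hit_w / denom - (~is_hit) / float(n - n_hit)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak


def gsea(ranking: Mapping[str, float] | pd.Series, gene_set: GeneSet,
         weight_p: float = 1.0, n_permutations: int = 1000,
         seed: int = 0, min_overlap: int = MIN_OVERLAP) -> EnrichmentResult:
    """Weighted-KS enrichment of a gene set in a signed ranking.

    Significance is assessed by gene-label permutation: random member sets
    of the same size are drawn from the ranked universe, and the p-value is
    the same-sign tail fraction. NES divides the observed ES by the mean
    |null ES| of matching sign.
    """
    genes, values = _ordered_ranking(ranking)
    members = gene_set.intersect(genes)
    if len(members) < min_overlap:
        raise EnrichmentError(
            f"gene set {gene_set.name!r} shares only {len(members)} genes "
            f"with the ranking (floor {min_overlap})")
    if len(members) == len(genes):
        raise EnrichmentError("gene set covers the entire ranking")
    is_hit = np.array([g in members for g in genes])
    weights = np.sign(values) * np.abs(values) ** weight_p
    es, peak = _running_es(is_hit, weights)

    rng = np.random.default_rng(seed)
    n, k = len(genes), len(members)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm_hit = np.zeros(n, dtype=bool)
        perm_hit[rng.choice(n, size=k, replace=False)] = True
        null[b], _ = _running_es(perm_hit, weights)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same_sign.size:
        p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + same_sign.size)
        nes = es / np.mean(np.abs(same_sign))
    else:
        p, nes = 1.0 / (1 + n_permutations), 0.0

    if es >= 0:
        leading = [g for g, h in zip(genes[:peak + 1], is_hit[:peak + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[peak:], is_hit[peak:]) if h]
    return EnrichmentResult(es=es, nes=float(nes), p=float(p),
                            fdr_q=float(p), leading_edge=leading)


def gsea_many(ranking: Mapping[str, float] | pd.Series,
              gene_sets: Sequence[GeneSet], weight_p: float = 1.0,
              n_permutations: int = 1000, seed: int = 0
              ) -> dict[str, EnrichmentResult]:
    """GSEA over several gene sets with BH FDR across the sets tested."""
    results = {gs.name: gsea(ranking, gs, weight_p, n_permutations,
                             seed=seed + i)
               for i, gs in enumerate(gene_sets)}
    qs = bh_adjust(np.array([r.p for r in results.values()]))
    return {name: replace(res, fdr_q=float(q))
            for (name, res), q in zip(results.items(), qs)}


# ---------------------------------------------------------------------------
# ssGSEA


def _sample_ranks(column: np.ndarray) -> np.ndarray:
    """Descending-order positions; ties broken by stable gene order.

    Returns, for each position in the descending ordering, the original gene
    index (i.e. order[0] is the top-expressed gene).
    """
    return np.argsort(-column, kind="stable")


def ssgsea(X: ExpressionMatrix, gene_set: GeneSet, alpha: float = 0.25,
           min_overlap: int = MIN_OVERLAP) -> list[SampleScore]:
    """Single-sample GSEA scores for one gene set.

    Per sample, genes are ordered by decreasing expression; the score is the
    summed difference between the weighted in-set ECDF (member at descending
    position i carries weight ``(N - i)
    ** alpha`` with i zero-based, i.e. rank N for the top gene) and the
    uniform out-of-set ECDF.
    """
    members = gene_set.intersect(X.gene_ids)
    if len(members) < min_overlap:
        raise EnrichmentError(
            f"gene set {gene_set.name!r} shares only {len(members)} genes "
            f"with the expression matrix (floor {min_overlap})")
    if len(members) == X.n_genes:
        raise EnrichmentError("gene set covers every gene in the matrix")
    n = X.n_genes
    is_member = np.array([g in members for g in X.gene_ids])
    rank_weight = (np.arange(n, 0, -1, dtype=float)) ** alpha
    scores: list[SampleScore] = []
    for j, sid in enumerate(X.sample_ids):
        col = X.values[:, j]
        if np.ptp(col) == 0:
            logger.warning("sample %r has constant expression; ssGSEA uses "
                           "tie-broken ranks", sid)
        order = _sample_ranks(col)
        hit = is_member[order]
        w = np.where(hit, rank_weight, 0.0)
        p_in = np.cumsum(w)
        p_in /= p_in[-1]
        p_out = np.cumsum(~hit) / float(n - len(members))
        scores.append(SampleScore(sample_id=sid,
                                  raw=float(np.sum(p_in - p_out)),
                                  dataset_id=X.dataset_id,
                                  set_name=gene_set.name))
    return scores


def scores_frame(scores: Sequence[SampleScore]) -> pd.DataFrame:
    """Tabulate SampleScore records (one row per sample/set)."""
    return pd.DataFrame([vars(s) for s in scores])


def normalize_scores(scores: Sequence[SampleScore],
                     mode: str = "scale") -> list[SampleScore]:
    """Normalize raw scores within each dataset.

    mode="scale" (default) divides by the dataset's (max - min) raw score;
    mode="minmax" additionally subtracts the minimum, mapping onto [0, 1].
    Relative order within a dataset is preserved either way.
    """
    if mode not in ("scale", "minmax"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    by_dataset: dict[str, list[SampleScore]] = {}
    for s in scores:
        by_dataset.setdefault(s.dataset_id, []).append(s)
    out: list[SampleScore] = []
    for dataset, group in by_dataset.items():
        raws = np.array([s.raw for s in group])
        span = raws.max() - raws.min()
        if span == 0:
            raise EnrichmentError(
                f"dataset {dataset!r}: all raw scores equal; cannot "
                "normalize by max - min")
        for s in group:
            norm = (s.raw - raws.min()) / span if mode == "minmax" \
                else s.raw / span
            out.append(replace(s, normalized=float(norm)))
    return out


# ---------------------------------------------------------------------------
# ESTIMATE-style stromal/immune scoring


def estimate_scores(X: ExpressionMatrix, stromal_set: GeneSet,
                    immune_set: GeneSet, alpha: float = 0.25) -> pd.DataFrame:
    """Stromal, immune and combined infiltration scores per sample.

    Both component scores are ssGSEA scores of the supplied signatures; the
    combined score is their sum and tracks total non-tumor content.
    """
    stromal = ssgsea(X, stromal_set, alpha=alpha)
    immune = ssgsea(X, immune_set, alpha=alpha)
    df = pd.DataFrame({
        "sample_id": [s.sample_id for s in stromal],
        "stromal": [s.raw for s in stromal],
        "immune": [s.raw for s in immune],
    })
    df["combined"] = df["stromal"] + df["immune"]
    return df.set_index("sample_id")
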