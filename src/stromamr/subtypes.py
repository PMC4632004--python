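"""Consensus molecular subtyping and subtype signature derivation.

The stage mirrors the classical expression-subtyping workflow: non-negative
matrix factorization (NMF) or k-means, run repeatedly on column subsamples
to build a consensus matrix; hierarchical clustering of the consensus for
final labels and the cophenetic coefficient for rank selection; silhouette
filtering (on 1 - consensus) to keep only core samples; a multiclass
SAM-like permutation statistic to find subtype-differential genes; and a
nearest-shrunken-centroid (PAM) classifier whose shrinkage is chosen by
cross-validation, yielding the subtype signature gene lists.

NMF is made applicable to log2 data by shifting each gene by its minimum,
which preserves within-gene ordering. Multiplicative updates run until the
relative objective change drops below 1e-6 (at most 500 iterations); the
objective is asserted non-increasing at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedKFold

from .datatypes import ExpressionMatrix, GeneSet


class SubtypeError(ValueError):
    """Invalid input to a subtype-discovery operation."""


# ---------------------------------------------------------------------------
# NMF


def _shift_nonnegative(values: np.ndarray) -> np.ndarray:
    return values - values.min(axis=1, keepdims=True)


def nmf_factorize(X: ExpressionMatrix, k: int, n_restarts: int = 5,
                  seed: int = 0, max_iter: int = 500, tol: float = 1e-6
                  ) -> tuple[np.ndarray, np.ndarray, pd.Series]:
    """Rank-k NMF of the min-shifted expression matrix.

    Multiplicative (Frobenius) updates, best of ``n_restarts`` random
    initializations by final objective. Sample labels are the argmax
    metagene of H.
    """
    if k < 2:
        raise SubtypeError("k must be >= 2")
    if k > min(X.n_genes, X.n_samples):
        raise SubtypeError(f"k={k} exceeds matrix dimensions {X.values.shape}")
    V = _shift_nonnegative(X.values)
    zero_rows = np.flatnonzero(V.sum(axis=1) == 0)
    if zero_rows.size:
        raise SubtypeError(
            f"all-zero rows after min-shift (constant genes), e.g. "
            f"{X.gene_ids[zero_rows[0]]!r}; filter constant genes first")
    rng = np.random.default_rng(seed)
    eps = 1e-12
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    scale = np.sqrt(V.mean() / k)
    for _ in range(n_restarts):
        W = rng.uniform(eps, 1.0, size=(V.shape[0], k)) * scale
        H = rng.uniform(eps, 1.0, size=(k, V.shape[1])) * scale
        obj = 0.5 * np.linalg.norm(V - W @ H) ** 2
        for _ in range(max_iter):
            H *= (W.T @ V) / (W.T @ W @ H + eps)
            W *= (V @ H.T) / (W @ (H @ H.T) + eps)
            new_obj = 0.5 * np.linalg.norm(V - W @ H) ** 2
            assert new_obj <= obj * (1 + 1e-9), "NMF objective increased"
            if obj > 0 and (obj - new_obj) / obj < tol:
                obj = new_obj
                break
            obj = new_obj
        if best is None or obj < best[0]:
            best = (obj, W, H)
    _, W, H = best
    labels = pd.Series(np.argmax(H, axis=0), index=X.sample_ids,
                       name="metagene")
    return W, H, labels


# ---------------------------------------------------------------------------
# consensus clustering


@dataclass
class ConsensusResult:
    k: int
    consensus_matrix: pd.DataFrame
    labels: pd.Series
    cophenetic: float
    method: str

    def __post_init__(self) -> None:
        c = self.consensus_matrix.to_numpy()
        if not np.allclose(c, c.T):
            raise SubtypeError("consensus matrix not symmetric")
        if c.min() < -1e-9 or c.max() > 1 + 1e-9:
            raise SubtypeError("consensus entries outside [0, 1]")
        if not np.allclose(np.diag(c), 1.0):
            raise SubtypeError("consensus diagonal must be 1")


def _cluster_once(values: np.ndarray, sample_ids: list[str], k: int,
                  method: str, seed: int) -> np.ndarray:
    if method == "nmf":
        em = ExpressionMatrix([f"g{i}" for i in range(values.shape[0])],
                              sample_ids, values)
        _, _, labels = nmf_factorize(em, k, n_restarts=1, seed=seed)
        return labels.to_numpy()
    if method == "kmeans":
        km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                    random_state=seed % (2 ** 31))
        return km.fit_predict(values.T)
    raise SubtypeError(f"unknown clustering method {method!r}")


def consensus_cluster(X: ExpressionMatrix, k_range, method: str = "nmf",
                      n_reps: int = 20, subsample_fraction: float = 0.8,
                      seed: int = 0) -> list[ConsensusResult]:
    """Consensus clustering over a range of k.

    For each k, the clustering is repeated on random column subsamples;
    consensus[i, j] is the co-clustering count divided by the co-sampling
    count. Final labels come from average-linkage hierarchical clustering of
    1 - consensus; the cophenetic correlation of that dendrogram against
    1 - consensus is reported for rank selection.
    """
    if n_reps < 2:
        raise SubtypeError("n_reps must be >= 2")
    if not 0 < subsample_fraction <= 1:
        raise SubtypeError("subsample_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    m = X.n_samples
    n_sub = max(2, int(round(subsample_fraction * m)))
    results = []
    for k in k_range:
        together = np.zeros((m, m))
        sampled = np.zeros((m, m))
        for rep in range(n_reps):
            if subsample_fraction < 1.0:
                cols = np.sort(rng.choice(m, size=n_sub, replace=False))
            else:
                cols = np.arange(m)
            labels = _cluster_once(
                X.values[:, cols], [X.sample_ids[c] for c in cols], k,
                method, seed=int(rng.integers(0, 2 ** 31)))
            same = labels[:, None] == labels[None, :]
            together[np.ix_(cols, cols)] += same
            sampled[np.ix_(cols, cols)] += 1
        off_diag = ~np.eye(m, dtype=bool)
        if (sampled[off_diag] == 0).any():
            raise SubtypeError(
                "some sample pairs were never co-subsampled; increase "
                "n_reps or subsample_fraction")
        consensus = np.where(sampled > 0, together / np.maximum(sampled, 1),
                             0.0)
        consensus = 0.5 * (consensus + consensus.T)
        np.fill_diagonal(consensus, 1.0)
        dist = 1.0 - consensus
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        link = hierarchy.linkage(condensed, method="average")
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust") - 1
        coph_corr, _ = hierarchy.cophenet(link, condensed)
        results.append(ConsensusResult(
            k=k,
            consensus_matrix=pd.DataFrame(consensus, index=X.sample_ids,
                                          columns=X.sample_ids),
            labels=pd.Series(labels, index=X.sample_ids, name="cluster"),
            cophenetic=float(coph_corr),
            method=method,
        ))
    return results


# ---------------------------------------------------------------------------
# silhouette filtering


def silhouette_filter(dissimilarity: np.ndarray | pd.DataFrame,
                      labels: pd.Series | np.ndarray
                      ) -> tuple[list, pd.Series]:
    """Silhouette widths and the core samples (width > 0).

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a the mean within-cluster
    dissimilarity and b the smallest mean dissimilarity to another cluster.
    Members of singleton clusters get width 0 (flagged via a warning-free
    convention: they are simply not core).
    """
    if isinstance(dissimilarity, pd.DataFrame):
        ids = list(dissimilarity.index)
        D = dissimilarity.to_numpy(float)
    else:
        D = np.asarray(dissimilarity, float)
        ids = list(labels.index) if isinstance(labels, pd.Series) \
            else list(range(D.shape[0]))
    lab = np.asarray(labels.to_numpy() if isinstance(labels, pd.Series)
                     else labels)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise SubtypeError("dissimilarity must be square and symmetric")
    if not np.allclose(np.diag(D), 0):
        raise SubtypeError("dissimilarity diagonal must be zero")
    clusters = np.unique(lab)
    if clusters.size < 2:
        raise SubtypeError("need at least 2 clusters")
    n = D.shape[0]
    widths = np.zeros(n)
    for i in range(n):
        own = lab == lab[i]
        n_own = own.sum()
        if n_own == 1:
            widths[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, lab == c].mean() for c in clusters if c != lab[i])
        denom = max(a, b)
        widths[i] = 0.0 if denom == 0 else (b - a) / denom
    series = pd.Series(widths, index=ids, name="silhouette_width")
    core = [ids[i] for i in range(n) if widths[i] > 0]
    return core, series


# ---------------------------------------------------------------------------
# SAM-like multiclass differential statistic


def _class_layout(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes, inv = np.unique(labels, return_inverse=True)
    onehot = np.equal.outer(inv, np.arange(classes.size)).astype(float)
    return classes, onehot


def _sam_d(values: np.ndarray, onehot: np.ndarray, s0: float | None
           ) -> tuple[np.ndarray, float]:
    n_k = onehot.sum(axis=0)
    n = values.shape[1]
    K = n_k.size
    means_k = (values @ onehot) / n_k
    grand = values.mean(axis=1, keepdims=True)
    between = np.sqrt(((means_k - grand) ** 2 * n_k).sum(axis=1) / (K - 1))
    resid_sq = ((values - means_k[:, np.argmax(onehot, axis=1)]) ** 2)
    pooled_sd = np.sqrt(resid_sq.sum(axis=1) / (n - K))
    se = pooled_sd * np.sqrt((1.0 / n_k).sum() / K)
    if s0 is None:
        s0 = float(np.median(se))
    return between / (se + s0), s0


def sam_multiclass(X: ExpressionMatrix, labels: pd.Series | np.ndarray,
                   n_permutations: int = 300, seed: int = 0,
                   s0: float | None = None) -> pd.DataFrame:
    """Multiclass SAM-like statistic with permutation q-values.

    d is a between-class contrast standardized by the per-gene pooled
    standard error plus a fudge constant s0 (median of the standard errors).
    q(gene) is the median null count of |d*| >= |d_gene| across label
    permutations divided by the observed count at that threshold, clamped to
    [0, 1] and made monotone in |d|.
    """
    lab = np.asarray(labels.to_numpy() if isinstance(labels, pd.Series)
                     else labels)
    if lab.size != X.n_samples:
        raise SubtypeError("labels length does not match sample count")
    classes, onehot = _class_layout(lab)
    if classes.size < 2:
        raise SubtypeError("need at least 2 classes")
    if (onehot.sum(axis=0) < 2).any():
        raise SubtypeError("every class needs at least 2 samples")
    d, s0_used = _sam_d(X.values, onehot, s0)
    abs_d = np.abs(d)

    rng = np.random.default_rng(seed)
    null_counts = np.empty((n_permutations, X.n_genes))
    for b in range(n_permutations):
        perm = rng.permutation(lab)
        _, perm_onehot = _class_layout(perm)
        d_null, _ = _sam_d(X.values, perm_onehot, s0_used)
        sorted_null = np.sort(np.abs(d_null))
        null_counts[b] = sorted_null.size - np.searchsorted(
            sorted_null, abs_d, side="left")
    med_null = np.median(null_counts, axis=0)
    sorted_abs = np.sort(abs_d)
    observed = abs_d.size - np.searchsorted(sorted_abs, abs_d, side="left")
    q = np.clip(med_null / np.maximum(observed, 1), 0.0, 1.0)
    # monotone: a larger |d| never gets a larger q
    order = np.argsort(-abs_d, kind="stable")
    q[order] = np.maximum.accumulate(q[order])
    return pd.DataFrame({"d": d, "q": q}, index=X.gene_ids)


# ---------------------------------------------------------------------------
# PAM (nearest shrunken centroids)


@dataclass
class SubtypeSignature:
    """A trained nearest-shrunken-centroid classifier and its gene lists."""

    classes: list
    genes: list[str]
    overall_centroid: np.ndarray = field(repr=False)
    shrunken_centroids: np.ndarray = field(repr=False)   # genes x classes
    scale: np.ndarray = field(repr=False)                # s_i + s0 per gene
    pam_threshold: float = 0.0
    cv_error_curve: pd.DataFrame | None = None
    resubstitution_error: float = float("nan")
    sam_stats: pd.DataFrame | None = None
    up_sets: dict = field(default_factory=dict)          # class -> GeneSet

    @property
    def signature_genes(self) -> list[str]:
        diff = self.shrunken_centroids - self.overall_centroid[:, None]
        keep = np.any(np.abs(diff) > 1e-12, axis=1)
        return [g for g, k in zip(self.genes, keep) if k]


def _pam_fit(values: np.ndarray, onehot: np.ndarray, delta: float
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shrunken centroids for one Δ; returns (overall, shrunken, scale)."""
    n_k = onehot.sum(axis=0)
    n = values.shape[1]
    means_k = (values @ onehot) / n_k
    overall = values.mean(axis=1)
    resid_sq = ((values - means_k[:, np.argmax(onehot, axis=1)]) ** 2)
    s = np.sqrt(resid_sq.sum(axis=1) / (n - n_k.size))
    s0 = float(np.median(s))
    scale = s + s0
    m_k = np.sqrt(1.0 / n_k - 1.0 / n)
    d_ik = (means_k - overall[:, None]) / (scale[:, None] * m_k[None, :])
    d_shr = np.sign(d_ik) * np.maximum(np.abs(d_ik) - delta, 0.0)
    shrunken = overall[:, None] + scale[:, None] * m_k[None, :] * d_shr
    return overall, shrunken, scale


def _pam_predict_values(values: np.ndarray, overall: np.ndarray,
                        shrunken: np.ndarray, scale: np.ndarray
                        ) -> np.ndarray:
    """Class index per column by discriminant distance (uniform priors)."""
    # discriminant: sum_i (x_i - c_ik)^2 / scale_i^2
    xs = values / scale[:, None]
    cs = shrunken / scale[:, None]
    d2 = (np.einsum("ij,ij->j", xs, xs)[:, None]
          - 2.0 * xs.T @ cs + np.einsum("ik,ik->k", cs, cs)[None, :])
    return np.argmin(d2, axis=1)


def pam_train(X: ExpressionMatrix, labels: pd.Series | np.ndarray,
              delta_grid: np.ndarray | None = None, cv_folds: int = 5,
              seed: int = 0, sam_stats: pd.DataFrame | None = None
              ) -> SubtypeSignature:
    """Train a nearest-shrunken-centroid classifier with CV-chosen Δ.

    The shrinkage Δ minimizing stratified cross-validation error is chosen
    (ties broken toward the largest, most parsimonious Δ). Genes with any
    surviving shrunken component form the signature; each signature gene is
    assigned to the class of its largest positive shrunken deviation,
    yielding disjoint per-class up-regulated lists.
    """
    lab = np.asarray(labels.to_numpy() if isinstance(labels, pd.Series)
                     else labels)
    classes, onehot = _class_layout(lab)
    if (onehot.sum(axis=0) < cv_folds).any():
        raise SubtypeError(
            f"every class needs at least cv_folds={cv_folds} samples")
    V = X.values
    if delta_grid is None:
        _, _, scale0 = _pam_fit(V, onehot, 0.0)
        n_k = onehot.sum(axis=0)
        m_k = np.sqrt(1.0 / n_k - 1.0 / V.shape[1])
        means_k = (V @ onehot) / n_k
        d_max = np.abs((means_k - V.mean(axis=1)[:, None])
                       / (scale0[:, None] * m_k[None, :])).max()
        delta_grid = np.linspace(0.0, float(d_max), 30)

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                          random_state=seed % (2 ** 31))
    class_index = np.argmax(onehot, axis=1)
    errors = np.zeros(len(delta_grid))
    for train, test in skf.split(V.T, class_index):
        _, tr_onehot = _class_layout(lab[train])
        for di, delta in enumerate(delta_grid):
            ov, sh, sc = _pam_fit(V[:, train], tr_onehot, delta)
            pred = _pam_predict_values(V[:, test], ov, sh, sc)
            errors[di] += np.sum(pred != class_index[test])
    errors /= V.shape[1]
    best_err = errors.min()
    # ties -> largest delta
    best_delta = float(max(delta_grid[np.isclose(errors, best_err)]))

    overall, shrunken, scale = _pam_fit(V, onehot, best_delta)
    diff = shrunken - overall[:, None]
    surviving = np.any(np.abs(diff) > 1e-12, axis=1)
    if not surviving.any():
        raise SubtypeError(
            f"Δ={best_delta:.3g} shrinks every gene away; the grid reaches "
            "too far")
    resub = float(np.mean(_pam_predict_values(V, overall, shrunken, scale)
                          != class_index))
    up_sets: dict = {}
    for gi in np.flatnonzero(surviving):
        pos = diff[gi]
        if pos.max() <= 0:
            continue
        cls = classes[int(np.argmax(pos))]
        up_sets.setdefault(cls, set()).add(X.gene_ids[gi])
    up_genesets = {c: GeneSet(f"{c}_up", f"up-regulated in {c}",
                              frozenset(genes))
                   for c, genes in up_sets.items()}
    return SubtypeSignature(
        classes=list(classes),
        genes=list(X.gene_ids),
        overall_centroid=overall,
        shrunken_centroids=shrunken,
        scale=scale,
        pam_threshold=best_delta,
        cv_error_curve=pd.DataFrame({"delta": delta_grid, "cv_error": errors}),
        resubstitution_error=resub,
        sam_stats=sam_stats,
        up_sets=up_genesets,
    )


def pam_predict(signature: SubtypeSignature, X: ExpressionMatrix,
                min_overlap: float = 0.8) -> pd.Series:
    """Classify samples with a trained shrunken-centroid signature.

    Requires at least ``min_overlap`` of the classifier's genes to be
    present; missing genes are dropped from the discriminant.
    """
    gidx = X.gene_index()
    present = [i for i, g in enumerate(signature.genes) if g in gidx]
    frac = len(present) / len(signature.genes)
    if frac < min_overlap:
        missing = [g for g in signature.genes if g not in gidx][:10]
        raise SubtypeError(
            f"only {frac:.0%} of classifier genes present "
            f"(floor {min_overlap:.0%}); missing e.g. {missing}")
    rows = [gidx[signature.genes[i]] for i in present]
    pred = _pam_predict_values(
        X.values[rows],
        signature.overall_centroid[present],
        signature.shrunken_centroids[present],
        signature.scale[present])
    return pd.Series([signature.classes[p] for p in pred],
                     index=X.sample_ids, name="subtype")
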