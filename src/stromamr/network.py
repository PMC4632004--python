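"""Reverse engineering of transcription-factor regulons and master-regulator
analysis (MRA).

The network is inferred ARACNe-style: mutual information (MI) between each
TF and every candidate target, a permutation null (the TF profile is
shuffled, giving one pooled null MI distribution per TF), Benjamini-Hochberg
correction within each TF's tests, bootstrap pruning of unstable edges, and
the Data Processing Inequality (DPI) to delete the weakest edge of every
fully connected (TF, TF, target) triplet — the likely indirect interaction.

MI is estimated by equal-frequency binning of the rank-transformed vectors
(plug-in estimator, natural log, so values are in nats). With ``b`` bins the
estimate carries an O(b^2/n) positive bias; the permutation null carries the
same bias, so edge calls are bias-matched.

Master regulators are TFs whose regulon overlaps a subtype signature more
than chance, scored with the hypergeometric tail probability over the
network's target universe and BH-corrected across TFs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GeneSet, bh_adjust
from .enrichment import EnrichmentResult, gsea


class NetworkError(ValueError):
    """Invalid input to a network-inference operation."""


@dataclass(frozen=True)
class Edge:
    """One TF-target interaction."""

    mi: float                       # nats, >= 0
    mode: int                       # +1 activated, -1 repressed
    bootstrap_support: float = 1.0  # fraction of bootstraps retaining it

    def __post_init__(self) -> None:
        if self.mi < 0:
            raise NetworkError(f"negative MI {self.mi}")
        if self.mode not in (-1, 1):
            raise NetworkError(f"mode must be +1 or -1, got {self.mode}")
        if not 0.0 <= self.bootstrap_support <= 1.0:
            raise NetworkError("bootstrap support outside [0, 1]")


@dataclass
class Regulon:
    """A TF with its inferred target set."""

    tf: str
    targets: dict[str, Edge]

    def __post_init__(self) -> None:
        if self.tf in self.targets:
            raise NetworkError(f"regulon of {self.tf!r} contains itself")

    def __len__(self) -> int:
        return len(self.targets)

    def target_set(self) -> frozenset[str]:
        return frozenset(self.targets)


@dataclass
class TranscriptionalNetwork:
    regulons: list[Regulon]
    universe: set[str]
    params: dict = field(default_factory=dict)
    # minimum accepted MI per TF, kept so bootstrap re-tests reuse the
    # original significance cutoff
    mi_thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for reg in self.regulons:
            stray = reg.target_set() - self.universe
            if stray:
                raise NetworkError(
                    f"regulon {reg.tf!r} has targets outside the universe: "
                    f"{sorted(stray)[:5]}")

    def regulon(self, tf: str) -> Regulon:
        for reg in self.regulons:
            if reg.tf == tf:
                return reg
        raise KeyError(tf)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(r.tf, t) for r in self.regulons for t in r.targets}

    def n_edges(self) -> int:
        return sum(len(r) for r in self.regulons)


# ---------------------------------------------------------------------------
# mutual information


def _equal_frequency_bins(v: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin indices from ordinal ranks; deterministic under ties."""
    order = np.argsort(v, kind="stable")
    ranks = np.empty(v.size, dtype=np.int64)
    ranks[order] = np.arange(v.size)
    return (ranks * n_bins) // v.size


def default_bins(n: int) -> int:
    return max(2, int(math.floor(n ** (1.0 / 3.0))))


def mutual_information(x: np.ndarray, y: np.ndarray,
                       n_bins: int | None = None) -> float:
    """Plug-in MI (nats) between two vectors via equal-frequency binning.

    Both vectors are rank-transformed and partitioned into ``n_bins``
    (default floor(n^(1/3)), at least 2) equal-count bins.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise NetworkError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 20:
        raise NetworkError(f"need at least 20 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise NetworkError("constant vector has undefined MI")
    b = n_bins or default_bins(n)
    bx = _equal_frequency_bins(x, b)
    by = _equal_frequency_bins(y, b)
    counts = np.bincount(bx * b + by, minlength=b * b).reshape(b, b)
    # exact summation makes MI(x, y) == MI(y, x) bit-for-bit
    p = counts / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    terms = [p[i, j] * math.log(p[i, j] / (px[i] * py[j]))
             for i in range(b) for j in range(b) if counts[i, j] > 0]
    return math.fsum(terms)


def _mi_from_counts(counts: np.ndarray) -> np.ndarray:
    """MI for a stack of contingency tables, shape (g, b, b) -> (g,)."""
    n = counts.sum(axis=(1, 2), keepdims=True).astype(float)
    p = counts / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log(p / (px * py))
    return np.nansum(term, axis=(1, 2))


def _bin_matrix(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Row-wise equal-frequency bin indices for a genes x samples matrix."""
    order = np.argsort(values, axis=1, kind="stable")
    ranks = np.empty_like(order)
    m = values.shape[1]
    np.put_along_axis(ranks, order, np.arange(m)[None, :].repeat(
        values.shape[0], axis=0), axis=1)
    return (ranks * n_bins) // m


def _mi_tf_vs_all(tf_bins: np.ndarray, gene_onehot: np.ndarray) -> np.ndarray:
    """MI between one binned TF vector and every row of a binned matrix.

    gene_onehot has shape (b, n_genes, m): indicator of each gene landing in
    each bin per sample.
    """
    b = gene_onehot.shape[0]
    tf_onehot = np.equal.outer(tf_bins, np.arange(b)).astype(float)  # m x b
    counts = np.tensordot(gene_onehot, tf_onehot, axes=([2], [0]))
    # counts: (b_gene, n_genes, b_tf) -> (n_genes, b_gene, b_tf)
    return _mi_from_counts(np.transpose(counts, (1, 0, 2)))


def _gene_onehot(bins: np.ndarray, n_bins: int) -> np.ndarray:
    return np.stack([(bins == b).astype(float) for b in range(n_bins)])


# ---------------------------------------------------------------------------
# regulon inference


def infer_regulons(X: ExpressionMatrix, tf_list: list[str],
                   n_permutations: int = 100, bh_alpha: float = 0.05,
                   seed: int = 0, n_bins: int | None = None
                   ) -> TranscriptionalNetwork:
    """Infer a TF-target network by MI with a permutation null.

    Per TF, MI is computed against every other gene; the null pools MI of
    the shuffled TF vector against all candidate targets over
    ``n_permutations`` rounds (one shared null distribution per TF). BH
    correction is applied within each TF's tests; edges with adjusted
    p < ``bh_alpha`` are kept, with mode = sign of the Spearman correlation.
    """
    present = [tf for tf in tf_list if tf in set(X.gene_ids)]
    if not present:
        raise NetworkError("no TF from the list is present in the matrix")
    rng = np.random.default_rng(seed)
    b = n_bins or default_bins(X.n_samples)
    bins = _bin_matrix(X.values, b)
    onehot = _gene_onehot(bins, b)
    gidx = X.gene_index()
    # Spearman correlation for modes: Pearson on row ranks
    ranks = stats.rankdata(X.values, axis=1)
    ranks = (ranks - ranks.mean(axis=1, keepdims=True))
    rnorm = np.linalg.norm(ranks, axis=1)

    regulons: list[Regulon] = []
    thresholds: dict[str, float] = {}
    candidate_mask = np.ones(X.n_genes, dtype=bool)
    for tf in present:
        i = gidx[tf]
        tf_bins = bins[i]
        mi_all = _mi_tf_vs_all(tf_bins, onehot)
        candidate_mask[:] = True
        candidate_mask[i] = False
        null = np.empty((n_permutations, X.n_genes))
        for p_ix in range(n_permutations):
            null[p_ix] = _mi_tf_vs_all(rng.permutation(tf_bins), onehot)
        pooled = np.sort(null[:, candidate_mask].ravel())
        exceed = pooled.size - np.searchsorted(pooled, mi_all, side="left")
        pvals = (1.0 + exceed) / (1.0 + pooled.size)
        cand = np.flatnonzero(candidate_mask)
        padj = bh_adjust(pvals[cand])
        keep = cand[padj < bh_alpha]
        if keep.size == 0:
            continue
        corr = ranks[keep] @ ranks[i] / (rnorm[keep] * rnorm[i])
        edges = {
            X.gene_ids[g]: Edge(mi=float(mi_all[g]),
                                mode=1 if c >= 0 else -1)
            for g, c in zip(keep, corr)
        }
        regulons.append(Regulon(tf, edges))
        thresholds[tf] = float(mi_all[keep].min())
    return TranscriptionalNetwork(
        regulons=regulons,
        universe=set(X.gene_ids),
        params={"n_permutations": n_permutations, "bh_alpha": bh_alpha,
                "n_bins": b, "seed": seed},
        mi_thresholds=thresholds,
    )


def bootstrap_filter(X: ExpressionMatrix, network: TranscriptionalNetwork,
                     n_bootstraps: int = 50, support_threshold: float = 0.95,
                     seed: int = 0) -> TranscriptionalNetwork:
    """Drop edges that are unstable under sample resampling.

    Each bootstrap resamples samples with replacement and re-tests every
    retained edge: the edge passes if its bootstrap MI reaches the TF's
    original acceptance threshold (the smallest MI among its significant
    edges). Support is the fraction of passing bootstraps; edges below
    ``support_threshold`` are removed. With threshold 0 the edge set is
    unchanged and supports are merely annotated.
    """
    if n_bootstraps < 2:
        raise NetworkError("need at least 2 bootstraps")
    rng = np.random.default_rng(seed)
    b = network.params.get("n_bins") or default_bins(X.n_samples)
    gidx = X.gene_index()
    tf_rows = {r.tf: gidx[r.tf] for r in network.regulons}
    target_rows = {r.tf: np.array([gidx[t] for t in sorted(r.targets)])
                   for r in network.regulons}
    target_names = {r.tf: sorted(r.targets) for r in network.regulons}
    passes = {r.tf: np.zeros(len(r.targets)) for r in network.regulons}
    m = X.n_samples
    for _ in range(n_bootstraps):
        idx = rng.integers(0, m, size=m)
        vals = X.values[:, idx]
        for reg in network.regulons:
            rows = np.concatenate(([tf_rows[reg.tf]], target_rows[reg.tf]))
            bins = _bin_matrix(vals[rows], b)
            onehot = _gene_onehot(bins[1:], b)
            mi = _mi_tf_vs_all(bins[0], onehot)
            thr = network.mi_thresholds.get(reg.tf, 0.0)
            passes[reg.tf] += (mi >= thr)
    new_regulons = []
    for reg in network.regulons:
        support = passes[reg.tf] / n_bootstraps
        kept = {
            t: replace(reg.targets[t], bootstrap_support=float(s))
            for t, s in zip(target_names[reg.tf], support)
            if s >= support_threshold
        }
        if kept:
            new_regulons.append(Regulon(reg.tf, kept))
    params = dict(network.params,
                  n_bootstraps=n_bootstraps,
                  support_threshold=support_threshold)
    return TranscriptionalNetwork(new_regulons, set(network.universe),
                                  params, dict(network.mi_thresholds))


def apply_dpi(network: TranscriptionalNetwork,
              epsilon: float = 0.0) -> TranscriptionalNetwork:
    """Prune indirect edges with the Data Processing Inequality.

    For every triplet (TF1, TF2, t) in which TF1-TF2, TF1-t and TF2-t are
    all edges, the minimum-MI edge is marked for removal when its MI is
    below ``(1 - epsilon) * min`` of the other two. A single pass over all
    triplets is made against the frozen (pre-pruning) MI values.
    """
    if epsilon < 0:
        raise NetworkError("epsilon must be >= 0")
    mi_of: dict[frozenset[str], float] = {}
    adjacency: dict[str, set[str]] = {}
    for reg in network.regulons:
        for t, e in reg.targets.items():
            key = frozenset((reg.tf, t))
            mi_of[key] = max(e.mi, mi_of.get(key, 0.0))
            adjacency.setdefault(reg.tf, set()).add(t)
            adjacency.setdefault(t, set()).add(reg.tf)
    # every triangle contains at least two TFs (edges always involve a TF),
    # so enumerating TF pairs with a shared undirected neighbor covers all
    tfs = [r.tf for r in network.regulons]
    doomed: set[frozenset[str]] = set()
    for i, tf1 in enumerate(tfs):
        for tf2 in tfs[i + 1:]:
            pair = frozenset((tf1, tf2))
            if pair not in mi_of:
                continue
            shared = (adjacency.get(tf1, set()) & adjacency.get(tf2, set())
                      ) - {tf1, tf2}
            for t in shared:
                e12, e1t, e2t = (mi_of[pair],
                                 mi_of[frozenset((tf1, t))],
                                 mi_of[frozenset((tf2, t))])
                triples = sorted([(e12, pair),
                                  (e1t, frozenset((tf1, t))),
                                  (e2t, frozenset((tf2, t)))])
                weakest_mi, weakest = triples[0]
                if weakest_mi < (1.0 - epsilon) * triples[1][0]:
                    doomed.add(weakest)
    new_regulons = []
    for reg in network.regulons:
        kept = {t: e for t, e in reg.targets.items()
                if frozenset((reg.tf, t)) not in doomed}
        if kept:
            new_regulons.append(Regulon(reg.tf, kept))
    params = dict(network.params, dpi_epsilon=epsilon)
    return TranscriptionalNetwork(new_regulons, set(network.universe),
                                  params, dict(network.mi_thresholds))


# ---------------------------------------------------------------------------
# master regulator analysis


@dataclass
class MRAResult:
    """Per-TF regulon/signature overlap statistics."""

    table: pd.DataFrame        # tf, regulon_size, signature_size,
                               # universe_size, overlap, p, p_adj, is_master
    signature_name: str
    fdr: float

    def masters(self) -> list[str]:
        return list(self.table.loc[self.table["is_master"], "tf"])


def mra(network: TranscriptionalNetwork, signature: GeneSet,
        min_regulon_size: int = 15, fdr: float = 0.05) -> MRAResult:
    """Call master regulators by hypergeometric regulon/signature overlap.

    For each TF whose regulon holds at least ``min_regulon_size`` targets,
    the overlap k between regulon and signature is scored as
    P[X >= k], X ~ Hypergeom(N = |universe|, K = regulon size,
    n = |signature ∩ universe|), then BH-corrected across the TFs tested.
    Interaction modes do not enter the overlap count.
    """
    universe = network.universe
    sig = signature.members & universe
    if not sig:
        raise NetworkError(
            f"signature {signature.name!r} shares no genes with the "
            "network universe")
    N = len(universe)
    n_sig = len(sig)
    rows = []
    for reg in network.regulons:
        targets = reg.target_set() & universe
        K = len(targets)
        if K < min_regulon_size:
            continue
        k = len(targets & sig)
        p = float(stats.hypergeom.sf(k - 1, N, K, n_sig))
        rows.append((reg.tf, K, n_sig, N, k, p))
    if not rows:
        raise NetworkError(
            f"no regulon reaches the minimum size {min_regulon_size}")
    table = pd.DataFrame(rows, columns=["tf", "regulon_size",
                                        "signature_size", "universe_size",
                                        "overlap", "p"])
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["is_master"] = table["p_adj"] < fdr
    return MRAResult(table=table.sort_values("p", kind="stable")
                     .reset_index(drop=True),
                     signature_name=signature.name, fdr=fdr)


def gsea_validate_mr(network: TranscriptionalNetwork, tf: str,
                     ranking, n_permutations: int = 1000,
                     seed: int = 0) -> EnrichmentResult:
    """Validate a master-regulator call by GSEA of its regulon.

    The regulon's target set is tested for enrichment in a supplied signed
    differential ranking (e.g. subtype vs rest).
    """
    reg = network.regulon(tf)
    if not reg.targets:
        raise NetworkError(f"regulon of {tf!r} is empty")
    gene_set = GeneSet(f"regulon_{tf}", f"inferred targets of {tf}",
                       frozenset(reg.targets))
    return gsea(ranking, gene_set, n_permutations=n_permutations, seed=seed)
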