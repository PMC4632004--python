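"""Core data containers shared by every pipeline stage.

All expression values are assumed to be on log2 scale; survival times are in
months. Containers validate their invariants at construction time so that a
malformed object can never propagate past the module boundary it was built in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An object violated one of its declared invariants."""


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2 expression values.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique gene symbols, one per row.
    sample_ids : sequence of str
        Unique sample identifiers, one per column.
    values : ndarray of shape (n_genes, n_samples)
        Finite log2 expression values.
    dataset_id : str
        Free-text cohort label carried through scoring and normalization.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n_genes, n_samples = self.values.shape
        if n_genes != len(self.gene_ids) or n_samples != len(self.sample_ids):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if n_genes < 2 or n_samples < 2:
            raise ValidationError("need at least 2 genes and 2 samples")
        if len(set(self.gene_ids)) != n_genes:
            dups = _duplicates(self.gene_ids)
            raise ValidationError(f"duplicate gene ids: {sorted(dups)[:5]}")
        if len(set(self.sample_ids)) != n_samples:
            dups = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample ids: {sorted(dups)[:5]}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        keep = [g for g in genes if g in idx]
        rows = [idx[g] for g in keep]
        return ExpressionMatrix(keep, list(self.sample_ids),
                                self.values[rows], self.dataset_id)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples),
                                self.values[:, cols], self.dataset_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, dataset_id: str = "dataset"
                   ) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(float),
                   dataset_id)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (GMT line semantics)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def intersect(self, genes: Iterable[str]) -> frozenset[str]:
        return self.members & set(genes)


@dataclass
class SurvivalTable:
    """Right-censored survival records: one row per sample.

    time is in months; event 1 = death observed, 0 = censored.
    """

    data: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "time", "event", "cohort_id")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        missing = [c for c in ("sample_id", "time", "event") if c not in df]
        if missing:
            raise ValidationError(f"missing survival columns: {missing}")
        if "cohort_id" not in df:
            df["cohort_id"] = "cohort"
        df["time"] = pd.to_numeric(df["time"], errors="raise")
        df["event"] = pd.to_numeric(df["event"], errors="raise")
        if (df["time"] < 0).any():
            bad = df.loc[df["time"] < 0, "sample_id"].iloc[0]
            raise ValidationError(f"negative survival time for sample {bad!r}")
        if not df["event"].isin([0, 1]).all():
            bad = df.loc[~df["event"].isin([0, 1]), "sample_id"].iloc[0]
            raise ValidationError(f"event not in {{0,1}} for sample {bad!r}")
        for cid, grp in df.groupby("cohort_id"):
            if grp["sample_id"].duplicated().any():
                dup = grp.loc[grp["sample_id"].duplicated(), "sample_id"].iloc[0]
                raise ValidationError(
                    f"duplicate sample id {dup!r} in cohort {cid!r}")
        df["event"] = df["event"].astype(int)
        self.data = df[list(self.REQUIRED)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def aligned_to(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        """Return rows reordered to match sample_ids; error on missing."""
        df = self.data.set_index("sample_id")
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise ValidationError(
                f"samples missing from survival table: {missing[:5]}")
        return df.loc[list(sample_ids)].reset_index()


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, clipped to [0,1])."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out
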