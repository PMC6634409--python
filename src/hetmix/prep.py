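"""Turn raw matrices plus clone numbers into labeled feature datasets.

Tumors are labeled high heterogeneity (1) when their subclone number reaches
a cutoff (default 6, chosen for balanced classes) and low (0) otherwise.
Three feature sets are produced: M (binary mutation calls after removing
rarely mutated genes), E (normalized expression after removing weakly
expressed genes) and EM = M u E, the column-wise combination with per-feature
datatype tags.

By default the two filters are applied to the full dataset before any
cross-validation split, matching the usual "prepare once, then evaluate"
workflow; both are unsupervised (they never look at the labels), but a strict
per-fold mode is available through :class:`hetmix.classify.ModelSpec` for
users who want the filters inside the folds as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FeatureDataset",
    "label_by_clone_count",
    "filter_mutation_features",
    "filter_expression_features",
    "combine_features",
    "build_feature_datasets",
    "read_matrix_tsv",
    "read_clone_table",
    "read_mutation_pairs",
]

MUTATION = "mutation"
EXPRESSION = "expression"


@dataclass
class FeatureDataset:
    """Samples x features matrix with binary labels and datatype tags."""

    X: np.ndarray
    y: np.ndarray
    feature_ids: list[str]
    feature_types: np.ndarray  # "mutation" | "expression" per column
    set_kind: str  # "M" | "E" | "EM"
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.feature_types = np.asarray(self.feature_types, dtype=object)
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(self.X.shape[0])]
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_mutation(self) -> int:
        return int((self.feature_types == MUTATION).sum())

    @property
    def n_expression(self) -> int:
        return int((self.feature_types == EXPRESSION).sum())

    def validate(self) -> None:
        n, f = self.X.shape
        if len(self.y) != n or len(self.sample_ids) != n:
            raise ValueError("labels/sample ids must match the number of rows")
        if len(self.feature_ids) != f or len(self.feature_types) != f:
            raise ValueError("feature ids/types must match the number of columns")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary")
        if len(set(self.feature_ids)) != f:
            raise ValueError("feature ids must be unique")
        if self.set_kind not in ("M", "E", "EM"):
            raise ValueError(f"set_kind must be M, E or EM, got {self.set_kind}")
        mut = self.feature_types == MUTATION
        if mut.any() and not np.isin(self.X[:, mut], (0.0, 1.0)).all():
            raise ValueError("mutation-tagged columns must be binary")
        exp = self.feature_types == EXPRESSION
        if exp.any() and self.X[:, exp].min() < 0:
            raise ValueError("expression-tagged columns must be non-negative")

    def subset_features(self, which) -> "FeatureDataset":
        """Dataset restricted to the given feature ids or column indices."""
        if len(which) and isinstance(next(iter(which)), str):
            index = {f: i for i, f in enumerate(self.feature_ids)}
            cols = np.array([index[f] for f in which], dtype=int)
        else:
            cols = np.asarray(list(which), dtype=int)
        return FeatureDataset(
            X=self.X[:, cols],
            y=self.y.copy(),
            feature_ids=[self.feature_ids[c] for c in cols],
            feature_types=self.feature_types[cols],
            set_kind=self.set_kind,
            sample_ids=list(self.sample_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.sample_ids, columns=self.feature_ids)


def label_by_clone_count(clone_counts, cutoff: int = 6) -> tuple[np.ndarray, dict[int, int]]:
    """Binary heterogeneity labels: 1 when the clone number reaches ``cutoff``.

    Returns the label vector and the class counts, so the balance obtained at
    the chosen cutoff can be inspected on any input.
    """
    counts = np.asarray(clone_counts, dtype=int)
    if counts.size and counts.min() < 1:
        raise ValueError("clone counts must be positive integers")
    y = (counts >= cutoff).astype(int)
    return y, {0: int((y == 0).sum()), 1: int((y == 1).sum())}


def filter_mutation_features(X_mut: pd.DataFrame, min_carriers: int = 6) -> pd.DataFrame:
    """Drop genes mutated in fewer than ``min_carriers`` samples.

    ``X_mut`` is samples x features, binary.  The default keeps features with
    at least 6 carriers, i.e. excludes mutation frequency <= 5.  Column order
    is preserved; the filter is idempotent.
    """
    arr = X_mut.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mutation matrix must be binary")
    keep = arr.sum(axis=0) >= min_carriers
    return X_mut.loc[:, keep]


def filter_expression_features(
    X_expr: pd.DataFrame, min_mean_count: float = 20.0, mode: str = "mean"
) -> pd.DataFrame:
    """Drop weakly expressed genes (normalized read count below a floor).

    ``mode`` selects the reading of "low over total samples": ``mean`` keeps a
    gene when its mean count across samples reaches the floor (the
    conventional low-expression screen, the default), ``max`` when any sample
    reaches it, ``all`` when every sample does.
    """
    arr = X_expr.to_numpy()
    if arr.size and arr.min() < 0:
        raise ValueError("expression matrix must be non-negative")
    if mode == "mean":
        stat = arr.mean(axis=0)
    elif mode == "max":
        stat = arr.max(axis=0)
    elif mode == "all":
        stat = arr.min(axis=0)
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return X_expr.loc[:, stat >= min_mean_count]


def combine_features(m_set: FeatureDataset, e_set: FeatureDataset) -> FeatureDataset:
    """Column-wise combination of the mutation and expression sets (EM)."""
    if m_set.n_samples != e_set.n_samples or m_set.sample_ids != e_set.sample_ids:
        raise ValueError("mutation and expression sets must cover the same samples in order")
    if not np.array_equal(m_set.y, e_set.y):
        raise ValueError("mutation and expression sets must share labels")
    overlap = set(m_set.feature_ids) & set(e_set.feature_ids)
    if overlap:
        raise ValueError(f"feature ids must be disjoint across types, shared: {sorted(overlap)[:5]}")
    return FeatureDataset(
        X=np.hstack([m_set.X, e_set.X]),
        y=m_set.y.copy(),
        feature_ids=m_set.feature_ids + e_set.feature_ids,
        feature_types=np.concatenate([m_set.feature_types, e_set.feature_types]),
        set_kind="EM",
        sample_ids=list(m_set.sample_ids),
    )


def build_feature_datasets(
    mut: pd.DataFrame,
    expr: pd.DataFrame,
    clone_counts,
    label_cutoff: int = 6,
    min_carriers: int = 6,
    min_mean_expr: float = 20.0,
    expr_filter_mode: str = "mean",
) -> dict[str, FeatureDataset]:
    """Build the M, E and EM datasets from features x samples matrices.

    ``mut`` and ``expr`` are features x samples (the on-disk orientation);
    ``clone_counts`` aligns with their shared sample columns.
    """
    if list(mut.columns) != list(expr.columns):
        raise ValueError("mutation and expression matrices must share sample columns in order")
    samples = list(mut.columns)
    y, _ = label_by_clone_count(clone_counts, cutoff=label_cutoff)
    if len(y) != len(samples):
        raise ValueError("clone counts must align with the sample columns")

    mut_f = filter_mutation_features(mut.T, min_carriers=min_carriers)
    expr_f = filter_expression_features(expr.T, min_mean_count=min_mean_expr, mode=expr_filter_mode)
    m_ids = [str(c) for c in mut_f.columns]
    e_ids = [str(c) for c in expr_f.columns]
    m_set = FeatureDataset(
        X=mut_f.to_numpy(float),
        y=y,
        feature_ids=m_ids,
        feature_types=np.array([MUTATION] * len(m_ids), dtype=object),
        set_kind="M",
        sample_ids=samples,
    )
    e_set = FeatureDataset(
        X=expr_f.to_numpy(float),
        y=y,
        feature_ids=e_ids,
        feature_types=np.array([EXPRESSION] * len(e_ids), dtype=object),
        set_kind="E",
        sample_ids=samples,
    )
    return {"M": m_set, "E": e_set, "EM": combine_features(m_set, e_set)}


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV with a header of sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_clone_table(path: str | Path) -> pd.Series:
    """Read a (sample_id, n_clones) TSV into a Series indexed by sample id."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("clone table needs sample_id and n_clones columns")
    return pd.Series(df.iloc[:, 1].to_numpy(int), index=df.iloc[:, 0].astype(str), name="n_clones")


def read_mutation_pairs(path: str | Path, sample_ids=None) -> pd.DataFrame:
    """Collapse a two-column (sample, gene) mutation list to a binary matrix.

    Returns genes x samples, matching the orientation of the matrix readers.
    """
    pairs = pd.read_csv(path, sep="\t")
    if pairs.shape[1] < 2:
        raise ValueError("mutation list needs sample and gene columns")
    pairs = pairs.iloc[:, :2]
    pairs.columns = ["sample", "gene"]
    mat = pd.crosstab(pairs["gene"], pairs["sample"]).clip(upper=1)
    if sample_ids is not None:
        mat = mat.reindex(columns=list(sample_ids), fill_value=0)
    return mat
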