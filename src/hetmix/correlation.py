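"""Per-gene Spearman screen of clone number against expression.

For each gene the rank correlation (average-rank tie handling) between its
expression across samples and the per-sample subclone number is computed with
a two-sided p-value from the t approximation, and genes significant at the
raw level p < alpha (default 0.01) are counted by sign.  No multiple-testing
correction enters the counts — a Benjamini-Hochberg q-value column is
emitted for information only.  Constant genes have undefined rank correlation
and are flagged and excluded from the significant counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationResult", "spearman_screen", "rank_for_enrichment", "write_ranked_list"]


@dataclass
class CorrelationResult:
    """Per-gene rank correlations with significant-gene tallies."""

    table: pd.DataFrame  # columns: gene, rho, p, q, flag
    alpha: float
    n_pos_sig: int
    n_neg_sig: int

    @property
    def n_tested(self) -> int:
        return int((self.table["flag"] == "ok").sum())

    def summary(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_genes": int(len(self.table)),
            "n_tested": self.n_tested,
            "n_pos_sig": self.n_pos_sig,
            "n_neg_sig": self.n_neg_sig,
        }


def _exact_spearman_p(x_ranks: np.ndarray, y: np.ndarray, observed_rho: float) -> float:
    """Two-sided permutation p-value by full enumeration (small n only)."""
    n = len(y)
    y_ranks = stats.rankdata(y)
    count = 0
    total = 0
    abs_obs = abs(observed_rho) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(x_ranks[list(perm)], y_ranks)[0, 1]
        if abs(r) >= abs_obs:
            count += 1
        total += 1
    return count / total


def spearman_screen(
    expr: pd.DataFrame,
    clone_counts,
    alpha: float = 0.01,
    exact_max_n: int = 0,
) -> CorrelationResult:
    """Screen genes for rank correlation between expression and clone number.

    ``expr`` is genes x samples; ``clone_counts`` aligns with its columns.
    With ``exact_max_n`` >= n the p-values come from full permutation
    enumeration instead of the t approximation (feasible for n <= 10).
    """
    counts = np.asarray(clone_counts, dtype=float)
    n = expr.shape[1]
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    if counts.shape[0] != n:
        raise ValueError("clone counts must align with expression samples")
    if counts.min() < 1:
        raise ValueError("clone counts must be positive integers")

    arr = expr.to_numpy(float)
    constant = np.ptp(arr, axis=1) == 0
    if np.ptp(counts) == 0:
        constant = np.ones(arr.shape[0], dtype=bool)  # no rank variation to correlate against

    rhos = np.full(arr.shape[0], np.nan)
    pvals = np.full(arr.shape[0], np.nan)
    use_exact = 0 < n <= exact_max_n
    for i in np.flatnonzero(~constant):
        rho, p = stats.spearmanr(arr[i], counts)
        if use_exact:
            p = _exact_spearman_p(stats.rankdata(arr[i]), counts, rho)
        rhos[i], pvals[i] = rho, p

    flags = np.where(constant, "constant", "ok")
    ok = flags == "ok"
    qvals = np.full(arr.shape[0], np.nan)
    if ok.any():
        qvals[ok] = stats.false_discovery_control(pvals[ok], method="bh")

    table = pd.DataFrame(
        {
            "gene": [str(g) for g in expr.index],
            "rho": rhos,
            "p": pvals,
            "q": qvals,
            "flag": flags,
        }
    )
    sig = ok & (pvals < alpha)
    result = CorrelationResult(
        table=table,
        alpha=alpha,
        n_pos_sig=int((sig & (rhos > 0)).sum()),
        n_neg_sig=int((sig & (rhos < 0)).sum()),
    )
    return result


def rank_for_enrichment(result: CorrelationResult) -> pd.DataFrame:
    """Genes ordered by rho descending (ties by gene id), for pre-ranked GSEA.

    Constant genes carry no score and are omitted.  The two-column output
    (gene, score) matches the plain .rnk format pre-ranked enrichment tools
    consume.
    """
    ok = result.table[result.table["flag"] == "ok"]
    ranked = ok.sort_values(["rho", "gene"], ascending=[False, True], kind="mergesort")
    return ranked[["gene", "rho"]].rename(columns={"rho": "score"}).reset_index(drop=True)


def write_ranked_list(result: CorrelationResult, path: str | Path) -> Path:
    path = Path(path)
    rank_for_enrichment(result).to_csv(path, sep="\t", index=False)
    return path
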