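"""Clone-mixing simulator: build tumors of known heterogeneity from cell lines.

Each simulated tumor is a convex combination of randomly chosen tumor cell
lines.  Per sample the procedure draws

1. the clone number Nc from a Poisson(lambda) truncated to Nc >= 1,
2. the tumor purity Pt (percent) from Normal(mean, var) clipped to (0, 100],
3. integer clone sizes Sj uniform on [size_min, size_max], normalized to
   weights wj = Sj / sum(S),
4. Nc distinct tumor lines, mixing their VAF profiles by the weights and
   scaling by purity: mixed_vaf = (Pt/100) * sum_j wj * vaf_j, and their
   expression profiles likewise with a normal-tissue term weighted by the
   remaining cell fraction: expr = (Pt/100) * sum_j wj * e_j + (1 - Pt/100) * normal,
5. binarizing mixed VAFs at a detection cutoff (call = mixed_vaf >= cutoff).

Mutation and expression channels of one sample use the SAME lines, weights
and purity, so the combined profile is internally consistent and the ground
truth (clone count, purity, weights) is recorded per sample.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hetmix.panel import CellLinePanel

__all__ = [
    "MixParams",
    "MixedTumorSample",
    "sample_clone_count",
    "sample_purity",
    "sample_clone_weights",
    "mix_mutation_profile",
    "mix_expression_profile",
    "simulate_cohort",
    "cohort_to_frames",
    "save_cohort",
    "load_cohort",
]

_PURITY_EPS = 1e-9  # lower clip of the purity distribution, keeps Pt in (0, 100]


@dataclass
class MixParams:
    """Simulation parameters; defaults are the standard study conditions."""

    clone_rate: float = 6.0  # Poisson rate lambda of the clone number
    purity_mean: float = 70.0  # percent
    purity_var: float = 100.0  # percent^2
    size_min: int = 20
    size_max: int = 100
    vaf_cutoff: float = 0.03
    n_samples: int = 150
    seed: int | None = None

    def validate(self) -> None:
        if self.clone_rate <= 0:
            raise ValueError(f"clone_rate must be > 0, got {self.clone_rate}")
        if not 0 < self.purity_mean <= 100:
            raise ValueError(f"purity_mean must be in (0, 100], got {self.purity_mean}")
        if self.purity_var < 0:
            raise ValueError(f"purity_var must be >= 0, got {self.purity_var}")
        if not 0 < self.size_min <= self.size_max:
            raise ValueError(f"need 0 < size_min <= size_max, got [{self.size_min}, {self.size_max}]")
        if not 0 < self.vaf_cutoff < 1:
            raise ValueError(f"vaf_cutoff must be in (0, 1), got {self.vaf_cutoff}")
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")


@dataclass
class MixedTumorSample:
    """One simulated tumor with its ground truth."""

    sample_id: str
    mutation_calls: np.ndarray  # binary over variants
    mixed_vaf: np.ndarray  # pre-binarization mixed VAFs, kept for diagnostics
    expression: np.ndarray  # non-negative over genes
    truth_n_clones: int
    truth_purity: float  # percent in (0, 100]
    truth_clone_lines: list[str]
    truth_clone_weights: np.ndarray = field(repr=False)

    def validate(self) -> None:
        if not (len(self.truth_clone_lines) == self.truth_n_clones == len(self.truth_clone_weights)):
            raise ValueError("clone lines, weights and clone count are inconsistent")
        if abs(float(np.sum(self.truth_clone_weights)) - 1.0) > 1e-12:
            raise ValueError("clone weights must sum to 1")
        if not np.isin(self.mutation_calls, (0, 1)).all():
            raise ValueError("mutation calls must be binary")
        if not np.all(np.isfinite(self.expression)) or self.expression.min() < 0:
            raise ValueError("expression must be finite and non-negative")
        if not 0 < self.truth_purity <= 100:
            raise ValueError("purity must be in (0, 100]")


def sample_clone_count(rng: np.random.Generator, rate: float = 6.0, size: int | None = None):
    """Draw clone numbers from a zero-truncated Poisson(rate).

    A tumor has at least one clone, so zero draws are redrawn; the result is
    Poisson(rate) conditioned on Nc >= 1 (mean rate / (1 - exp(-rate))).
    Returns a scalar int when ``size`` is None, else an int array.
    """
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    n = 1 if size is None else int(size)
    out = rng.poisson(rate, n)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(rate, int(zero.sum()))
        zero = out == 0
    return int(out[0]) if size is None else out


def sample_purity(
    rng: np.random.Generator, mean: float = 70.0, var: float = 100.0, size: int | None = None
):
    """Draw tumor purity (percent) from Normal(mean, var), clipped to (0, 100].

    At the default mean 70 / variance 100 the boundaries sit 3 and 7 standard
    deviations away, so clipping is astronomically rare and leaves the moments
    essentially untouched.
    """
    if var < 0:
        raise ValueError(f"var must be >= 0, got {var}")
    draws = rng.normal(mean, np.sqrt(var), 1 if size is None else int(size))
    draws = np.clip(draws, _PURITY_EPS, 100.0)
    return float(draws[0]) if size is None else draws


def sample_clone_weights(
    rng: np.random.Generator,
    n_clones: int,
    size_min: int = 20,
    size_max: int = 100,
    return_sizes: bool = False,
):
    """Draw integer clone sizes uniformly on [size_min, size_max] and normalize."""
    if n_clones < 1:
        raise ValueError(f"n_clones must be >= 1, got {n_clones}")
    sizes = rng.integers(size_min, size_max + 1, n_clones)
    weights = sizes / sizes.sum()
    return (weights, sizes) if return_sizes else weights


def _check_mix_inputs(profiles: np.ndarray, weights: np.ndarray, purity: float) -> tuple[np.ndarray, np.ndarray]:
    profiles = np.asarray(profiles, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if profiles.ndim != 2 or profiles.shape[1] != weights.shape[0]:
        raise ValueError(
            f"profile matrix has {profiles.shape} but {weights.shape[0]} clone weights were given"
        )
    if abs(float(weights.sum()) - 1.0) > 1e-9:
        raise ValueError("clone weights must sum to 1")
    if not 0 < purity <= 100:
        raise ValueError(f"purity must be in (0, 100], got {purity}")
    return profiles, weights


def mix_mutation_profile(
    clone_vafs: np.ndarray,
    weights: np.ndarray,
    purity: float,
    vaf_cutoff: float = 0.03,
) -> tuple[np.ndarray, np.ndarray]:
    """Mix per-clone VAFs by clone weight, scale by purity, binarize.

    mixed_vaf_v = (purity/100) * sum_j w_j * vaf_vj; a variant is called
    (1) when its mixed VAF reaches the cutoff (inclusive).  Returns
    ``(calls, mixed_vaf)`` so the pre-binarization values stay available.
    """
    clone_vafs, weights = _check_mix_inputs(clone_vafs, weights, purity)
    if clone_vafs.min() < 0 or clone_vafs.max() > 1:
        raise ValueError("VAFs must lie in [0, 1]")
    mixed = (purity / 100.0) * (clone_vafs @ weights)
    calls = (mixed >= vaf_cutoff).astype(np.uint8)
    return calls, mixed


def mix_expression_profile(
    clone_expr: np.ndarray,
    weights: np.ndarray,
    purity: float,
    normal_profile: np.ndarray,
) -> np.ndarray:
    """Clone-weighted expression mixture with normal-tissue admixture.

    expr_g = (purity/100) * sum_j w_j * e_gj + (1 - purity/100) * normal_g.
    The tumor and normal weights always sum to 1, so the result is a convex
    combination bounded by the per-gene extremes of its inputs.
    """
    clone_expr, weights = _check_mix_inputs(clone_expr, weights, purity)
    normal_profile = np.asarray(normal_profile, dtype=float)
    if normal_profile.shape != (clone_expr.shape[0],):
        raise ValueError(
            f"normal profile has shape {normal_profile.shape}, expected ({clone_expr.shape[0]},)"
        )
    if clone_expr.min() < 0 or normal_profile.min() < 0:
        raise ValueError("expression values must be non-negative")
    frac = purity / 100.0
    return frac * (clone_expr @ weights) + (1.0 - frac) * normal_profile


def simulate_cohort(
    panel: CellLinePanel,
    params: MixParams | None = None,
    rng: np.random.Generator | None = None,
) -> list[MixedTumorSample]:
    """Simulate ``params.n_samples`` mixed tumors from a cell-line panel.

    Per sample the clone number, lines, weights and purity are drawn once and
    shared by the mutation and expression channels.  Each sample consumes its
    own spawned random substream, so cohorts are reproducible regardless of
    how the per-sample work is scheduled.  The clone number is capped at the
    panel size (lines are drawn without replacement); at the default rate 6
    with 38 lines the cap is effectively never reached.
    """
    params = params or MixParams()
    params.validate()
    panel.validate()
    if rng is None:
        seed_seq = np.random.SeedSequence(params.seed)
    else:
        seed_seq = np.random.SeedSequence(int(rng.integers(2**31)))
    substreams = seed_seq.spawn(params.n_samples)

    vaf = panel.tumor_vaf.to_numpy()
    expr = panel.tumor_expr.to_numpy()
    normal = panel.normal_expr.to_numpy().mean(axis=1)  # unweighted mean of normal profiles
    line_ids = np.asarray(panel.line_ids)

    cohort: list[MixedTumorSample] = []
    for i, ss in enumerate(substreams):
        sub = np.random.default_rng(ss)
        n_clones = min(sample_clone_count(sub, params.clone_rate), panel.n_tumor_lines)
        lines = sub.choice(panel.n_tumor_lines, size=n_clones, replace=False)
        weights = sample_clone_weights(sub, n_clones, params.size_min, params.size_max)
        purity = sample_purity(sub, params.purity_mean, params.purity_var)
        calls, mixed = mix_mutation_profile(vaf[:, lines], weights, purity, params.vaf_cutoff)
        expression = mix_expression_profile(expr[:, lines], weights, purity, normal)
        sample = MixedTumorSample(
            sample_id=f"s{i:04d}",
            mutation_calls=calls,
            mixed_vaf=mixed,
            expression=expression,
            truth_n_clones=n_clones,
            truth_purity=purity,
            truth_clone_lines=list(line_ids[lines]),
            truth_clone_weights=weights,
        )
        sample.validate()
        cohort.append(sample)
    return cohort


def cohort_to_frames(
    cohort: list[MixedTumorSample], panel: CellLinePanel
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Assemble a cohort into (mutation, expression, truth) tables.

    Mutation and expression tables are features x samples; the truth table
    has one row per sample with clone count, purity, lines and weights.
    """
    sample_ids = [s.sample_id for s in cohort]
    mut = pd.DataFrame(
        np.column_stack([s.mutation_calls for s in cohort]),
        index=panel.variant_ids,
        columns=sample_ids,
    )
    expr = pd.DataFrame(
        np.column_stack([s.expression for s in cohort]),
        index=panel.gene_ids,
        columns=sample_ids,
    )
    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "n_clones": [s.truth_n_clones for s in cohort],
            "purity": [s.truth_purity for s in cohort],
            "clone_lines": [",".join(s.truth_clone_lines) for s in cohort],
            "clone_weights": [",".join(f"{w:.10g}" for w in s.truth_clone_weights) for s in cohort],
        }
    )
    return mut, expr, truth


def save_cohort(
    cohort: list[MixedTumorSample],
    panel: CellLinePanel,
    params: MixParams,
    out_dir: str | Path,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mut, expr, truth = cohort_to_frames(cohort, panel)
    mut.to_csv(out / "mutation_calls.tsv", sep="\t", index_label="variant_id")
    expr.to_csv(out / "expression.tsv", sep="\t", index_label="gene_id")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    (out / "mix_params.json").write_text(json.dumps(asdict(params), indent=2))
    return out


def load_cohort(in_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    src = Path(in_dir)
    mut = pd.read_csv(src / "mutation_calls.tsv", sep="\t", index_col="variant_id")
    expr = pd.read_csv(src / "expression.tsv", sep="\t", index_col="gene_id")
    truth = pd.read_csv(src / "truth.tsv", sep="\t")
    return mut, expr, truth
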