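"""Robustness experiments: gene-subset degradation and tumor-purity sweep.

Two end-to-end studies of classifier stability:

* ``gene_subset_experiment`` — how expression-based classification degrades
  when only a random subset of genes is available: for each subset size a
  number of random draws is evaluated by cross-validation and the mean and
  variance of accuracy across draws are recorded, with the full-gene-set
  baseline included.  Performance is expected to fall, and its variance to
  rise, as the subset shrinks.
* ``purity_sweep`` — how performance depends on mean tumor purity: a fresh
  cohort is simulated per purity level (variance unchanged) and every
  requested method x datatype combination is cross-validated.  The
  mutation channel is the purity-sensitive one, since low purity dilutes
  mixed VAFs below the detection cutoff.

Every experiment writes a manifest of parameters and seeds sufficient to
re-run it bit-identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hetmix.classify import ModelSpec, cross_validate
from hetmix.clonemix import MixParams, cohort_to_frames, simulate_cohort
from hetmix.panel import CellLinePanel
from hetmix.prep import FeatureDataset, build_feature_datasets

__all__ = ["ExperimentGrid", "gene_subset_experiment", "purity_sweep", "write_manifest"]


@dataclass
class ExperimentGrid:
    """Settings shared by the two robustness experiments."""

    subset_sizes: tuple = (50, 100, 500, 1000, 5000)  # "all" baseline is always added
    n_draws: int = 10
    purity_levels: tuple = (50.0, 70.0, 90.0)
    mix: MixParams = field(default_factory=MixParams)
    model: ModelSpec = field(default_factory=ModelSpec)
    n_folds: int = 10
    n_runs: int = 1
    label_cutoff: int = 6
    seed: int | None = None

    def validate(self) -> None:
        if any(s < 1 for s in self.subset_sizes):
            raise ValueError("subset sizes must be positive")
        if any(not 0 < p <= 100 for p in self.purity_levels):
            raise ValueError("purity levels must be in (0, 100]")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


def write_manifest(path: str | Path, **entries) -> Path:
    """Record parameters, seeds and the package version for exact re-runs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    from hetmix import __version__

    payload = {"hetmix_version": __version__}
    for key, value in entries.items():
        payload[key] = asdict(value) if hasattr(value, "__dataclass_fields__") else value
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path


def gene_subset_experiment(
    dataset: FeatureDataset,
    spec: ModelSpec | None = None,
    subset_sizes=(50, 100, 500, 1000, 5000),
    n_draws: int = 10,
    rng: np.random.Generator | int | None = None,
    n_folds: int = 10,
    n_runs: int = 1,
) -> pd.DataFrame:
    """Accuracy mean and variance across random gene subsets of each size.

    ``dataset`` must be expression-typed (set kind E).  Sizes exceeding the
    feature count are skipped with a warning; the full feature set is always
    evaluated as the baseline (reported with size = n_features and draw 0).
    Returns the per-draw table; aggregate with ``groupby("size")``.
    """
    if dataset.set_kind != "E":
        raise ValueError("gene-subset experiment expects the expression dataset (set kind E)")
    spec = spec or ModelSpec()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    n_feat = dataset.n_features
    sizes = []
    for s in subset_sizes:
        if s > n_feat:
            warnings.warn(f"subset size {s} exceeds the {n_feat} available genes; skipped")
        elif s not in sizes:
            sizes.append(int(s))
    if n_feat not in sizes:
        sizes.append(n_feat)

    rows = []
    for size in sizes:
        draws = 1 if size == n_feat else n_draws
        for draw in range(draws):
            draw_seed = int(rng.integers(2**31))
            if size == n_feat:
                sub = dataset
            else:
                cols = np.sort(np.random.default_rng(draw_seed).choice(n_feat, size, replace=False))
                sub = dataset.subset_features(cols)
            res = cross_validate(sub, spec, n_folds=n_folds, n_runs=n_runs, rng=draw_seed)
            rows.append(
                {
                    "size": size,
                    "draw": draw,
                    "accuracy": res.accuracy,
                    "auc": res.auc,
                    "sensitivity": res.sensitivity,
                    "specificity": res.specificity,
                    "seed": draw_seed,
                }
            )
    return pd.DataFrame(rows)


def summarize_subsets(per_draw: pd.DataFrame) -> pd.DataFrame:
    """Per-size mean and variance of accuracy across draws."""
    g = per_draw.groupby("size")["accuracy"]
    return pd.DataFrame(
        {"accuracy_mean": g.mean(), "accuracy_var": g.var(ddof=0), "n_draws": g.count()}
    ).reset_index()


def purity_sweep(
    panel: CellLinePanel,
    purity_levels=(50.0, 70.0, 90.0),
    mix_params: MixParams | None = None,
    methods=("naive_bayes", "svm_rbf", "random_forest"),
    set_kinds=("M", "E", "EM"),
    base_spec: ModelSpec | None = None,
    rng: np.random.Generator | int | None = None,
    n_folds: int = 10,
    n_runs: int = 1,
    label_cutoff: int = 6,
) -> pd.DataFrame:
    """Cross-validated performance at each mean tumor purity level.

    A cohort is regenerated per level with ``purity_mean`` set to that level
    and the purity variance unchanged; each requested method is evaluated on
    each requested dataset kind.  Returns one row per
    (purity, set_kind, method).
    """
    mix_params = mix_params or MixParams()
    base_spec = base_spec or ModelSpec()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    rows = []
    for level in purity_levels:
        level_seed = int(rng.integers(2**31))
        params = MixParams(**{**asdict(mix_params), "purity_mean": float(level), "seed": level_seed})
        cohort = simulate_cohort(panel, params)
        mut, expr, truth = cohort_to_frames(cohort, panel)
        datasets = build_feature_datasets(mut, expr, truth["n_clones"], label_cutoff=label_cutoff)
        for kind in set_kinds:
            for method in methods:
                spec = ModelSpec(**{**asdict(base_spec), "method": method})
                res = cross_validate(
                    datasets[kind], spec, n_folds=n_folds, n_runs=n_runs, rng=level_seed
                )
                rows.append(
                    {
                        "purity": float(level),
                        "set_kind": kind,
                        "method": method,
                        "accuracy": res.accuracy,
                        "auc": res.auc,
                        "sensitivity": res.sensitivity,
                        "specificity": res.specificity,
                        "seed": level_seed,
                    }
                )
    return pd.DataFrame(rows)
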