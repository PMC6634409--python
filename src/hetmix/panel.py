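"""Synthetic cell-line panels: the raw material for clone mixing.

A panel holds per-line variant allele frequencies (VAFs) for a set of tumor
cell lines, per-line expression profiles, and separate normal-tissue
expression profiles.  Real panels of this shape come from cancer cell-line
compendia plus normal-tissue atlases; the generator here produces a
statistical stand-in with the same structure so that the whole mixing and
classification pipeline runs offline with known ground truth:

* each tumor line carries a sparse, line-specific set of variants whose VAFs
  are concentrated near 0.5 (heterozygous clonal variants), so an unmixed
  pure line always exceeds the binarization cutoff;
* expression follows shared log-scale gene baselines with per-line
  multiplicative shifts on a subset of marker genes, so mixtures of different
  line sets are distinguishable;
* normal profiles are drawn from a per-gene shifted baseline, so the normal
  admixture term of a mixed tumor moves expression measurably.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PanelParams", "CellLinePanel", "generate_panel", "save_panel", "load_panel"]


@dataclass
class PanelParams:
    """Parameters of the synthetic panel generator.

    Counts default to the panel size used throughout (38 tumor lines, 2
    normal profiles); feature counts are desk-scale defaults.  Expression
    parameters are on the natural-log scale of normalized read counts.
    """

    n_tumor_lines: int = 38
    n_normal_profiles: int = 2
    n_variants: int = 500
    n_genes: int = 800
    #: probability that a given line carries a given variant (sparse burden)
    variant_prob: float = 0.08
    #: VAF of carried variants: Normal(vaf_mean, vaf_sd) clipped to [vaf_min, 1]
    vaf_mean: float = 0.5
    vaf_sd: float = 0.12
    vaf_min: float = 0.05
    #: per-gene baseline log-expression ~ Normal(baseline_log_mean, baseline_log_sd)
    baseline_log_mean: float = 4.6  # exp(4.6) ~ 100 normalized counts
    baseline_log_sd: float = 1.0
    #: per-line log-scale noise around the gene baseline
    line_log_noise_sd: float = 0.3
    #: fraction of genes given a line-specific expression shift
    marker_fraction: float = 0.05
    marker_log_fold_mean: float = 2.0  # ~7.4-fold median marker elevation
    marker_log_fold_sd: float = 0.3
    #: per-gene offset of the normal baseline relative to the tumor baseline
    normal_shift_sd: float = 1.0
    normal_profile_noise_sd: float = 0.2
    seed: int | None = None

    def validate(self) -> None:
        for name in ("n_tumor_lines", "n_normal_profiles", "n_variants", "n_genes"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive count, got {getattr(self, name)}")
        if not 0.0 < self.variant_prob <= 1.0:
            raise ValueError(f"variant_prob must be in (0, 1], got {self.variant_prob}")
        if not 0.0 <= self.marker_fraction <= 1.0:
            raise ValueError(f"marker_fraction must be in [0, 1], got {self.marker_fraction}")
        if not 0.0 < self.vaf_min <= 1.0:
            raise ValueError(f"vaf_min must be in (0, 1], got {self.vaf_min}")


@dataclass
class CellLinePanel:
    """Tumor cell-line VAF and expression profiles plus normal profiles.

    ``tumor_vaf`` is variants x tumor lines, ``tumor_expr`` genes x tumor
    lines, ``normal_expr`` genes x normal profiles; all share id indexes.
    """

    tumor_vaf: pd.DataFrame
    tumor_expr: pd.DataFrame
    normal_expr: pd.DataFrame
    params: PanelParams | None = field(default=None, repr=False)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.tumor_vaf.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tumor_expr.index)

    @property
    def line_ids(self) -> list[str]:
        return list(self.tumor_vaf.columns)

    @property
    def n_tumor_lines(self) -> int:
        return self.tumor_vaf.shape[1]

    @property
    def n_normal_profiles(self) -> int:
        return self.normal_expr.shape[1]

    def validate(self) -> None:
        vaf = self.tumor_vaf.to_numpy()
        if not np.all(np.isfinite(vaf)) or vaf.min() < 0 or vaf.max() > 1:
            raise ValueError("tumor VAFs must be finite and within [0, 1]")
        for name, mat in (("tumor_expr", self.tumor_expr), ("normal_expr", self.normal_expr)):
            arr = mat.to_numpy()
            if not np.all(np.isfinite(arr)) or arr.min() < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if list(self.tumor_expr.columns) != list(self.tumor_vaf.columns):
            raise ValueError("tumor_expr and tumor_vaf must share line ids")
        if list(self.normal_expr.index) != list(self.tumor_expr.index):
            raise ValueError("normal_expr and tumor_expr must share gene ids")
        if self.n_tumor_lines < 1 or self.n_normal_profiles < 1:
            raise ValueError("panel needs at least one tumor line and one normal profile")
        if (vaf > 0).sum(axis=0).min() < 1:
            raise ValueError("every tumor line must carry at least one variant with VAF > 0")


def generate_panel(params: PanelParams | None = None, rng: np.random.Generator | None = None) -> CellLinePanel:
    """Draw a synthetic panel from ``params``.

    With ``rng`` omitted the generator is seeded from ``params.seed``, so
    identical (params, seed) yield bit-identical panels.
    """
    params = params or PanelParams()
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    nv, ng = params.n_variants, params.n_genes
    nl, nn = params.n_tumor_lines, params.n_normal_profiles
    variant_ids = [f"v{i:04d}" for i in range(nv)]
    gene_ids = [f"g{i:04d}" for i in range(ng)]
    line_ids = [f"line{i:02d}" for i in range(nl)]
    normal_ids = [f"normal{i}" for i in range(nn)]

    carriers = rng.random((nv, nl)) < params.variant_prob
    # a line with no variants would be invisible to the mutation channel
    for j in np.flatnonzero(~carriers.any(axis=0)):
        carriers[rng.integers(nv), j] = True
    vafs = np.clip(rng.normal(params.vaf_mean, params.vaf_sd, (nv, nl)), params.vaf_min, 1.0)
    tumor_vaf = np.where(carriers, vafs, 0.0)

    baseline = rng.normal(params.baseline_log_mean, params.baseline_log_sd, ng)
    log_expr = baseline[:, None] + rng.normal(0.0, params.line_log_noise_sd, (ng, nl))
    n_markers = int(round(params.marker_fraction * ng))
    for j in range(nl):
        marked = rng.choice(ng, size=n_markers, replace=False)
        log_expr[marked, j] += rng.normal(params.marker_log_fold_mean, params.marker_log_fold_sd, n_markers)
    tumor_expr = np.exp(log_expr)

    normal_shift = rng.normal(0.0, params.normal_shift_sd, ng)
    log_normal = (
        baseline[:, None]
        + normal_shift[:, None]
        + rng.normal(0.0, params.normal_profile_noise_sd, (ng, nn))
    )
    normal_expr = np.exp(log_normal)

    panel = CellLinePanel(
        tumor_vaf=pd.DataFrame(tumor_vaf, index=variant_ids, columns=line_ids),
        tumor_expr=pd.DataFrame(tumor_expr, index=gene_ids, columns=line_ids),
        normal_expr=pd.DataFrame(normal_expr, index=gene_ids, columns=normal_ids),
        params=params,
    )
    panel.validate()
    return panel


def save_panel(panel: CellLinePanel, out_dir: str | Path) -> Path:
    """Write the panel as TSV matrices plus a JSON sidecar of parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel.tumor_vaf.to_csv(out / "tumor_vaf.tsv", sep="\t", index_label="variant_id")
    panel.tumor_expr.to_csv(out / "tumor_expr.tsv", sep="\t", index_label="gene_id")
    panel.normal_expr.to_csv(out / "normal_expr.tsv", sep="\t", index_label="gene_id")
    sidecar = asdict(panel.params) if panel.params is not None else {}
    (out / "panel_params.json").write_text(json.dumps(sidecar, indent=2))
    return out


def load_panel(in_dir: str | Path) -> CellLinePanel:
    src = Path(in_dir)
    params = None
    sidecar = src / "panel_params.json"
    if sidecar.exists():
        raw = json.loads(sidecar.read_text())
        if raw:
            params = PanelParams(**raw)
    panel = CellLinePanel(
        tumor_vaf=pd.read_csv(src / "tumor_vaf.tsv", sep="\t", index_col="variant_id"),
        tumor_expr=pd.read_csv(src / "tumor_expr.tsv", sep="\t", index_col="gene_id"),
        normal_expr=pd.read_csv(src / "normal_expr.tsv", sep="\t", index_col="gene_id"),
        params=params,
    )
    panel.validate()
    return panel
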