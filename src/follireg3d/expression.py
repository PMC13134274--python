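"""Stage-wise differential expression and specificity statistics.

Expression values are pre-normalized non-negative abundances for granulosa
cells sampled at the seven ordered follicle stages SWF, LWF, SYF, F5, F3,
F1, POF.  Differential calls use a Welch two-sample t-test on log2(x+1)
with Benjamini-Hochberg adjustment across all genes; this is a documented,
deliberately simple replacement for a negative-binomial count model, and
all downstream contracts are written against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

STAGES = ("SWF", "LWF", "SYF", "F5", "F3", "F1", "POF")
"""The seven ordered folliculogenesis stages."""


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with stage labels per sample."""

    values: pd.DataFrame
    stage_of_sample: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stage_of_sample:
            # sample ids follow the 'STAGE_rep' convention
            self.stage_of_sample = {s: s.rsplit("_", 1)[0] for s in self.values.columns}
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("gene ids must be unique")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            st = self.stage_of_sample[s]
            if st not in seen:
                seen.append(st)
        return seen

    def samples_of_stage(self, stage: str) -> list[str]:
        return [s for s in self.values.columns if self.stage_of_sample[s] == stage]

    def stage_means(self, stages: Sequence[str] | None = None) -> pd.DataFrame:
        """Per-gene mean abundance per stage (linear scale)."""
        stages = list(stages) if stages is not None else self.stages
        cols = {st: self.values[self.samples_of_stage(st)].mean(axis=1) for st in stages}
        return pd.DataFrame(cols)


def call_degs(
    expr: ExpressionMatrix,
    stage_a: str,
    stage_b: str,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
    strict_lfc: bool = True,
) -> pd.DataFrame:
    """Differential genes between two stages (Welch on log2(x+1), BH).

    log2 fold change is computed on stage means with pseudocount 1,
    B over A.  ``direction`` is 'up'/'down' when |log2fc| exceeds
    ``lfc_min`` (strictly by default) and fdr < ``fdr_max``, else 'ns'.
    """
    sa = expr.samples_of_stage(stage_a)
    sb = expr.samples_of_stage(stage_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each stage needs >= 2 replicates")
    a = np.log2(expr.values[sa].to_numpy() + 1.0)
    b = np.log2(expr.values[sb].to_numpy() + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    mean_a = expr.values[sa].mean(axis=1).to_numpy()
    mean_b = expr.values[sb].mean(axis=1).to_numpy()
    log2fc = np.log2(mean_b + 1.0) - np.log2(mean_a + 1.0)
    # zero within-group variance: Welch is undefined; equal means are a
    # perfect null, different means a noiseless separation
    nan_p = np.isnan(p)
    p = np.where(nan_p & np.isclose(a.mean(axis=1), b.mean(axis=1)), 1.0, p)
    p = np.where(np.isnan(p), 0.0, p)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    exceeds = np.abs(log2fc) > lfc_min if strict_lfc else np.abs(log2fc) >= lfc_min
    sig = exceeds & (fdr < fdr_max)
    direction = np.where(~sig, "ns", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "direction": direction,
        }
    ).set_index("gene_id")


def deg_proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher's exact p for DEG proportions in two transitions."""
    if k1 > n1 or k2 > n2 or min(k1, k2, n1, n2) < 0:
        raise ValueError("require 0 <= k <= n for both groups")
    _, p = stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided")
    return float(min(p, 1.0))


def cluster_stage_profiles(
    expr: ExpressionMatrix,
    genes: Sequence[str],
    k: int = 8,
    restarts: int = 50,
    seed: int = 0,
) -> dict[str, int]:
    """K-means clustering of z-scored stage-mean profiles.

    Profiles are per-gene z-scored across stages (sigma -> 1 for flat
    genes); k-means++ with ``restarts`` initializations, best by within-
    cluster sum of squares; deterministic for a fixed seed.
    """
    genes = list(genes)
    if k > len(genes):
        raise ValueError("k must not exceed the number of genes")
    means = np.log2(expr.stage_means().loc[genes].to_numpy() + 1.0)
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (means - mu) / sd
    km = KMeans(n_clusters=k, n_init=restarts, init="k-means++", random_state=seed)
    labels = km.fit_predict(z)
    return {g: int(c) for g, c in zip(genes, labels)}


def tsi(stage_means: Sequence[float], log_transform: bool = True) -> float:
    """Stage-specificity index tau in [0, 1].

    tau = sum_i (1 - x_i / x_max) / (n - 1); 0 for a flat profile, 1 for
    single-stage expression.  By default computed on log2(x+1) of the
    stage means; ``log_transform=False`` applies tau to the raw profile
    (the scale-invariant linear variant).
    """
    x = np.asarray(stage_means, dtype=float)
    if x.size < 2:
        raise ValueError("tau needs >= 2 stages")
    if np.any(x < 0):
        raise ValueError("tau requires non-negative values")
    if log_transform:
        x = np.log2(x + 1.0)
    xmax = x.max()
    if xmax == 0:
        return 0.0
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def cliffs_delta(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Cliff's delta effect size: (#{a>b} - #{a<b}) / (|A| |B|)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    diff = a[:, None] - b[None, :]
    return float((np.sum(diff > 0) - np.sum(diff < 0)) / (a.size * b.size))


def deg_truth_directions(
    means_a: Mapping[str, float], means_b: Mapping[str, float], lfc_min: float = 1.0
) -> dict[str, str]:
    """Noise-free DEG directions from true stage means (utility for
    planted-truth bookkeeping)."""
    out = {}
    for g in means_a:
        lfc = np.log2(means_b[g] + 1.0) - np.log2(means_a[g] + 1.0)
        out[g] = "up" if lfc > lfc_min else ("down" if lfc < -lfc_min else "ns")
    return out
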