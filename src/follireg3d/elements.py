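"""ROSE-style super-enhancer / super-silencer calling and element sets.

Peaks carrying region-mean signal are stitched when their gaps are within
a stitch distance (12.5 kb default, the ROSE convention), ranked by total
constituent signal, and split into "super" and "typical" at the knee of
the ranked signal curve — the point where a slope-1 tangent touches the
min-max-scaled curve.  The same machinery applied to H3K27ac yields
super-enhancers and to H3K27me3 super-silencers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import GenomicInterval, merge_intervals, overlap, subtract_elements


@dataclass
class StitchedRegion:
    interval: GenomicInterval
    constituent_count: int
    signal: float
    rank: int = 0  # descending signal, 1 = strongest
    is_super: bool = False


def stitch_peaks(
    peaks: Sequence[GenomicInterval],
    stitch_distance: int = 12500,
    tss: Sequence[GenomicInterval] | None = None,
    tss_exclusion: int = 0,
) -> list[StitchedRegion]:
    """Merge peaks whose gaps are <= ``stitch_distance`` into regions.

    Peak signal is its region-mean (score); a region's signal is the sum
    of constituent length x mean signal, approximating read load.  With
    ``tss_exclusion`` > 0, peaks falling fully within +-tss_exclusion of
    a TSS are removed before stitching.
    """
    kept = list(peaks)
    if tss_exclusion > 0 and tss:
        windows = [
            GenomicInterval(t.chrom, max(0, t.midpoint - tss_exclusion), t.midpoint + tss_exclusion)
            for t in tss
        ]
        contained: set[int] = set()
        for pi, wi in overlap(kept, windows):
            w = windows[wi]
            p = kept[pi]
            if p.start >= w.start and p.end <= w.end:
                contained.add(pi)
        kept = [p for i, p in enumerate(kept) if i not in contained]
    regions: list[StitchedRegion] = []
    for group in merge_intervals(kept, max_gap=stitch_distance):
        members = [kept[i] for i in group]
        start = min(m.start for m in members)
        end = max(m.end for m in members)
        signal = float(sum(m.length * m.score for m in members))
        iv = GenomicInterval(members[0].chrom, start, end, ".", signal)
        regions.append(StitchedRegion(iv, len(members), signal))
    return regions


def rank_and_cut(regions: Sequence[StitchedRegion]) -> tuple[list[StitchedRegion], float]:
    """Assign ranks and the super flag by the hockey-stick tangent cutoff.

    Regions are sorted ascending by signal and both axes min-max scaled to
    [0, 1]; the cutoff sits where the curve lies furthest below the
    diagonal (the slope-1 tangent point), ties broken toward the higher
    cutoff (fewer supers).  Regions with signal strictly above the cutoff
    signal are super.  Returns (regions, cutoff_signal).
    """
    if len(regions) < 3:
        raise ValueError("need >= 3 regions to place a cutoff")
    out = sorted(regions, key=lambda r: -r.signal)
    for i, r in enumerate(out):
        r.rank = i + 1
    sig = np.array([r.signal for r in out])[::-1]  # ascending
    smin, smax = sig.min(), sig.max()
    if smax == smin:
        warnings.warn("all region signals equal; no supers called")
        for r in out:
            r.is_super = False
        return out, float(smax)
    y = (sig - smin) / (smax - smin)
    x = np.arange(len(sig)) / (len(sig) - 1)
    gap = x - y
    cut_idx = int(np.flatnonzero(gap == gap.max())[-1])  # tie -> higher cutoff
    cutoff = float(sig[cut_idx])
    for r in out:
        r.is_super = r.signal > cutoff
    return out, cutoff


def call_super_elements(
    peaks: Sequence[GenomicInterval],
    stitch_distance: int = 12500,
    tss: Sequence[GenomicInterval] | None = None,
    tss_exclusion: int = 0,
) -> tuple[list[StitchedRegion], float]:
    """Stitch + rank: SEs from H3K27ac peaks, SSs from H3K27me3 peaks."""
    return rank_and_cut(stitch_peaks(peaks, stitch_distance, tss, tss_exclusion))


# alias: super-silencers use the identical machinery on the repressive mark
call_ss = call_super_elements


def stage_specific_supers(
    per_stage: Mapping[str, Sequence[GenomicInterval]],
) -> dict[str, list[GenomicInterval]]:
    """Per-stage elements with zero overlap against every other stage."""
    if len(per_stage) < 2:
        raise ValueError("need >= 2 stages")
    out: dict[str, list[GenomicInterval]] = {}
    for stage, elems in per_stage.items():
        others = [iv for s, ivs in per_stage.items() if s != stage for iv in ivs]
        out[stage] = subtract_elements(list(elems), others)
    return out


def dynamic_elements(
    per_stage: Mapping[str, Sequence[GenomicInterval]],
    stage_order: Sequence[str],
) -> list[GenomicInterval]:
    """Elements gained or lost between any adjacent stage pair.

    An element is dynamic when it is present (>= 1 bp overlap with the
    stage's element set) in one of two adjacent stages but not the other.
    The union is reported de-duplicated by coordinates.
    """
    seen: set[tuple[str, int, int]] = set()
    out: list[GenomicInterval] = []
    for s_prev, s_next in zip(stage_order[:-1], stage_order[1:]):
        prev = list(per_stage.get(s_prev, []))
        nxt = list(per_stage.get(s_next, []))
        for iv in subtract_elements(prev, nxt) + subtract_elements(nxt, prev):
            key = (iv.chrom, iv.start, iv.end)
            if key not in seen:
                seen.add(key)
                out.append(iv)
    return out


def enhancer_count_expression(
    gene_counts: Mapping[str, int],
    gene_expression: Mapping[str, float],
) -> dict:
    """Group genes by enhancer count and compare expression distributions.

    Groups: Bottom (exactly 1 enhancer), Middle (10-20), Top (>= 50);
    genes with other counts fall in no group.  Returns per-group
    expression arrays and a one-sided Mann-Whitney p for Top > Bottom.
    """
    groups: dict[str, list[float]] = {"Bottom": [], "Middle": [], "Top": []}
    for g, c in gene_counts.items():
        if g not in gene_expression or c < 0:
            if c < 0:
                raise ValueError("enhancer counts must be >= 0")
            continue
        if c == 1:
            groups["Bottom"].append(gene_expression[g])
        elif 10 <= c <= 20:
            groups["Middle"].append(gene_expression[g])
        elif c >= 50:
            groups["Top"].append(gene_expression[g])
    present = {k: np.asarray(v) for k, v in groups.items() if v}
    for k in groups:
        if k not in present:
            warnings.warn(f"enhancer-count group {k} is empty; omitted")
    p = None
    if "Top" in present and "Bottom" in present:
        _, p = stats.mannwhitneyu(present["Top"], present["Bottom"], alternative="greater")
        p = float(p)
    return {"groups": present, "p_top_gt_bottom": p}
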