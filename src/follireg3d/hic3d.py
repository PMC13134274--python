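"""Hi-C statistics: balancing, compartments, TAD boundaries, loops.

The boundary workflow follows the insulation-score approach: per-bin mean
of the square of contacts spanning the bin, log2-ratioed to the chromosome
mean and z-scored; boundaries are prominent local minima.  Stage-specific
boundaries must (1) be called in exactly one of a pair of adjacent stages
and (2) have a cross-stage insulation-window Spearman correlation that
does not exceed the 95th percentile of a random-bin permutation null
(1,000 draws by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.signal import find_peaks

from .core_io import ContactMatrix, GenomicInterval, LoopCall, SignalTrack, overlap

MIN_VALID_PAIRS = 11  # minimum pairwise-complete points for a window rho


@dataclass
class BoundaryCall:
    chrom: str
    bin: int
    stage: str
    insulation_z: float
    specific: bool = False
    spearman_vs_adjacent: dict[str, float] = field(default_factory=dict)
    null_quantile: float = float("nan")

    def as_interval(self, resolution: int) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.bin * resolution, (self.bin + 1) * resolution,
                               f"{self.stage}_boundary_{self.bin}")


# ---------------------------------------------------------------------------
# balancing and QC
# ---------------------------------------------------------------------------


def ice_balance(matrix: ContactMatrix, n_iter: int = 20, tol: float = 1e-5) -> ContactMatrix:
    """Iterative proportional fitting to equalize informative row sums."""
    m = matrix.counts.astype(float).copy()
    informative = m.sum(axis=1) > 0
    for _ in range(n_iter):
        rs = m.sum(axis=1)
        target = rs[informative].mean()
        bias = np.where(rs > 0, rs / target, 1.0)
        m = m / np.sqrt(np.outer(bias, bias))
        if np.abs(m.sum(axis=1)[informative] - target).max() / target < tol:
            break
    return ContactMatrix(matrix.chrom, matrix.resolution, (m + m.T) / 2, balanced=True)


def resolution_qc(matrix: ContactMatrix, min_contacts: int = 1000) -> float:
    """Fraction of bins with row-sum strictly above ``min_contacts``.

    Run on raw counts; the study's criterion for usable resolution is this
    fraction exceeding 0.8 at 10 kb.
    """
    if matrix.balanced:
        raise ValueError("resolution QC must run on raw counts")
    return float(np.mean(matrix.counts.sum(axis=1) > min_contacts))


# ---------------------------------------------------------------------------
# A/B compartments
# ---------------------------------------------------------------------------


def observed_over_expected(counts: np.ndarray) -> np.ndarray:
    """Divide each diagonal by its mean (distance-decay normalization)."""
    n = counts.shape[0]
    oe = np.zeros_like(counts, dtype=float)
    for d in range(n):
        diag = np.diagonal(counts, d)
        mu = diag.mean()
        if mu > 0:
            vals = diag / mu
            idx = np.arange(n - d)
            oe[idx, idx + d] = vals
            oe[idx + d, idx] = vals
    return oe


def compartment_eigenvector(
    matrix: ContactMatrix, orientation_track: SignalTrack
) -> tuple[np.ndarray, list[str]]:
    """A/B compartment calls from the leading correlation eigenvector.

    Observed/expected by diagonal means, Pearson correlation matrix, first
    eigenvector; the sign is oriented so that bins positively correlated
    with ``orientation_track`` (gene density or mean expression) are "A".
    Zero-coverage bins are labeled "NA" with eigenvector NaN.
    """
    if not matrix.balanced:
        raise ValueError("compartment analysis requires a balanced matrix")
    n = matrix.n_bins
    informative = matrix.counts.sum(axis=1) > 0
    if informative.sum() < 20:
        raise ValueError("need >= 20 informative bins")
    sub = matrix.counts[np.ix_(informative, informative)]
    oe = observed_over_expected(sub)
    if np.allclose(oe, 0):
        raise ValueError("degenerate (rank-0) matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(oe)
    if np.isnan(corr).all() or np.allclose(np.nan_to_num(corr - corr[0, 0]), 0):
        warnings.warn("uniform matrix: compartment signal undefined; labeling all A")
        ev_full = np.full(n, np.nan)
        ev_full[informative] = 0.0
        return ev_full, ["A" if informative[i] else "NA" for i in range(n)]
    corr = np.nan_to_num(corr)
    w, v = np.linalg.eigh(corr)
    ev = v[:, np.argmax(w)]
    track = np.asarray(orientation_track.values, dtype=float)[: n][informative]
    valid = ~np.isnan(track)
    if valid.sum() >= 3 and np.std(ev[valid]) > 0 and np.std(track[valid]) > 0:
        r = np.corrcoef(ev[valid], track[valid])[0, 1]
        if r < 0:
            ev = -ev
    ev_full = np.full(n, np.nan)
    ev_full[informative] = ev
    labels = [
        "NA" if not informative[i] else ("A" if ev_full[i] > 0 else "B") for i in range(n)
    ]
    return ev_full, labels


# ---------------------------------------------------------------------------
# insulation and boundaries
# ---------------------------------------------------------------------------


def insulation_track(matrix: ContactMatrix, window_bins: int = 10) -> SignalTrack:
    """Z-scored log2 insulation profile.

    For bin i, the mean of the ``window_bins`` x ``window_bins`` square of
    contacts crossing i (rows i-w..i-1, columns i+1..i+w), divided by the
    chromosome mean of that statistic, logged and z-scored.  Bins closer
    than the window to either edge are NaN.  The ratio construction makes
    the track invariant to global count scaling.
    """
    if window_bins < 2:
        raise ValueError("window_bins must be >= 2")
    m = matrix.counts
    n = matrix.n_bins
    raw = np.full(n, np.nan)
    for i in range(window_bins, n - window_bins):
        raw[i] = m[i - window_bins : i, i + 1 : i + 1 + window_bins].mean()
    valid = ~np.isnan(raw)
    mean = np.nanmean(raw[valid]) if valid.any() else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        logr = np.where(valid & (raw > 0), np.log2(raw / mean), np.nan)
    ok = ~np.isnan(logr)
    if ok.sum() > 1 and np.nanstd(logr[ok]) > 0:
        z = (logr - np.nanmean(logr[ok])) / np.nanstd(logr[ok])
    else:
        z = np.where(ok, 0.0, np.nan)
    return SignalTrack(matrix.chrom, matrix.resolution, z)


def call_boundaries(
    insulation: SignalTrack, stage: str = ".", delta_min: float = 0.1
) -> list[BoundaryCall]:
    """Boundaries = local insulation minima with prominence >= delta_min.

    Prominence is measured in z units; plateau ties resolve to the
    leftmost bin.
    """
    z = insulation.values
    valid = ~np.isnan(z)
    if valid.sum() < 3:
        return []
    lo, hi = np.flatnonzero(valid)[[0, -1]]
    seg = z[lo : hi + 1]
    peaks, props = find_peaks(-seg, prominence=delta_min, plateau_size=1)
    bins = props.get("left_edges", peaks)
    return [
        BoundaryCall(insulation.chrom, int(lo + b), stage, float(z[lo + b]))
        for b in bins
    ]


def boundary_similarity(
    boundary_bin: int,
    track_a: SignalTrack,
    track_b: SignalTrack,
    flank_bins: int = 10,
) -> float:
    """Spearman rho between the two insulation windows centered on a bin.

    Windows span ``flank_bins`` on each side (21 points at the default 10
    bins / +-200 kb at 20 kb resolution).  NaN bins are dropped pairwise;
    fewer than 11 complete pairs yields NaN.
    """
    a, b = track_a.values, track_b.values
    if boundary_bin < flank_bins or boundary_bin + flank_bins >= min(len(a), len(b)):
        return float("nan")
    wa = a[boundary_bin - flank_bins : boundary_bin + flank_bins + 1]
    wb = b[boundary_bin - flank_bins : boundary_bin + flank_bins + 1]
    ok = ~(np.isnan(wa) | np.isnan(wb))
    if ok.sum() < MIN_VALID_PAIRS:
        warnings.warn("fewer than 11 complete pairs in boundary window")
        return float("nan")
    rho, _ = stats.spearmanr(wa[ok], wb[ok])
    return float(rho)


def boundary_null(
    track_a: SignalTrack,
    track_b: SignalTrack,
    n_perm: int = 1000,
    flank_bins: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Null window-correlation distribution from randomly selected bins.

    Each draw picks one uniformly random bin (with a full window in both
    tracks) and correlates the two stages' windows at that same bin;
    repeated ``n_perm`` times (1,000 by default), deterministic per seed.
    """
    n = min(len(track_a.values), len(track_b.values))
    candidates = [
        i
        for i in range(flank_bins, n - flank_bins)
        if not np.isnan(track_a.values[i]) and not np.isnan(track_b.values[i])
    ]
    if not candidates:
        raise ValueError("tracks too short for the requested window")
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm)
    picks = rng.choice(candidates, size=n_perm, replace=True)
    for k, i in enumerate(picks):
        out[k] = boundary_similarity(int(i), track_a, track_b, flank_bins)
    return out


def classify_specific_boundaries(
    stage_boundaries: Mapping[str, Sequence[BoundaryCall]],
    tracks: Mapping[str, SignalTrack],
    stage_order: Sequence[str],
    match_tolerance_bins: int = 1,
    alpha_quantile: float = 0.95,
    n_perm: int = 1000,
    flank_bins: int = 10,
    seed: int = 0,
) -> list[BoundaryCall]:
    """Flag stage-specific boundaries by the two-criterion test.

    A boundary in stage s is specific iff (1) no boundary of any adjacent
    stage lies within +-``match_tolerance_bins`` bins, and (2) for every
    adjacent stage the insulation-window Spearman rho does not exceed that
    stage pair's null ``alpha_quantile`` (high rho = similar landscape, so
    the test is one-sided upward).  Returns all boundaries with the
    ``specific`` flag, rho map and null quantile filled in.
    """
    adjacency = {s: [] for s in stage_order}
    for s_prev, s_next in zip(stage_order[:-1], stage_order[1:]):
        adjacency[s_prev].append(s_next)
        adjacency[s_next].append(s_prev)
    # one null per ordered stage pair, derived deterministically from seed
    null_q: dict[tuple[str, str], float] = {}
    for si, s in enumerate(stage_order):
        for adj in adjacency[s]:
            key = (s, adj)
            if key not in null_q:
                sub = (seed + 7919 * si + 104729 * stage_order.index(adj)) % (2**31)
                null = boundary_null(tracks[s], tracks[adj], n_perm, flank_bins, sub)
                null_q[key] = float(np.nanquantile(null, alpha_quantile))
    out: list[BoundaryCall] = []
    for s in stage_order:
        for b in stage_boundaries.get(s, []):
            b.spearman_vs_adjacent = {}
            solo = True
            for adj in adjacency[s]:
                for ob in stage_boundaries.get(adj, []):
                    if ob.chrom == b.chrom and abs(ob.bin - b.bin) <= match_tolerance_bins:
                        solo = False
            nonsig = True
            for adj in adjacency[s]:
                rho = boundary_similarity(b.bin, tracks[s], tracks[adj], flank_bins)
                b.spearman_vs_adjacent[adj] = rho
                b.null_quantile = null_q[(s, adj)]
                if not np.isnan(rho) and rho > null_q[(s, adj)]:
                    nonsig = False
            b.specific = bool(solo and nonsig and adjacency[s])
            out.append(b)
    return out


# ---------------------------------------------------------------------------
# intra-TAD strength and loops
# ---------------------------------------------------------------------------


def tads_from_boundaries(
    boundaries: Sequence[int], n_bins: int, resolution: int, chrom: str
) -> list[GenomicInterval]:
    """Partition a chromosome into TAD intervals at boundary bins."""
    cuts = sorted(set(b for b in boundaries if 0 < b < n_bins))
    edges = [0] + cuts + [n_bins]
    return [
        GenomicInterval(chrom, a * resolution, b * resolution, f"{chrom}_tad_{i}")
        for i, (a, b) in enumerate(zip(edges[:-1], edges[1:]))
        if b > a
    ]


def intra_tad_strength(
    matrix: ContactMatrix, tads: Sequence[GenomicInterval]
) -> np.ndarray:
    """Per-TAD mean contact among interior bin pairs (diagonal excluded).

    TADs spanning fewer than 2 bins give NaN.  Cross-stage comparison is a
    two-sample test on these per-TAD values.
    """
    res = matrix.resolution
    out = np.full(len(tads), np.nan)
    for k, tad in enumerate(tads):
        b0 = tad.start // res
        b1 = min(matrix.n_bins, -(-tad.end // res))
        if b1 - b0 < 2:
            continue
        block = matrix.counts[b0:b1, b0:b1]
        mask = ~np.eye(block.shape[0], dtype=bool)
        out[k] = block[mask].mean()
    return out


def merge_loops(
    loop_sets: Sequence[Sequence[LoopCall]], merge_resolution: int = 25000
) -> list[LoopCall]:
    """Integrate loops called at several resolutions into one bin size.

    Each anchor is re-binned by midpoint at ``merge_resolution``; loops
    identical after re-binning collapse to a single call keeping the
    maximum score.  Output anchors are merge_resolution-sized intervals,
    so the operation is idempotent.
    """
    best: dict[tuple[str, int, int], float] = {}
    for loops in loop_sets:
        for lp in loops:
            b1 = lp.anchor1.midpoint // merge_resolution
            b2 = lp.anchor2.midpoint // merge_resolution
            if b1 > b2:
                b1, b2 = b2, b1
            key = (lp.anchor1.chrom, b1, b2)
            if key not in best or lp.score > best[key]:
                best[key] = lp.score
    out = []
    for (chrom, b1, b2), score in sorted(best.items()):
        out.append(
            LoopCall(
                GenomicInterval(chrom, b1 * merge_resolution, (b1 + 1) * merge_resolution),
                GenomicInterval(chrom, b2 * merge_resolution, (b2 + 1) * merge_resolution),
                merge_resolution,
                score,
            )
        )
    return out


def link_distal(
    loops: Sequence[LoopCall],
    enhancers: Sequence[GenomicInterval],
    promoters: Sequence[GenomicInterval],
) -> list[dict]:
    """Enhancer-gene pairs bridged by a loop.

    A pair is emitted when one anchor overlaps the enhancer and the other
    overlaps the promoter (>= 1 bp each); promoters carry gene_id in
    ``name``.  Distance is |enhancer midpoint - promoter midpoint| (the
    promoter midpoint is the TSS for symmetric promoter windows).
    """
    anchors1 = [lp.anchor1 for lp in loops]
    anchors2 = [lp.anchor2 for lp in loops]
    e_on_1 = _anchor_map(anchors1, enhancers)
    e_on_2 = _anchor_map(anchors2, enhancers)
    p_on_1 = _anchor_map(anchors1, promoters)
    p_on_2 = _anchor_map(anchors2, promoters)
    pairs: list[dict] = []
    seen: set[tuple] = set()
    for li in range(len(loops)):
        for e_side, p_side in ((e_on_1, p_on_2), (e_on_2, p_on_1)):
            for ei in e_side.get(li, []):
                for pi in p_side.get(li, []):
                    enh, prom = enhancers[ei], promoters[pi]
                    key = (li, ei, pi)
                    if key in seen:
                        continue
                    seen.add(key)
                    pairs.append(
                        {
                            "enhancer": enh,
                            "gene_id": prom.name,
                            "loop_id": li,
                            "distance_bp": abs(enh.midpoint - prom.midpoint),
                        }
                    )
    return pairs


def _anchor_map(anchors, features) -> dict[int, list[int]]:
    m: dict[int, list[int]] = {}
    for ai, fi in overlap(anchors, features):
        m.setdefault(ai, []).append(fi)
    return m
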