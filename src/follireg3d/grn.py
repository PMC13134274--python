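"""TAD-constrained tripartite TF -> Enhancer -> Target network inference.

Enhancer-gene candidates are restricted to pairs sharing a TAD and scored
by Pearson correlation of H3K27ac signal vs expression across stages (BH
across all tested pairs genome-wide, FDR < 0.05 retained).  TF-enhancer
edges come from log-odds PWM scanning plus a hypergeometric enrichment
test (P < 1e-5).  Network statistics: stability under random edge removal
and a degree-preserving rewiring permutation test on the TF->gene path
count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GenomicInterval, Pwm, overlap


@dataclass
class EnhGenePair:
    enhancer: GenomicInterval
    gene_id: str
    tad_id: str
    pearson_r: float
    p: float
    fdr: float = float("nan")
    distance_bp: int = 0
    mode: str = "proximal_in_tad"


@dataclass
class MotifHit:
    seq_id: str
    position: int
    strand: str
    score: float


@dataclass
class TfEnhPair:
    tf_name: str
    enhancer_id: str
    motif_hits: int
    enrichment_p: float


@dataclass
class RegNetwork:
    """Tripartite TF -> enhancer -> gene graph.

    Edges are stored per layer; a TF->gene *path* exists iff some enhancer
    carries both a TF edge and a gene edge.
    """

    tf_edges: set[tuple[str, str]] = field(default_factory=set)   # (tf, enh)
    gene_edges: set[tuple[str, str]] = field(default_factory=set)  # (enh, gene)
    tf_edge_attr: dict[tuple[str, str], dict] = field(default_factory=dict)
    gene_edge_attr: dict[tuple[str, str], dict] = field(default_factory=dict)

    @property
    def tfs(self) -> set[str]:
        return {t for t, _ in self.tf_edges}

    @property
    def enhancers(self) -> set[str]:
        return {e for _, e in self.tf_edges} | {e for e, _ in self.gene_edges}

    @property
    def genes(self) -> set[str]:
        return {g for _, g in self.gene_edges}

    def paths(
        self,
        tf_edges: set[tuple[str, str]] | None = None,
        gene_edges: set[tuple[str, str]] | None = None,
    ) -> set[tuple[str, str]]:
        """All (tf, gene) pairs connected through at least one enhancer."""
        tf_edges = self.tf_edges if tf_edges is None else tf_edges
        gene_edges = self.gene_edges if gene_edges is None else gene_edges
        by_enh: dict[str, list[str]] = {}
        for e, g in gene_edges:
            by_enh.setdefault(e, []).append(g)
        out: set[tuple[str, str]] = set()
        for t, e in tf_edges:
            for g in by_enh.get(e, []):
                out.add((t, g))
        return out

    def targets_of(self, tf: str) -> set[str]:
        return {g for t, g in self.paths() if t == tf}

    def summary(self) -> dict[str, int]:
        return {
            "n_tfs": len(self.tfs),
            "n_enhancers": len(self.enhancers),
            "n_genes": len(self.genes),
            "n_paths": len(self.paths()),
            "n_edges": len(self.tf_edges) + len(self.gene_edges),
        }

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for t, e in sorted(self.tf_edges):
            rows.append({"layer": "tf_enhancer", "source": t, "target": e,
                         **self.tf_edge_attr.get((t, e), {})})
        for e, g in sorted(self.gene_edges):
            rows.append({"layer": "enhancer_gene", "source": e, "target": g,
                         **self.gene_edge_attr.get((e, g), {})})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# enhancer-gene correlation within TADs
# ---------------------------------------------------------------------------


def enhancer_id(iv: GenomicInterval) -> str:
    return iv.name if iv.name not in (".", "") else f"{iv.chrom}:{iv.start}-{iv.end}"


def correlate_in_tad(
    enh_signal: pd.DataFrame,
    enhancers: Sequence[GenomicInterval],
    expr_means: pd.DataFrame,
    gene_tss: Sequence[GenomicInterval],
    tads: Sequence[GenomicInterval],
    fdr_max: float = 0.05,
) -> tuple[list[EnhGenePair], dict]:
    """Pearson-correlate enhancer activity with expression within TADs.

    ``enh_signal``: enhancer x stage region-mean H3K27ac; ``expr_means``:
    gene x stage expression means on the same stage columns; ``gene_tss``
    intervals carry gene_id in ``name``.  Every (enhancer, gene) pair
    whose enhancer midpoint and TSS fall into the same TAD is tested (r,
    exact-t p, df = n_stages - 2); BH runs across all tested pairs
    genome-wide; pairs with fdr < ``fdr_max`` are returned.  Constant
    vectors are skipped and counted in the report.
    """
    stages = [s for s in enh_signal.columns if s in expr_means.columns]
    if len(stages) < 3:
        raise ValueError("need >= 3 shared stages for correlation")
    enh_mid = [GenomicInterval(e.chrom, e.midpoint, e.midpoint + 1) for e in enhancers]
    tss_pts = list(gene_tss)
    e_tad = {ei: ti for ei, ti in overlap(enh_mid, list(tads))}
    g_tad: dict[int, int] = {gi: ti for gi, ti in overlap(tss_pts, list(tads))}
    genes_by_tad: dict[int, list[int]] = {}
    for gi, ti in g_tad.items():
        genes_by_tad.setdefault(ti, []).append(gi)
    sig = enh_signal[stages].to_numpy(dtype=float)
    ex = expr_means[stages].to_numpy(dtype=float)
    gene_index = {g: k for k, g in enumerate(expr_means.index)}
    tested: list[tuple[int, int, int, float, float]] = []
    n_skipped = 0
    for ei, ti in e_tad.items():
        x = sig[ei]
        for gi in genes_by_tad.get(ti, []):
            gid = tss_pts[gi].name
            if gid not in gene_index:
                continue
            y = ex[gene_index[gid]]
            if np.std(x) == 0 or np.std(y) == 0:
                n_skipped += 1
                continue
            r, p = stats.pearsonr(x, y)
            tested.append((ei, gi, ti, float(r), float(p)))
    report = {"n_tested": len(tested), "n_skipped_constant": n_skipped}
    if not tested:
        return [], report
    pvals = np.array([t[4] for t in tested])
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    pairs = []
    for (ei, gi, ti, r, p), q in zip(tested, fdr):
        if q < fdr_max:
            enh = enhancers[ei]
            pairs.append(
                EnhGenePair(
                    enhancer=enh,
                    gene_id=tss_pts[gi].name,
                    tad_id=tads[ti].name,
                    pearson_r=r,
                    p=p,
                    fdr=float(q),
                    distance_bp=abs(enh.midpoint - tss_pts[gi].midpoint),
                )
            )
    report["n_significant"] = len(pairs)
    return pairs, report


# ---------------------------------------------------------------------------
# PWM scanning and enrichment
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")
_ENCODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def scan_pwm(
    sequences: Mapping[str, str], pwm: Pwm, score_fraction: float = 0.8
) -> list[MotifHit]:
    """Log-odds scan of both strands at every position.

    A hit requires score >= ``score_fraction`` x the maximum achievable
    log-odds score of the PWM.  Windows containing N are skipped.
    Sequences shorter than the motif yield no hits.
    """
    lods = np.log2(pwm.matrix / pwm.background[None, :])
    max_score = float(lods.max(axis=1).sum())
    threshold = score_fraction * max_score
    L = len(pwm)
    hits: list[MotifHit] = []
    # batch sequences of equal length for a vectorized scan
    by_len: dict[int, list[str]] = {}
    for sid, seq in sequences.items():
        if len(seq) >= L:
            by_len.setdefault(len(seq), []).append(sid)
    for slen, ids in by_len.items():
        n_pos = slen - L + 1
        for strand in ("+", "-"):
            codes = np.empty((len(ids), slen), dtype=np.int8)
            for r, sid in enumerate(ids):
                s = sequences[sid].upper()
                if strand == "-":
                    s = s.translate(_COMP)[::-1]
                codes[r] = _encode(s)
            scores = np.zeros((len(ids), n_pos))
            bad = np.zeros((len(ids), n_pos), dtype=bool)
            for k in range(L):
                col = codes[:, k : k + n_pos]
                bad |= col < 0
                scores += np.where(col >= 0, lods[k, np.clip(col, 0, 3)], 0.0)
            for r, pos in zip(*np.nonzero((~bad) & (scores >= threshold))):
                orig = int(pos) if strand == "+" else slen - L - int(pos)
                hits.append(MotifHit(ids[r], orig, strand, float(scores[r, pos])))
    hits.sort(key=lambda h: (h.seq_id, h.position, h.strand))
    return hits


def motif_enrichment(
    target_seqs: Mapping[str, str],
    background_seqs: Mapping[str, str],
    pwms: Sequence[Pwm],
    p_max: float = 1e-5,
    score_fraction: float = 0.8,
) -> tuple[list[TfEnhPair], pd.DataFrame]:
    """Per-TF hypergeometric motif enrichment in target vs background.

    Sequences are binarized (>= 1 hit).  With ``n_t`` targets, ``n_b``
    backgrounds (two disjoint sets; pass the complement of the target set
    as background), K total hit sequences and k target hit sequences, the
    one-sided p is P(X >= k), X ~ Hypergeom(n_t + n_b, K, n_t).  TFs with
    p < ``p_max`` are enriched; TF-enhancer pairs are emitted for every
    (enriched TF, target enhancer with >= 1 hit).
    """
    if not target_seqs:
        raise ValueError("target set must be non-empty")
    if not background_seqs:
        raise ValueError("background set must be non-empty")
    n_t, n_b = len(target_seqs), len(background_seqs)
    rows = []
    pairs: list[TfEnhPair] = []
    for pwm in pwms:
        t_hits = scan_pwm(target_seqs, pwm, score_fraction)
        b_hits = scan_pwm(background_seqs, pwm, score_fraction)
        t_ids: dict[str, int] = {}
        for h in t_hits:
            t_ids[h.seq_id] = t_ids.get(h.seq_id, 0) + 1
        b_ids = {h.seq_id for h in b_hits}
        k = len(t_ids)
        K = k + len(b_ids)
        p = float(stats.hypergeom.sf(k - 1, n_t + n_b, K, n_t)) if K else 1.0
        enriched = p < p_max
        rows.append(
            {"tf_name": pwm.tf_name, "target_hits": k, "background_hits": len(b_ids),
             "n_target": n_t, "n_background": n_b, "p": p, "enriched": enriched}
        )
        if enriched:
            for sid, nh in sorted(t_ids.items()):
                pairs.append(TfEnhPair(pwm.tf_name, sid, nh, p))
    return pairs, pd.DataFrame(rows).set_index("tf_name")


# ---------------------------------------------------------------------------
# network assembly and statistics
# ---------------------------------------------------------------------------


def assemble_grn(
    tf_enh: Sequence[TfEnhPair], enh_gene: Sequence[EnhGenePair]
) -> RegNetwork:
    """Join the two edge layers on shared enhancer identifiers."""
    net = RegNetwork()
    for te in tf_enh:
        net.tf_edges.add((te.tf_name, te.enhancer_id))
        net.tf_edge_attr[(te.tf_name, te.enhancer_id)] = {
            "motif_hits": te.motif_hits, "enrichment_p": te.enrichment_p,
        }
    for eg in enh_gene:
        eid = enhancer_id(eg.enhancer)
        net.gene_edges.add((eid, eg.gene_id))
        net.gene_edge_attr[(eid, eg.gene_id)] = {
            "pearson_r": eg.pearson_r, "fdr": eg.fdr, "mode": eg.mode,
        }
    return net


@dataclass
class StabilityReport:
    removal_fraction: float
    trials: int
    stability_score: float
    permutation_p: float = float("nan")
    n_perm: int = 0
    seed: int = 0


def stability_score(
    grn: RegNetwork,
    removal_fraction: float = 0.1,
    trials: int = 100,
    seed: int = 0,
) -> StabilityReport:
    """Mean fraction of TF->gene paths surviving random edge removal.

    Each trial removes floor(removal_fraction x E) edges uniformly at
    random from the pooled edge set and recomputes path survival.
    """
    if not (0 < removal_fraction < 1):
        raise ValueError("removal_fraction must be in (0, 1)")
    edges = sorted(grn.tf_edges) + sorted(grn.gene_edges)
    n_tf = len(grn.tf_edges)
    if len(edges) < 10:
        raise ValueError("network too small (< 10 edges)")
    base_paths = grn.paths()
    if not base_paths:
        raise ValueError("network has no TF->gene paths")
    n_remove = int(removal_fraction * len(edges))
    rng = np.random.default_rng(seed)
    scores = np.empty(trials)
    for t in range(trials):
        drop = set(rng.choice(len(edges), size=n_remove, replace=False)) if n_remove else set()
        tf_kept = {edges[i] for i in range(n_tf) if i not in drop}
        gene_kept = {edges[i] for i in range(n_tf, len(edges)) if i not in drop}
        surviving = grn.paths(tf_kept, gene_kept)
        scores[t] = len(base_paths & surviving) / len(base_paths)
    return StabilityReport(removal_fraction, trials, float(scores.mean()), seed=seed)


def _rewire_layer(
    edges: list[tuple[str, str]], rng: np.random.Generator, n_swaps: int
) -> list[tuple[str, str]]:
    """Degree-preserving double-edge swaps within one bipartite layer."""
    edges = list(edges)
    edge_set = set(edges)
    m = len(edges)
    if m < 2:
        return edges
    attempts = 0
    done = 0
    while done < n_swaps and attempts < 20 * n_swaps:
        attempts += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        (a, b), (c, d) = edges[i], edges[j]
        if a == c or b == d:
            continue
        if (a, d) in edge_set or (c, b) in edge_set:
            continue
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add((a, d))
        edge_set.add((c, b))
        edges[i], edges[j] = (a, d), (c, b)
        done += 1
    return edges


def permutation_test(
    grn: RegNetwork, n_perm: int = 1000, seed: int = 0, check_degrees: bool = False
) -> tuple[float, np.ndarray]:
    """Rewiring permutation test on the TF->gene path count.

    Null replicates rewire each bipartite layer by degree-preserving
    double-edge swaps (10 x E attempted swaps per layer); the statistic is
    the number of distinct TF->gene paths.  The test is two-sided
    (p = (1 + 2 min(#{null >= obs}, #{null <= obs})) / (n_perm + 1),
    capped at 1): a redundantly wired circuit, where several enhancers
    carry the same TF to the same gene, has *fewer* distinct paths than
    its degree-preserving null, so "distinct from random" must consider
    both tails.
    """
    tf_edges = sorted(grn.tf_edges)
    gene_edges = sorted(grn.gene_edges)
    if len(tf_edges) < 2 or len(gene_edges) < 2:
        warnings.warn("layers too small to rewire; permutation p undefined")
        return float("nan"), np.array([])
    observed = len(grn.paths())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        t_new = _rewire_layer(tf_edges, rng, 10 * len(tf_edges))
        g_new = _rewire_layer(gene_edges, rng, 10 * len(gene_edges))
        if check_degrees:
            for old, new in ((tf_edges, t_new), (gene_edges, g_new)):
                for side in (0, 1):
                    assert _degrees(old, side) == _degrees(new, side)
        null[k] = len(grn.paths(set(t_new), set(g_new)))
    hi = int(np.sum(null >= observed))
    lo = int(np.sum(null <= observed))
    p = min(1.0, (1 + 2 * min(hi, lo)) / (n_perm + 1))
    return float(p), null


def _degrees(edges: Sequence[tuple[str, str]], side: int) -> dict[str, int]:
    d: dict[str, int] = {}
    for e in edges:
        d[e[side]] = d.get(e[side], 0) + 1
    return d


# ---------------------------------------------------------------------------
# core TFs and variant mapping
# ---------------------------------------------------------------------------


def extract_core_tfs(
    grn: RegNetwork,
    dynamic_enrichment: pd.DataFrame,
    deg_tfs: set[str],
    clusters: Mapping[str, int],
    co_min: float = 0.3,
    p_max: float = 1e-5,
) -> tuple[set[str], pd.DataFrame]:
    """Core TFs by the two-criterion rule.

    Criterion 1: the TF's motif is enriched (p < ``p_max``) in dynamic
    enhancers vs all enhancers (``dynamic_enrichment`` is the table from
    :func:`motif_enrichment` with that target/background split).
    Criterion 2: the TF is a differential gene in >= 1 adjacent-stage
    contrast AND at least ``co_min`` of its target genes share the TF's
    expression cluster.  TFs absent from the cluster map fail criterion 2.
    """
    rows = []
    core: set[str] = set()
    for tf in sorted(grn.tfs):
        enr_p = (
            float(dynamic_enrichment.loc[tf, "p"]) if tf in dynamic_enrichment.index else 1.0
        )
        c1 = enr_p < p_max
        targets = grn.targets_of(tf)
        if tf in clusters and targets:
            shared = sum(1 for g in targets if clusters.get(g) == clusters[tf])
            co_frac = shared / len(targets)
        else:
            co_frac = 0.0
        c2 = (tf in deg_tfs) and (tf in clusters) and co_frac >= co_min
        if c1 and c2:
            core.add(tf)
        rows.append(
            {"tf_name": tf, "dynamic_enrichment_p": enr_p, "is_deg": tf in deg_tfs,
             "co_cluster_fraction": co_frac, "core": c1 and c2}
        )
    return core, pd.DataFrame(rows).set_index("tf_name")


def variant_to_gene(
    gwas_loci: Sequence[GenomicInterval],
    enhancers: Sequence[GenomicInterval],
    links: Sequence[EnhGenePair],
) -> pd.DataFrame:
    """Map GWAS loci to genes through enhancer overlap and E-G links.

    One row per (locus, enhancer, linked gene); loci in no enhancer or in
    unlinked enhancers contribute no rows.
    """
    links_by_enh: dict[tuple[str, int, int], list[EnhGenePair]] = {}
    for lk in links:
        key = (lk.enhancer.chrom, lk.enhancer.start, lk.enhancer.end)
        links_by_enh.setdefault(key, []).append(lk)
    rows = []
    for li, ei in overlap(list(gwas_loci), list(enhancers)):
        enh = enhancers[ei]
        for lk in links_by_enh.get((enh.chrom, enh.start, enh.end), []):
            rows.append(
                {
                    "locus": gwas_loci[li].name or f"{gwas_loci[li].chrom}:{gwas_loci[li].start}",
                    "enhancer": enhancer_id(enh),
                    "gene_id": lk.gene_id,
                    "mode": lk.mode,
                    "pearson_r": lk.pearson_r,
                }
            )
    return pd.DataFrame(rows, columns=["locus", "enhancer", "gene_id", "mode", "pearson_r"])
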