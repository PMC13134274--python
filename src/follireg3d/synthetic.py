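"""Synthetic staged multi-omics dataset with planted ground truth.

Emulates the study design: seven ordered granulosa-cell stages (SWF, LWF,
SYF, F5, F3, F1, POF) with replicated expression, per-stage H3K27ac /
H3K27me3 elements with planted super-enhancers / super-silencers, binned
Hi-C contact matrices at three stages (SYF, F5, F1) with planted TADs,
stage-specific boundaries and a checkerboard compartment structure, loop
calls at three resolutions, enhancer sequences with planted motif
occurrences, PWMs for planted and decoy TFs, and GWAS loci.  Every
planted object is recorded in a ground-truth manifest keyed to the
recovery tests.

All randomness flows from one seed through named substreams, so any
single layer regenerates identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    ContactMatrix,
    GenomicInterval,
    LoopCall,
    Pwm,
    write_bed,
    write_bedgraph,
    write_bedpe,
    write_contact_matrices,
    write_fasta,
    write_json,
    write_meme,
)
from .expression import STAGES, ExpressionMatrix

HIC_STAGES = ("SYF", "F5", "F1")

# log2-scale stage-mean archetypes over the 7 stages: one peak per stage
# plus a hierarchical-high profile (F5/F3/F1), qualitatively mirroring the
# observed expression cluster shapes.
_BASE, _PEAK = 3.0, 9.0


def stage_archetypes() -> np.ndarray:
    arch = np.full((8, 7), _BASE)
    for k in range(7):
        arch[k, k] = _PEAK
    arch[7, 3:6] = _PEAK  # hierarchical stages F5, F3, F1
    return arch


@dataclass
class SimConfig:
    """Default study conditions for the synthetic dataset."""

    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    bin_size: int = 20_000
    n_genes: int = 600
    n_enhancers: int = 800
    n_replicates: int = 4
    noise_sd: float = 0.3          # log2-scale replicate / signal noise
    tad_enrichment: float = 3.0
    compartment_enrichment: float = 1.5
    hic_depth: float = 150.0       # Poisson mean scale at distance 1
    n_circuit_tfs: int = 10
    n_core_tfs: int = 5
    n_decoy_tfs: int = 20
    targets_per_tf: int = 3
    enhancers_per_target: int = 4
    n_distal_links: int = 30
    n_decoy_loops: int = 60
    loop_resolutions: tuple = (10_000, 20_000, 25_000)
    merge_resolution: int = 25_000
    n_se_shared: int = 10
    n_se_specific_per_stage: int = 2
    n_ss_shared: int = 8
    n_ss_specific_per_stage: int = 1
    se_constituents: int = 4
    enhancer_length: int = 600
    motif_length: int = 12
    n_gwas_loci: int = 40
    n_gwas_in_enhancer: int = 12
    specific_boundaries_per_chrom: int = 5
    a_compartment_gene_bias: float = 0.75

    def validate(self) -> None:
        for chrom, ln in self.chrom_lengths.items():
            if not (5_000_000 <= ln <= 20_000_000):
                raise ValueError(f"{chrom}: chromosome length outside 5-20 Mb")
        if not (300 <= self.n_genes <= 2000):
            raise ValueError("n_genes outside the documented 300-2000 range")
        if not (500 <= self.n_enhancers <= 5000):
            raise ValueError("n_enhancers outside the documented 500-5000 range")
        n_se = self.n_se_shared + self.n_se_specific_per_stage * len(STAGES)
        if n_se > self.n_enhancers:
            raise ValueError("more super-enhancers requested than enhancers")
        n_circuit_enh = (
            self.n_circuit_tfs * self.targets_per_tf * self.enhancers_per_target
        )
        if n_circuit_enh + self.n_distal_links > self.n_enhancers:
            raise ValueError("circuit + distal enhancers exceed n_enhancers")
        if self.n_core_tfs > self.n_circuit_tfs:
            raise ValueError("n_core_tfs cannot exceed n_circuit_tfs")


@dataclass
class GroundTruth:
    """Planted objects, serialized alongside the data as a manifest."""

    seed: int
    planted_eg_links: list = field(default_factory=list)
    planted_distal_links: list = field(default_factory=list)
    planted_tf_circuit: list = field(default_factory=list)
    core_tfs: list = field(default_factory=list)
    decoy_tfs: list = field(default_factory=list)
    noncore_circuit_tfs: list = field(default_factory=list)
    se_regions: dict = field(default_factory=dict)       # stage -> [[chrom,s,e],...]
    ss_regions: dict = field(default_factory=dict)
    stage_specific_se: dict = field(default_factory=dict)
    specific_boundaries: list = field(default_factory=list)  # [stage, chrom, bin]
    shared_boundaries: list = field(default_factory=list)    # [chrom, bin]
    compartments: dict = field(default_factory=dict)     # chrom -> list of A/B
    deg_genes: dict = field(default_factory=dict)        # contrast -> gene -> dir
    cluster_labels: dict = field(default_factory=dict)   # gene -> archetype 0..7
    loop_truth: list = field(default_factory=list)
    gwas_truth: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimResult:
    config: SimConfig
    seed: int
    truth: GroundTruth
    genes: pd.DataFrame
    expression: ExpressionMatrix
    enhancers: list
    enhancer_presence: dict        # stage -> set of enhancer names
    enhancer_stage_signal: pd.DataFrame   # enhancer x stage region-mean
    h3k27ac_peaks: dict            # stage -> [GenomicInterval] (elements + SE parts)
    h3k27ac_signal: dict           # stage -> bedGraph records
    h3k27me3_peaks: dict
    h3k27me3_signal: dict
    matrices: dict                 # stage -> chrom -> ContactMatrix
    tads: dict                     # stage -> chrom -> [GenomicInterval]
    loops: dict                    # resolution -> [LoopCall]
    sequences: dict                # enhancer name -> sequence
    pwms: list
    gwas_loci: list


class _Occupancy:
    """Per-chromosome interval bookkeeping for collision-free placement."""

    def __init__(self, chrom_lengths: dict):
        self.used: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
        self.lengths = chrom_lengths

    def free(self, chrom: str, start: int, end: int) -> bool:
        if start < 0 or end > self.lengths[chrom]:
            return False
        return all(e <= start or s >= end for s, e in self.used[chrom])

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.used[chrom].append((start, end))

    def place(self, chrom, length, rng, lo=None, hi=None, margin=1000, tries=300):
        lo = 0 if lo is None else lo
        hi = self.lengths[chrom] if hi is None else hi
        for _ in range(tries):
            start = int(rng.integers(lo, max(lo + 1, hi - length)))
            if self.free(chrom, start - margin, start + length + margin):
                self.reserve(chrom, start, start + length)
                return start
        raise RuntimeError(f"could not place a {length} bp feature on {chrom}")


def _anchor_at(mid: int, resolution: int, target_bin: int, merge_resolution: int):
    """An r-sized anchor whose midpoint re-bins to ``target_bin`` at the
    merge resolution (emulates the same loop reported at several
    resolutions)."""
    for shift in (0, -1, 1):
        a = (mid // resolution + shift) * resolution
        if a >= 0 and (a + resolution // 2) // merge_resolution == target_bin:
            return a, a + resolution
    a = target_bin * merge_resolution
    return a, a + resolution


def generate(
    config: SimConfig | None = None, seed: int = 0, outdir: str | Path | None = None
) -> SimResult:
    """Generate the dataset (and optionally write it to ``outdir``).

    Deterministic per seed: regeneration is byte-identical on disk.
    """
    cfg = config or SimConfig()
    cfg.validate()
    ss = np.random.SeedSequence(seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ["layout", "expression", "elements", "hic", "loops", "sequences", "gwas"],
            ss.spawn(7),
        )
    }
    truth = GroundTruth(seed=seed)
    occ = _Occupancy(cfg.chrom_lengths)
    arch = stage_archetypes()
    res = cfg.bin_size
    rng = streams["layout"]

    # ---- TAD scaffold, boundaries, compartments -------------------------
    base_joints: dict[str, list[int]] = {}
    specific_joints: dict[str, list[tuple[str, int]]] = {}  # chrom -> [(stage, bin)]
    compartments: dict[str, np.ndarray] = {}
    for chrom, ln in cfg.chrom_lengths.items():
        n_bins = ln // res
        joints, pos = [], 0
        while True:
            pos += int(rng.integers(14, 25))
            if pos >= n_bins - 14:
                break
            joints.append(pos)
        base_joints[chrom] = joints
        truth.shared_boundaries += [[chrom, j] for j in joints]
        # stage-specific joints split large TADs, one stage each
        edges = [0] + joints + [n_bins]
        big = [
            k for k in range(1, len(edges) - 2)
            if edges[k + 1] - edges[k] >= 20
        ]
        rng.shuffle(big)
        chosen = big[: cfg.specific_boundaries_per_chrom]
        sp = []
        for idx, k in enumerate(sorted(chosen)):
            stage = HIC_STAGES[idx % len(HIC_STAGES)]
            joint = (edges[k] + edges[k + 1]) // 2
            sp.append((stage, joint))
            truth.specific_boundaries.append([stage, chrom, joint])
        specific_joints[chrom] = sp
        # compartment checkerboard: alternate label every 2 TADs
        labels = np.empty(n_bins, dtype="<U2")
        for k in range(len(edges) - 1):
            labels[edges[k] : edges[k + 1]] = "A" if (k // 2) % 2 == 0 else "B"
        compartments[chrom] = labels
        truth.compartments[chrom] = labels.tolist()

    def stage_partition(chrom: str, stage: str) -> list[int]:
        extra = [j for s, j in specific_joints[chrom] if s == stage]
        return sorted(base_joints[chrom] + extra)

    # ---- TF roster ------------------------------------------------------
    n_tfs = cfg.n_circuit_tfs + cfg.n_decoy_tfs
    tf_names = [f"TF{k:02d}" for k in range(n_tfs)]
    core_tfs = tf_names[: cfg.n_core_tfs]
    noncore = tf_names[cfg.n_core_tfs : cfg.n_circuit_tfs]
    decoys = tf_names[cfg.n_circuit_tfs :]
    truth.core_tfs = list(core_tfs)
    truth.noncore_circuit_tfs = list(noncore)
    truth.decoy_tfs = list(decoys)
    # archetypes: core TFs share their targets' archetype; non-core circuit
    # TFs are flat (fail the DEG criterion) or mis-clustered
    tf_target_arch = {tf: k % 7 for k, tf in enumerate(tf_names[: cfg.n_circuit_tfs])}
    tf_expr_arch: dict[str, int | None] = {}
    for k, tf in enumerate(tf_names):
        if tf in core_tfs:
            tf_expr_arch[tf] = tf_target_arch[tf]
        elif tf in noncore:
            # alternate failure modes for criterion 2
            tf_expr_arch[tf] = None if k % 2 else (tf_target_arch[tf] + 3) % 8
        else:
            tf_expr_arch[tf] = (k % 8) if k % 2 else None

    # ---- circuit placement ----------------------------------------------
    chroms = list(cfg.chrom_lengths)
    host_tads = []
    for chrom in chroms:
        n_bins = cfg.chrom_lengths[chrom] // res
        edges = [0] + base_joints[chrom] + [n_bins]
        split = {j for _, j in specific_joints[chrom]}
        for k in range(1, len(edges) - 2):
            a, b = edges[k], edges[k + 1]
            if b - a >= 14 and not any(a < j < b for j in split):
                host_tads.append((chrom, a, b))
    rng.shuffle(host_tads)
    n_targets = cfg.n_circuit_tfs * cfg.targets_per_tf
    if len(host_tads) < n_targets:
        raise ValueError("genome too small to host the planted circuit")
    # circuit TADs host only their own planted target gene; co-expressed
    # bystander genes would create real but unplanted correlations
    circuit_spans = [
        (chrom, a * res, b * res) for chrom, a, b in host_tads[:n_targets]
    ]

    def in_circuit_tad(chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos < e for c, s, e in circuit_spans)

    genes_rows = []
    enhancers: list[GenomicInterval] = []
    enh_meta: dict[str, dict] = {}
    gene_arch: dict[str, int | None] = {}

    def add_gene(gid, chrom, tss, strand="+"):
        genes_rows.append(
            {"gene_id": gid, "chrom": chrom, "start": tss, "end": tss + 2000,
             "strand": strand, "tss": tss}
        )

    eidx = 0

    def add_enhancer(chrom, start, meta):
        nonlocal eidx
        name = f"enh_{eidx:04d}"
        eidx += 1
        iv = GenomicInterval(chrom, start, start + cfg.enhancer_length, name)
        enhancers.append(iv)
        enh_meta[name] = meta
        return iv

    gidx = 0
    for t in range(n_targets):
        tf = tf_names[t // cfg.targets_per_tf]
        chrom, a, b = host_tads[t]
        lo, hi = (a + 2) * res, (b - 2) * res  # stay clear of TAD edges
        span = hi - lo
        gid = f"gene_{gidx:04d}"
        gidx += 1
        tss = occ.place(chrom, 2000, rng, lo + span // 10, lo + span // 10 + 5 * res)
        add_gene(gid, chrom, tss)
        gene_arch[gid] = tf_target_arch[tf]
        for e in range(cfg.enhancers_per_target):
            frac = 0.3 + 0.6 * e / max(1, cfg.enhancers_per_target - 1)
            base = lo + int(span * frac)
            start = occ.place(chrom, cfg.enhancer_length, rng, base, base + 3 * res)
            iv = add_enhancer(chrom, start, {"kind": "circuit", "tf": tf, "gene": gid})
            truth.planted_eg_links.append(
                {"enhancer": iv.name, "gene": gid, "chrom": chrom,
                 "start": iv.start, "end": iv.end}
            )
            truth.planted_tf_circuit.append({"tf": tf, "enhancer": iv.name, "gene": gid})

    # ---- distal loop links ----------------------------------------------
    mres = cfg.merge_resolution
    loop_sets: dict[int, list[LoopCall]] = {r: [] for r in cfg.loop_resolutions}
    for d in range(cfg.n_distal_links):
        chrom = chroms[d % len(chroms)]
        ln = cfg.chrom_lengths[chrom]
        for _ in range(300):
            b_e = int(streams["loops"].integers(4, ln // mres - 4))
            gap = int(streams["loops"].integers(10, 60))
            b_p = b_e + gap
            if b_p >= ln // mres - 4:
                continue
            e_lo, p_lo = b_e * mres, b_p * mres
            if occ.free(chrom, e_lo, e_lo + mres) and occ.free(chrom, p_lo, p_lo + mres):
                break
        else:
            raise RuntimeError("could not place distal loop link")
        # reserve both anchor bins wholesale so no other feature lands there
        occ.reserve(chrom, e_lo, e_lo + mres)
        occ.reserve(chrom, p_lo, p_lo + mres)
        e_start = e_lo + 8000 + int(streams["loops"].integers(0, 9000 - cfg.enhancer_length))
        iv = GenomicInterval(chrom, e_start, e_start + cfg.enhancer_length, f"enh_{eidx:04d}")
        eidx += 1
        enhancers.append(iv)
        enh_meta[iv.name] = {"kind": "loop", "gene": None}
        tss = p_lo + 8000 + int(streams["loops"].integers(0, 9000))
        gid = f"gene_{gidx:04d}"
        gidx += 1
        add_gene(gid, chrom, tss)
        gene_arch[gid] = None  # flat profile: recovered through loops, not correlation
        enh_meta[iv.name]["gene"] = gid
        truth.planted_distal_links.append(
            {"enhancer": iv.name, "gene": gid, "chrom": chrom,
             "anchor_bin_enh": b_e, "anchor_bin_prom": b_p}
        )
        truth.loop_truth.append([chrom, b_e, b_p])
        for r in cfg.loop_resolutions:
            a1 = _anchor_at(iv.midpoint, r, b_e, mres)
            a2 = _anchor_at(tss, r, b_p, mres)
            loop_sets[r].append(
                LoopCall(
                    GenomicInterval(chrom, a1[0], a1[1]),
                    GenomicInterval(chrom, a2[0], a2[1]),
                    r,
                    float(streams["loops"].uniform(1, 10)),
                )
            )
    # decoy loops in feature-free zones, some at multiple resolutions
    for d in range(cfg.n_decoy_loops):
        chrom = chroms[d % len(chroms)]
        ln = cfg.chrom_lengths[chrom]
        for _ in range(300):
            b1 = int(streams["loops"].integers(4, ln // mres - 4))
            b2 = b1 + int(streams["loops"].integers(8, 80))
            if b2 >= ln // mres - 4:
                continue
            if occ.free(chrom, b1 * mres, (b1 + 1) * mres) and occ.free(
                chrom, b2 * mres, (b2 + 1) * mres
            ):
                break
        else:
            continue
        occ.reserve(chrom, b1 * mres, (b1 + 1) * mres)
        occ.reserve(chrom, b2 * mres, (b2 + 1) * mres)
        n_res = int(streams["loops"].integers(1, len(cfg.loop_resolutions) + 1))
        for r in list(cfg.loop_resolutions)[:n_res]:
            a1 = _anchor_at(b1 * mres + mres // 2, r, b1, mres)
            a2 = _anchor_at(b2 * mres + mres // 2, r, b2, mres)
            loop_sets[r].append(
                LoopCall(
                    GenomicInterval(chrom, a1[0], a1[1]),
                    GenomicInterval(chrom, a2[0], a2[1]),
                    r,
                    float(streams["loops"].uniform(1, 10)),
                )
            )

    # ---- super-enhancer / super-silencer regions ------------------------
    se_regions: list[dict] = []
    width, gap = 1500, 3000
    se_span = cfg.se_constituents * width + (cfg.se_constituents - 1) * gap

    def plant_region(stage_set, kind):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = occ.place(chrom, se_span, rng, margin=14_000)
        parts = [
            (start + k * (width + gap), start + k * (width + gap) + width)
            for k in range(cfg.se_constituents)
        ]
        se_regions.append(
            {"chrom": chrom, "start": start, "end": start + se_span,
             "stages": stage_set, "kind": kind, "parts": parts}
        )

    plant_stages = list(STAGES)
    for _ in range(cfg.n_se_shared):
        plant_region(plant_stages, "SE")
    for s in plant_stages:
        for _ in range(cfg.n_se_specific_per_stage):
            plant_region([s], "SE")
    for _ in range(cfg.n_ss_shared):
        plant_region(plant_stages, "SS")
    for s in plant_stages:
        for _ in range(cfg.n_ss_specific_per_stage):
            plant_region([s], "SS")
    for s in plant_stages:
        truth.se_regions[s] = [
            [r["chrom"], r["start"], r["end"]]
            for r in se_regions
            if r["kind"] == "SE" and s in r["stages"]
        ]
        truth.ss_regions[s] = [
            [r["chrom"], r["start"], r["end"]]
            for r in se_regions
            if r["kind"] == "SS" and s in r["stages"]
        ]
        truth.stage_specific_se[s] = [
            [r["chrom"], r["start"], r["end"]]
            for r in se_regions
            if r["kind"] == "SE" and r["stages"] == [s]
        ]

    # ---- decoy enhancers and remaining genes ----------------------------
    n_decoy_enh = cfg.n_enhancers - len(enhancers)
    for _ in range(n_decoy_enh):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = occ.place(chrom, cfg.enhancer_length, rng)
        add_enhancer(chrom, start, {"kind": "decoy", "gene": None})

    # TF genes themselves (kept out of circuit TADs for the same reason)
    for tf in tf_names:
        for _ in range(300):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            try:
                tss = occ.place(chrom, 2000, rng, tries=5)
            except RuntimeError:
                continue
            if not in_circuit_tad(chrom, tss):
                break
            occ.used[chrom].remove((tss, tss + 2000))
        else:
            raise RuntimeError("could not place TF gene")
        add_gene(tf, chrom, tss)
        gene_arch[tf] = tf_expr_arch[tf]

    n_background = cfg.n_genes - len(genes_rows)
    n_arch_background = max(0, 8 * 50 - sum(1 for a in gene_arch.values() if a is not None))
    for k in range(n_background):
        gid = f"gene_{gidx:04d}"
        gidx += 1
        # bias placement toward the A compartment
        for _ in range(300):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            n_bins = cfg.chrom_lengths[chrom] // res
            want_a = rng.random() < cfg.a_compartment_gene_bias
            b = int(rng.integers(2, n_bins - 2))
            if k < n_arch_background and in_circuit_tad(chrom, b * res):
                continue
            if (compartments[chrom][b] == "A") == want_a:
                try:
                    tss = occ.place(chrom, 2000, rng, b * res, (b + 1) * res, tries=5)
                    break
                except RuntimeError:
                    continue
        else:
            raise RuntimeError("could not place background gene")
        add_gene(gid, chrom, tss)
        if k < n_arch_background:
            gene_arch[gid] = k % 8
        else:
            gene_arch[gid] = None

    genes = pd.DataFrame(genes_rows).set_index("gene_id", drop=False)
    truth.cluster_labels = {g: a for g, a in gene_arch.items() if a is not None}

    # ---- expression matrix ----------------------------------------------
    erng = streams["expression"]
    sample_ids = [f"{s}_{r + 1}" for s in STAGES for r in range(cfg.n_replicates)]
    log2_means = np.empty((len(genes), 7))
    for i, gid in enumerate(genes.index):
        a = gene_arch[gid]
        log2_means[i] = arch[a] if a is not None else np.full(7, 5.0)
    noise = (
        erng.normal(0.0, cfg.noise_sd, size=(len(genes), 7, cfg.n_replicates))
        if cfg.noise_sd > 0
        else np.zeros((len(genes), 7, cfg.n_replicates))
    )
    vals = np.maximum(0.0, 2.0 ** (log2_means[:, :, None] + noise) - 1.0)
    expr_df = pd.DataFrame(
        vals.reshape(len(genes), -1), index=genes.index, columns=sample_ids
    )
    expression = ExpressionMatrix(expr_df)
    # planted DEG directions from the noise-free archetype means
    lin_means = 2.0 ** log2_means - 1.0
    for s_a, s_b in zip(STAGES[:-1], STAGES[1:]):
        ia, ib = STAGES.index(s_a), STAGES.index(s_b)
        lfc = np.log2(lin_means[:, ib] + 1) - np.log2(lin_means[:, ia] + 1)
        contrast = {}
        for g, f in zip(genes.index, lfc):
            if f > 1:
                contrast[g] = "up"
            elif f < -1:
                contrast[g] = "down"
        truth.deg_genes[f"{s_a}_vs_{s_b}"] = contrast

    # ---- per-stage H3K27ac / H3K27me3 elements and signal ---------------
    elrng = streams["elements"]
    arch_z = arch  # log2 stage means drive element activity directly
    presence: dict[str, set[str]] = {s: set() for s in STAGES}
    ac_peaks: dict[str, list[GenomicInterval]] = {s: [] for s in STAGES}
    ac_signal: dict[str, list[GenomicInterval]] = {s: [] for s in STAGES}
    me_peaks: dict[str, list[GenomicInterval]] = {s: [] for s in STAGES}
    me_signal: dict[str, list[GenomicInterval]] = {s: [] for s in STAGES}
    enh_sig = pd.DataFrame(0.0, index=[e.name for e in enhancers], columns=list(STAGES))
    for iv in enhancers:
        meta = enh_meta[iv.name]
        if meta["kind"] == "circuit":
            tf = meta["tf"]
            target_profile = arch_z[tf_target_arch[tf]]
            dynamic = tf in core_tfs
            for si, s in enumerate(STAGES):
                active = target_profile[si] >= 6.0
                if dynamic and not active:
                    continue  # gained/lost element: absent off-peak
                v = float(2.0 ** (1.0 + 0.5 * target_profile[si] + elrng.normal(0, cfg.noise_sd)))
                presence[s].add(iv.name)
                enh_sig.loc[iv.name, s] = v
        else:
            for s in STAGES:
                v = float(2.0 ** (2.0 + elrng.normal(0, 0.5)))
                presence[s].add(iv.name)
                enh_sig.loc[iv.name, s] = v
    for s in STAGES:
        for iv in enhancers:
            v = enh_sig.loc[iv.name, s]
            if iv.name in presence[s]:
                rec = GenomicInterval(iv.chrom, iv.start, iv.end, iv.name, float(v))
                ac_peaks[s].append(rec)
                ac_signal[s].append(rec)
    # SE/SS constituents: high signal, present only in their stages
    for r in se_regions:
        target_peaks = ac_peaks if r["kind"] == "SE" else me_peaks
        target_sig = ac_signal if r["kind"] == "SE" else me_signal
        for s in r["stages"]:
            for k, (a, b) in enumerate(r["parts"]):
                v = float(2.0 ** (np.log2(25.0) + elrng.normal(0, cfg.noise_sd)))
                rec = GenomicInterval(
                    r["chrom"], a, b, f"{r['kind']}part_{r['chrom']}_{r['start']}_{k}", v
                )
                target_peaks[s].append(rec)
                target_sig[s].append(rec)
    # scattered typical H3K27me3 peaks so super-silencer ranking has a body
    for _ in range(150):
        chrom = chroms[int(elrng.integers(0, len(chroms)))]
        try:
            start = occ.place(chrom, 1000, elrng)
        except RuntimeError:
            continue
        for s in STAGES:
            v = float(2.0 ** (1.5 + elrng.normal(0, 0.4)))
            rec = GenomicInterval(chrom, start, start + 1000, ".", v)
            me_peaks[s].append(rec)
            me_signal[s].append(rec)
    for s in STAGES:
        for coll in (ac_peaks, ac_signal, me_peaks, me_signal):
            coll[s].sort(key=lambda g: (g.chrom, g.start))

    # ---- Hi-C matrices ---------------------------------------------------
    hrng = streams["hic"]
    matrices: dict[str, dict[str, ContactMatrix]] = {}
    tads: dict[str, dict[str, list[GenomicInterval]]] = {}
    for s in HIC_STAGES:
        matrices[s] = {}
        tads[s] = {}
        for chrom, ln in cfg.chrom_lengths.items():
            n_bins = ln // res
            joints = stage_partition(chrom, s)
            tad_id = np.zeros(n_bins, dtype=int)
            for j in joints:
                tad_id[j:] += 1
            comp = compartments[chrom]
            d = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins)))
            mean = cfg.hic_depth * (1.0 + d) ** -0.8
            same_tad = np.equal.outer(tad_id, tad_id)
            mean = mean * np.where(same_tad, cfg.tad_enrichment, 1.0)
            comp_codes = comp == "A"
            same_comp = np.equal.outer(comp_codes, comp_codes)
            mean = mean * np.where(same_comp, cfg.compartment_enrichment, 1.0)
            upper = np.triu(hrng.poisson(mean))
            counts = upper + np.triu(upper, 1).T
            matrices[s][chrom] = ContactMatrix(chrom, res, counts.astype(float))
            edges = [0] + joints + [n_bins]
            tads[s][chrom] = [
                GenomicInterval(chrom, a * res, b * res, f"{chrom}_tad_{k}")
                for k, (a, b) in enumerate(zip(edges[:-1], edges[1:]))
            ]

    # ---- PWMs and enhancer sequences ------------------------------------
    qrng = streams["sequences"]
    consensi: list[str] = []
    while len(consensi) < n_tfs:
        cand = "".join("ACGT"[i] for i in qrng.integers(0, 4, cfg.motif_length))
        if all(sum(a != b for a, b in zip(cand, c)) >= 4 for c in consensi):
            consensi.append(cand)
    pwms = []
    for tf, cons in zip(tf_names, consensi):
        mat = np.full((cfg.motif_length, 4), 0.1 / 3)
        for k, b in enumerate(cons):
            mat[k, "ACGT".index(b)] = 0.9
        pwms.append(Pwm(tf, mat))
    comp_tr = str.maketrans("ACGT", "TGCA")
    sequences: dict[str, str] = {}
    for iv in enhancers:
        seq = list("ACGT"[i] for i in qrng.integers(0, 4, cfg.enhancer_length))
        meta = enh_meta[iv.name]
        if meta["kind"] == "circuit":
            cons = consensi[tf_names.index(meta["tf"])]
            for _ in range(2):
                pos = int(qrng.integers(0, cfg.enhancer_length - cfg.motif_length))
                planted = cons if qrng.random() < 0.5 else cons.translate(comp_tr)[::-1]
                seq[pos : pos + cfg.motif_length] = list(planted)
        sequences[iv.name] = "".join(seq)

    # ---- GWAS loci -------------------------------------------------------
    grng = streams["gwas"]
    gwas: list[GenomicInterval] = []
    linked = [iv for iv in enhancers if enh_meta[iv.name]["kind"] == "circuit"]
    picks = grng.choice(len(linked), size=cfg.n_gwas_in_enhancer, replace=False)
    for k, pi in enumerate(picks):
        enh = linked[int(pi)]
        pos = int(grng.integers(enh.start, enh.end - 1))
        gwas.append(GenomicInterval(enh.chrom, pos, pos + 1, f"rs_{k:03d}"))
        truth.gwas_truth.append(
            {"locus": f"rs_{k:03d}", "enhancer": enh.name, "gene": enh_meta[enh.name]["gene"]}
        )
    for k in range(cfg.n_gwas_in_enhancer, cfg.n_gwas_loci):
        chrom = chroms[int(grng.integers(0, len(chroms)))]
        pos = occ.place(chrom, 1, grng)
        gwas.append(GenomicInterval(chrom, pos, pos + 1, f"rs_{k:03d}"))

    result = SimResult(
        config=cfg, seed=seed, truth=truth, genes=genes, expression=expression,
        enhancers=enhancers, enhancer_presence=presence, enhancer_stage_signal=enh_sig,
        h3k27ac_peaks=ac_peaks, h3k27ac_signal=ac_signal,
        h3k27me3_peaks=me_peaks, h3k27me3_signal=me_signal,
        matrices=matrices, tads=tads, loops=loop_sets,
        sequences=sequences, pwms=pwms, gwas_loci=gwas,
    )
    if outdir is not None:
        write_dataset(result, outdir)
    return result


def write_dataset(result: SimResult, outdir: str | Path) -> None:
    """Serialize every layer in the formats the readers consume."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    result.expression.values.to_csv(out / "expression.tsv", sep="\t")
    for s in STAGES:
        write_bed(result.h3k27ac_peaks[s], out / f"peaks_h3k27ac_{s}.bed")
        write_bedgraph(result.h3k27ac_signal[s], out / f"signal_h3k27ac_{s}.bedgraph")
        write_bed(result.h3k27me3_peaks[s], out / f"peaks_h3k27me3_{s}.bed")
        write_bedgraph(result.h3k27me3_signal[s], out / f"signal_h3k27me3_{s}.bedgraph")
    for s in HIC_STAGES:
        write_contact_matrices(result.matrices[s], out / f"hic_{s}.tsv")
    for r, loops in result.loops.items():
        write_bedpe(loops, out / f"loops_{r}.bedpe")
    write_bed(result.enhancers, out / "enhancers.bed")
    write_fasta(result.sequences, out / "enhancer_seqs.fasta")
    write_meme(result.pwms, out / "motifs.meme")
    write_bed(result.gwas_loci, out / "gwas_loci.bed")
    write_json(result.truth.to_dict(), out / "ground_truth.json")
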