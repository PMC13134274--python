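"""Shared domain types, file formats and interval arithmetic.

All coordinates are 0-based, half-open ``[start, end)`` internally.  Gene
tables supplied 1-based-inclusive (GTF-lite) are converted on read.  Strand
is carried through BED round-trips but ignored by interval arithmetic:
regulatory elements are treated as strandless; motif scanning handles both
strands explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

MISSING = float("nan")  #: sentinel for missing signal, distinct from 0

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A labeled genomic region, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp


@dataclass
class SignalTrack:
    """Binned per-chromosome signal; missing bins are NaN (never 0)."""

    chrom: str
    bin_size: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_bins(self) -> int:
        return len(self.values)


@dataclass
class Pwm:
    """Position probability matrix with background base frequencies.

    ``matrix`` is L x 4 over (A, C, G, T); every row sums to 1 and all
    entries are strictly positive (pseudocount applied upstream).
    """

    tf_name: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if np.any(self.matrix <= 0):
            raise ValueError("PWM entries must be > 0 (apply a pseudocount)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1 +- 1e-6")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class LoopCall:
    """A focal chromatin loop between two cis anchors."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    resolution: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("loop anchors must be on the same chromosome")
        if self.anchor1.start > self.anchor2.start:
            raise ValueError("anchor1 must not start after anchor2")


@dataclass
class ContactMatrix:
    """Symmetric binned cis Hi-C contact matrix for one chromosome."""

    chrom: str
    resolution: int
    counts: np.ndarray
    balanced: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n, m = self.counts.shape
        if n != m:
            raise ValueError("contact matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------


def overlap(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    min_bp: int = 1,
) -> list[tuple[int, int]]:
    """All (query index, subject index) pairs sharing >= ``min_bp`` bases.

    Half-open semantics: touching intervals share 0 bases and do not pair.
    Strand is ignored.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(subject):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    pairs: list[tuple[int, int]] = []
    for i, q in enumerate(query):
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(q.start, q.end):
            shared = min(q.end, hit.end) - max(q.start, hit.begin)
            if shared >= min_bp:
                pairs.append((i, hit.data))
    pairs.sort()
    return pairs


def subtract_elements(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Whole elements of A with zero (>=1 bp) overlap against B.

    Elements are never clipped: an element of A touched by any B element is
    dropped entirely.  With A, B the element sets of adjacent stages this
    yields stage-specific elements.
    """
    hit_a = {i for i, _ in overlap(set_a, set_b)}
    return [iv for i, iv in enumerate(set_a) if i not in hit_a]


def merge_intervals(
    intervals: Sequence[GenomicInterval], max_gap: int = 0
) -> list[list[int]]:
    """Group interval indices whose gaps are <= ``max_gap`` per chromosome.

    Returns groups of indices into ``intervals``; transitive closure of the
    pairwise gap relation, computed by a sorted sweep.
    """
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].chrom, intervals[i].start))
    groups: list[list[int]] = []
    cur: list[int] = []
    cur_chrom = None
    cur_end = -1
    for i in order:
        iv = intervals[i]
        if cur and iv.chrom == cur_chrom and iv.start - cur_end <= max_gap:
            cur.append(i)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                groups.append(cur)
            cur = [i]
            cur_chrom = iv.chrom
            cur_end = iv.end
    if cur:
        groups.append(cur)
    return groups


# ---------------------------------------------------------------------------
# BED / bedGraph / BEDPE
# ---------------------------------------------------------------------------


def read_bed(path: str | Path, n_columns: int | None = None) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into intervals, in file order.

    Missing name/score/strand columns are filled with ".", 0.0, ".".
    Malformed lines raise with the offending line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            ncol = n_columns if n_columns is not None else len(fields)
            if len(fields) < max(3, min(ncol, 3)):
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line") from exc
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, score, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path, n_columns: int = 6) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.name, f"{iv.score:g}", iv.strand]
            fh.write("\t".join(fields[:n_columns]) + "\n")


def read_bedgraph(path: str | Path) -> list[GenomicInterval]:
    """bedGraph records as intervals with the value in ``score``."""
    records: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
            try:
                records.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]), ".", float(fields[3]))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_bedgraph(records: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.score:g}\n")


def region_mean_signal(
    signal: Sequence[GenomicInterval], regions: Sequence[GenomicInterval]
) -> np.ndarray:
    """Per-region base-weighted mean of a bedGraph-style signal.

    Bases not covered by any signal record contribute 0, so the result is
    a true region mean, not a covered-base mean.
    """
    sums = np.zeros(len(regions))
    for ri, si in overlap(regions, signal):
        r, s = regions[ri], signal[si]
        shared = min(r.end, s.end) - max(r.start, s.start)
        sums[ri] += shared * s.score
    lengths = np.array([r.length for r in regions], dtype=float)
    return sums / lengths


def read_bedpe(path: str | Path) -> list[LoopCall]:
    """BEDPE loops: chrom1,start1,end1,chrom2,start2,end2[,name,score,resolution]."""
    loops: list[LoopCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: BEDPE needs >= 6 columns")
            try:
                a1 = GenomicInterval(f[0], int(f[1]), int(f[2]))
                a2 = GenomicInterval(f[3], int(f[4]), int(f[5]))
                score = float(f[7]) if len(f) > 7 and f[7] != "." else 0.0
                resolution = int(f[8]) if len(f) > 8 else 0
                if a1.start > a2.start:
                    a1, a2 = a2, a1
                loops.append(LoopCall(a1, a2, resolution, score))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return loops


def write_bedpe(loops: Iterable[LoopCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, lp in enumerate(loops):
            fh.write(
                "\t".join(
                    [
                        lp.anchor1.chrom,
                        str(lp.anchor1.start),
                        str(lp.anchor1.end),
                        lp.anchor2.chrom,
                        str(lp.anchor2.start),
                        str(lp.anchor2.end),
                        f"loop_{i}",
                        f"{lp.score:g}",
                        str(lp.resolution),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# contact matrices (COO TSV)
# ---------------------------------------------------------------------------


def read_contact_matrices(path: str | Path) -> dict[str, ContactMatrix]:
    """Read COO TSV contact matrices (chrom, bin_i, bin_j, count).

    A ``# resolution=<bp>`` header line declares the bin size.  Rows with
    j < i are accepted and mirrored; a duplicate (i, j) record is an error
    (ambiguous); negative counts are an error.
    """
    resolution = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "resolution=" in first:
        resolution = int(first.split("resolution=")[1].split()[0])
    if resolution is None:
        raise ValueError(f"{path}: missing '# resolution=' header")
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["chrom", "bin_i", "bin_j", "count"],
        header=0,
        dtype={"chrom": str, "bin_i": int, "bin_j": int, "count": float},
    )
    if (df["count"] < 0).any():
        bad = df.index[df["count"] < 0][0]
        raise ValueError(f"{path}: negative count at record {bad}")
    lo = np.minimum(df["bin_i"], df["bin_j"])
    hi = np.maximum(df["bin_i"], df["bin_j"])
    df = df.assign(bin_i=lo, bin_j=hi)
    if df.duplicated(subset=["chrom", "bin_i", "bin_j"]).any():
        dup = df[df.duplicated(subset=["chrom", "bin_i", "bin_j"])].iloc[0]
        raise ValueError(
            f"{path}: duplicate record for ({dup.chrom}, {dup.bin_i}, {dup.bin_j})"
        )
    out: dict[str, ContactMatrix] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        n = int(max(sub["bin_i"].max(), sub["bin_j"].max())) + 1
        m = np.zeros((n, n))
        m[sub["bin_i"], sub["bin_j"]] = sub["count"]
        m[sub["bin_j"], sub["bin_i"]] = sub["count"]
        out[str(chrom)] = ContactMatrix(str(chrom), resolution, m)
    return out


def write_contact_matrices(matrices: Mapping[str, ContactMatrix], path: str | Path) -> None:
    resolutions = {m.resolution for m in matrices.values()}
    if len(resolutions) != 1:
        raise ValueError("all matrices in one file must share a resolution")
    frames = []
    for chrom in sorted(matrices):
        m = matrices[chrom].counts
        iu, ju = np.triu_indices(m.shape[0])
        vals = m[iu, ju]
        keep = vals != 0
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "bin_i": iu[keep], "bin_j": ju[keep], "count": vals[keep]}
            )
        )
    body = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"# resolution={resolutions.pop()}\n")
        body.to_csv(fh, sep="\t", index=False, float_format="%g")


# ---------------------------------------------------------------------------
# FASTA / PWM (MEME minimal)
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_meme(path: str | Path, pseudocount: float = 1e-3) -> list[Pwm]:
    """Parse MEME minimal motif files into :class:`Pwm` objects.

    Probabilities are re-normalized after adding ``pseudocount`` so that
    log-odds scores are always finite.
    """
    background = np.full(4, 0.25)
    pwms: list[Pwm] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            freq_fields = lines[i + 1].split()
            background = np.array([float(freq_fields[k]) for k in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                i += 1
            header = lines[i].strip()
            width = int(header.split("w=")[1].split()[0])
            rows = []
            for k in range(1, width + 1):
                rows.append([float(x) for x in lines[i + k].split()])
            mat = np.array(rows) + pseudocount
            mat /= mat.sum(axis=1, keepdims=True)
            pwms.append(Pwm(name, mat, background / background.sum()))
            i += width + 1
            continue
        i += 1
    return pwms


def write_meme(pwms: Sequence[Pwm], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.tf_name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(p)} nsites= 20 E= 0\n")
            for row in p.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# gene tables / expression TSV / misc
# ---------------------------------------------------------------------------


def read_gene_table(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    """Gene annotation TSV: gene_id, chrom, start, end, strand, tss.

    ``one_based=True`` converts GTF-style 1-based inclusive coordinates to
    the internal 0-based half-open convention on read.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "start", "end", "strand", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if one_based:
        df = df.assign(start=df["start"] - 1, tss=df["tss"] - 1)
    return df


def tss_intervals(genes: pd.DataFrame, flank: int = 2000) -> list[GenomicInterval]:
    """Promoter intervals (TSS +- flank) carrying gene_id in ``name``."""
    out = []
    for row in genes.itertuples():
        start = max(0, int(row.tss) - flank)
        out.append(GenomicInterval(row.chrom, start, int(row.tss) + flank, row.gene_id))
    return out


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Expression TSV: rows = genes, columns = 'STAGE_rep' sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def bin_density(
    positions: Sequence[int], chrom_length: int, bin_size: int
) -> np.ndarray:
    """Per-bin count of point features (e.g. TSS) along a chromosome."""
    n = int(np.ceil(chrom_length / bin_size))
    counts = np.zeros(n)
    for p in positions:
        if 0 <= p < chrom_length:
            counts[p // bin_size] += 1
    return counts


def write_json(obj: object, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o: object):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
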