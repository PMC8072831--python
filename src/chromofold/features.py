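"""Binary epigenomic feature tracks and CTCF constraints.

RNA-seq and H3K27me3 ChIP-seq signals enter the reconstruction as
binary one-dimensional arrays at the Hi-C resolution: one flag per bin
for "overlaps an expressed gene" and one for "binned methylation signal
exceeds the threshold" (default 300).  CTCF ChIA-PET loop calls enter
as a binary symmetric matrix of coupled bin pairs; multiplied by a
scalar and added to the Hi-C matrix it acts as an extra proximity
constraint on the loop anchors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import Block, BlockTree
from .io import ContactMatrix

__all__ = [
    "FeatureAnnotation",
    "BlockFlags",
    "binarize_chip",
    "binarize_rna",
    "build_ctcf_matrix",
    "augment_with_ctcf",
    "annotate_blocks",
    "read_bed_intervals",
    "read_bedgraph",
    "read_bedpe_pairs",
]


@dataclass
class FeatureAnnotation:
    """Per-bin binary feature flags plus the CTCF pair matrix.

    The derived per-bin score is +1 for bins that are only expressed,
    -1 for bins that are only repressed, and 0 otherwise (neither, or
    both marks present and cancelling).
    """

    expressed: np.ndarray
    repressed: np.ndarray
    ctcf: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.expressed = np.asarray(self.expressed, dtype=int)
        self.repressed = np.asarray(self.repressed, dtype=int)
        n = self.expressed.shape[0]
        if self.repressed.shape != (n,):
            raise ValueError("expressed/repressed length mismatch")
        for arr, name in ((self.expressed, "expressed"), (self.repressed, "repressed")):
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} array must be binary")
        if self.ctcf is None:
            self.ctcf = np.zeros((n, n), dtype=int)
        else:
            self.ctcf = np.asarray(self.ctcf, dtype=int)
            if self.ctcf.shape != (n, n):
                raise ValueError("ctcf matrix shape mismatch")
            if not np.isin(self.ctcf, (0, 1)).all():
                raise ValueError("ctcf matrix must be binary")
            if np.any(self.ctcf != self.ctcf.T):
                raise ValueError("ctcf matrix must be symmetric")
            if np.any(np.diag(self.ctcf) != 0):
                raise ValueError("ctcf matrix must have zero diagonal")

    @property
    def n_bins(self) -> int:
        return self.expressed.shape[0]

    @property
    def score(self) -> np.ndarray:
        """Per-bin score in {-1, 0, +1}: expressed minus repressed."""
        return self.expressed - self.repressed

    def bead_features(self, start: int = 0, end: int | None = None) -> list[str]:
        """Per-bead feature labels for a bin span."""
        end = self.n_bins if end is None else end
        out = []
        for i in range(start, end):
            e, r = self.expressed[i], self.repressed[i]
            out.append("both" if e and r else "active" if e else "repressed" if r else "none")
        return out

    @classmethod
    def empty(cls, n_bins: int) -> "FeatureAnnotation":
        return cls(np.zeros(n_bins, dtype=int), np.zeros(n_bins, dtype=int))


@dataclass(frozen=True)
class BlockFlags:
    """Feature presence of one block: drives which score terms are active."""

    expressed: bool = False
    repressed: bool = False
    ctcf: bool = False


def binarize_chip(
    signal: np.ndarray,
    fine_res_bp: int,
    target_res_bp: int,
    threshold: float = 300.0,
) -> np.ndarray:
    """Aggregate a fine-resolution ChIP signal into target bins and threshold.

    Fine values are summed within each target bin; the output flag is 1
    iff the aggregate strictly exceeds the threshold.  An incomplete
    trailing bin aggregates whatever fine bins it covers.
    """
    signal = np.asarray(signal, dtype=float)
    if np.any(signal < 0):
        raise ValueError("ChIP signal must be nonnegative")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if target_res_bp <= 0 or fine_res_bp <= 0 or target_res_bp % fine_res_bp != 0:
        raise ValueError("target resolution must be a positive multiple of the fine one")
    ratio = target_res_bp // fine_res_bp
    n_out = int(np.ceil(signal.size / ratio))
    padded = np.zeros(n_out * ratio)
    padded[: signal.size] = signal
    agg = padded.reshape(n_out, ratio).sum(axis=1)
    return (agg > threshold).astype(int)


def binarize_rna(
    expressed_intervals: list[tuple[int, int]],
    n_bins: int,
    resolution_bp: int,
    start_bin: int = 0,
) -> np.ndarray:
    """Flag bins overlapping any expressed-gene interval by >= 1 bp.

    Intervals are genomic bp [start, end); bins are 0-based half-open.
    Intervals sticking out of the matrix span are clipped (warning).
    """
    out = np.zeros(n_bins, dtype=int)
    span_start = start_bin * resolution_bp
    span_end = (start_bin + n_bins) * resolution_bp
    for a, b in expressed_intervals:
        if a >= b:
            raise ValueError(f"interval start must precede end: ({a}, {b})")
        if a < span_start or b > span_end:
            warnings.warn(f"interval ({a}, {b}) clipped to matrix span")
        a, b = max(a, span_start), min(b, span_end)
        if a >= b:
            continue
        first = (a - span_start) // resolution_bp
        last = (b - 1 - span_start) // resolution_bp  # inclusive; b is exclusive
        out[first : last + 1] = 1
    return out


def build_ctcf_matrix(loop_pairs: list[tuple[int, int]], n_bins: int) -> np.ndarray:
    """Binary symmetric matrix of CTCF-coupled bin pairs, zero diagonal.

    Pairs whose two anchors fall in the same bin carry no geometric
    constraint and are dropped with a warning.
    """
    m = np.zeros((n_bins, n_bins), dtype=int)
    for i, j in loop_pairs:
        if not (0 <= i < n_bins and 0 <= j < n_bins):
            raise ValueError(f"loop anchor ({i}, {j}) outside [0, {n_bins})")
        if i == j:
            warnings.warn(f"dropping self-contact CTCF pair at bin {i}")
            continue
        m[i, j] = m[j, i] = 1
    return m


def augment_with_ctcf(
    hic: ContactMatrix, ctcf: np.ndarray, scalar: float
) -> ContactMatrix:
    """Add scalar * ctcf to the Hi-C matrix, hardening loop-anchor proximity."""
    ctcf = np.asarray(ctcf)
    if ctcf.shape != hic.values.shape:
        raise ValueError("ctcf matrix shape does not match Hi-C matrix")
    if scalar <= 0:
        raise ValueError("scalar must be positive")
    return ContactMatrix(
        values=hic.values + scalar * ctcf,
        resolution_bp=hic.resolution_bp,
        start_bin=hic.start_bin,
        chrom=hic.chrom,
    )


def default_ctcf_scalar(block_values: np.ndarray) -> float:
    """90th percentile of the nonzero contact entries of a block.

    Puts a CTCF-coupled pair among the strongest observed contacts of
    its block without dwarfing them.  Falls back to 1 for empty blocks.
    """
    v = np.asarray(block_values, dtype=float)
    iu, ju = np.triu_indices(v.shape[0], k=1)
    nz = v[iu, ju][v[iu, ju] > 0]
    return float(np.percentile(nz, 90)) if nz.size else 1.0


def annotate_blocks(
    annotation: FeatureAnnotation,
    blocks: list[Block] | BlockTree,
    rule: str = "any",
    fraction: float = 0.5,
) -> list[BlockFlags]:
    """Lift per-bin flags to per-block flags.

    With the default "any" rule a block is flagged expressed/repressed
    as soon as one of its bins carries the flag; the "fraction" rule
    requires the given fraction of bins instead.  A block is flagged
    ctcf only if a CTCF pair falls entirely inside it — pairs spanning
    two blocks surface at the coarser level where both anchors share a
    block.
    """
    if isinstance(blocks, BlockTree):
        blocks = blocks.levels[0]
    out = []
    for blk in blocks:
        if blk.end_bin > annotation.n_bins:
            raise ValueError("block span exceeds annotation length")
        sl = slice(blk.start_bin, blk.end_bin)
        if rule == "any":
            expressed = bool(annotation.expressed[sl].any())
            repressed = bool(annotation.repressed[sl].any())
        elif rule == "fraction":
            expressed = bool(annotation.expressed[sl].mean() >= fraction)
            repressed = bool(annotation.repressed[sl].mean() >= fraction)
        else:
            raise ValueError(f"unknown rule {rule!r}")
        ctcf = bool(np.triu(annotation.ctcf[sl, sl], k=1).any())
        out.append(BlockFlags(expressed=expressed, repressed=repressed, ctcf=ctcf))
    return out


def coarsen_annotation(
    annotation: FeatureAnnotation, blocks: list[Block]
) -> FeatureAnnotation:
    """Feature annotation at the next resolution level (one bin per block).

    Bin flags propagate by "any"; the CTCF matrix is binned pairwise, so
    an inter-block loop becomes an intra-level contact between the two
    coarse bins (the level at which it finally constrains geometry).
    """
    k = len(blocks)
    expressed = np.zeros(k, dtype=int)
    repressed = np.zeros(k, dtype=int)
    ctcf = np.zeros((k, k), dtype=int)
    for a, ba in enumerate(blocks):
        sa = slice(ba.start_bin, ba.end_bin)
        expressed[a] = int(annotation.expressed[sa].any())
        repressed[a] = int(annotation.repressed[sa].any())
        for b in range(a + 1, k):
            bb = blocks[b]
            sb = slice(bb.start_bin, bb.end_bin)
            if annotation.ctcf[sa, sb].any():
                ctcf[a, b] = ctcf[b, a] = 1
    return FeatureAnnotation(expressed=expressed, repressed=repressed, ctcf=ctcf)


# ---------------------------------------------------------------------------
# Track readers (BED / bedGraph / BEDPE)
# ---------------------------------------------------------------------------


def read_bed_intervals(path, chrom: str | None = None) -> list[tuple[int, int]]:
    """(start, end) bp intervals from a BED file, optionally one chromosome."""
    df = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
    )
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    return list(zip(df["start"].astype(int), df["end"].astype(int)))


def read_bedgraph(path, chrom: str | None = None) -> pd.DataFrame:
    """bedGraph rows (chrom, start, end, value), optionally one chromosome."""
    df = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
    )
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    return df.reset_index(drop=True)


def bedgraph_to_signal(
    df: pd.DataFrame, fine_res_bp: int, span_start_bp: int, n_fine_bins: int
) -> np.ndarray:
    """Rasterize bedGraph rows onto a uniform fine-resolution grid."""
    signal = np.zeros(n_fine_bins)
    span_end = span_start_bp + n_fine_bins * fine_res_bp
    for _, row in df.iterrows():
        a = max(int(row["start"]), span_start_bp)
        b = min(int(row["end"]), span_end)
        if a >= b:
            continue
        first = (a - span_start_bp) // fine_res_bp
        last = (b - 1 - span_start_bp) // fine_res_bp
        signal[first : last + 1] += float(row["value"])
    return signal


def read_bedpe_pairs(
    path,
    resolution_bp: int,
    start_bin: int = 0,
    n_bins: int | None = None,
    chrom: str | None = None,
) -> list[tuple[int, int]]:
    """Loop-anchor bin pairs from a BEDPE file (anchor midpoints -> bins)."""
    df = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None, usecols=[0, 1, 2, 3, 4, 5],
        names=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
    )
    if chrom is not None:
        df = df[(df["chrom1"] == chrom) & (df["chrom2"] == chrom)]
    pairs = []
    for _, row in df.iterrows():
        mid1 = (int(row["start1"]) + int(row["end1"])) // 2
        mid2 = (int(row["start2"]) + int(row["end2"])) // 2
        i = mid1 // resolution_bp - start_bin
        j = mid2 // resolution_bp - start_bin
        if n_bins is not None and not (0 <= i < n_bins and 0 <= j < n_bins):
            warnings.warn(f"dropping loop outside matrix span: bins ({i}, {j})")
            continue
        pairs.append((min(i, j), max(i, j)))
    return pairs
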