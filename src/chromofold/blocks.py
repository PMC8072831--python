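"""Diagonal-block (TAD-like) decomposition of a contact matrix.

A Hi-C matrix of a chromosome is close to block-diagonal: TADs interact
internally much more than with their surroundings.  Boundaries between
blocks are located with a moving average over sliding triangles whose
apex slides along the main diagonal — a boundary shows up as a local
minimum of the triangle mean, because the triangle there straddles two
blocks and averages mostly inter-block entries.  Binning each block into
a single bin yields the matrix of the next, coarser resolution level;
repeating until no internal boundary remains builds the block tree that
drives the multilevel reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ContactMatrix

__all__ = [
    "Block",
    "BlockTree",
    "triangle_score",
    "detect_blocks",
    "bin_matrix",
    "build_block_tree",
]


@dataclass(frozen=True)
class Block:
    """Half-open bin span [start_bin, end_bin) at one resolution level."""

    start_bin: int
    end_bin: int
    level: int = 0
    total_contacts: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start_bin < self.end_bin):
            raise ValueError(f"invalid block span [{self.start_bin}, {self.end_bin})")

    @property
    def size(self) -> int:
        return self.end_bin - self.start_bin


@dataclass
class BlockTree:
    """Nested block partitions across resolution levels.

    ``levels[k]`` partitions ``matrices[k]``; each level-k block becomes
    one bin (one bead) of ``matrices[k+1]``.  The last matrix is the one
    on which no further boundary was found.
    """

    levels: list[list[Block]] = field(default_factory=list)
    matrices: list[ContactMatrix] = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def blocks_as_bed(self, level: int = 0) -> list[tuple[str, int, int, int]]:
        """(chrom, start_bp, end_bp, level) rows for the given level."""
        mat = self.matrices[level]
        res = mat.resolution_bp
        off = mat.start_bin
        return [
            (mat.chrom, (off + b.start_bin) * res, (off + b.end_bin) * res, level)
            for b in self.levels[level]
        ]


def triangle_score(matrix: ContactMatrix | np.ndarray, window: int) -> np.ndarray:
    """Mean contact frequency in a sliding triangle at each boundary.

    Position ``p`` scores the triangle of half-width ``window`` whose
    apex sits on the diagonal between bins p and p+1: entries (i, j)
    with ``p - window < i <= p < j <= p + window``.  Near the matrix
    edges the triangle is truncated.  Low scores mark weak coupling
    across a candidate boundary.
    """
    m = matrix.values if isinstance(matrix, ContactMatrix) else np.asarray(matrix, float)
    n = m.shape[0]
    if not (2 <= window <= n // 2):
        raise ValueError(f"window must be in [2, {n // 2}], got {window}")
    scores = np.empty(n - 1)
    for p in range(n - 1):
        i0 = max(0, p - window + 1)
        j1 = min(n, p + window + 1)
        tri = m[i0 : p + 1, p + 1 : j1]
        scores[p] = tri.mean() if tri.size else 0.0
    return scores


def _local_minima(scores: np.ndarray) -> list[int]:
    """Strict local minima; on plateaus the leftmost position wins."""
    mins = []
    n = len(scores)
    for p in range(n):
        left = scores[p - 1] if p > 0 else np.inf
        right = scores[p + 1] if p < n - 1 else np.inf
        if scores[p] < left and scores[p] <= right:
            # leftmost-of-plateau: require a strict rise somewhere right
            q = p
            while q < n - 1 and scores[q + 1] == scores[p]:
                q += 1
            if q == n - 1 or scores[q + 1] > scores[p]:
                mins.append(p)
    return mins


def detect_blocks(
    matrix: ContactMatrix | np.ndarray,
    window: int = 5,
    min_size: int = 4,
    max_size: int = 40,
    boundary_threshold: float = 0.5,
) -> list[Block]:
    """Partition the matrix into diagonal blocks.

    Boundaries are strict local minima of :func:`triangle_score` that
    fall below ``boundary_threshold`` times the mean score (a relative
    cut that rejects shallow noise dips inside a block).  Boundaries
    closer than ``min_size`` to each other or to the matrix edges are
    merged, keeping the lower-scoring one; blocks longer than
    ``max_size`` are split at their internal minimum.  The returned
    blocks tile [0, n).
    """
    m = matrix.values if isinstance(matrix, ContactMatrix) else np.asarray(matrix, float)
    n = m.shape[0]
    if min_size < 2 or max_size < min_size:
        raise ValueError("need min_size >= 2 and max_size >= min_size")
    if n < 2 * min_size:
        return [_make_block(m, 0, n)]
    window = min(window, n // 2)

    scores = triangle_score(m, window)
    mean_score = scores.mean()
    cut = boundary_threshold * mean_score
    cand = [p for p in _local_minima(scores) if scores[p] <= cut]
    # boundary after bin p splits at p+1
    bounds = sorted(p + 1 for p in cand)

    # merge boundaries violating min_size, dropping the higher-scoring one;
    # the matrix edges act as immovable boundaries
    def bound_score(b: int) -> float:
        return scores[b - 1]

    changed = True
    while changed and bounds:
        changed = False
        pts = [0] + bounds + [n]
        for a, b in zip(pts[:-1], pts[1:]):
            if b - a < min_size:
                # drop the higher-scoring of the two offending boundaries
                removable = [x for x in (a, b) if x in bounds]
                victim = max(removable, key=bound_score)
                bounds.remove(victim)
                changed = True
                break

    # split blocks exceeding max_size at their deepest internal minimum
    def split_long(a: int, b: int) -> list[int]:
        if b - a <= max_size:
            return []
        lo, hi = a + min_size, b - min_size
        if lo >= hi:
            return []
        inner = range(lo, hi)
        best = min(inner, key=lambda x: scores[x - 1])
        return [best] + split_long(a, best) + split_long(best, b)

    extra: list[int] = []
    pts = [0] + bounds + [n]
    for a, b in zip(pts[:-1], pts[1:]):
        extra.extend(split_long(a, b))
    bounds = sorted(set(bounds) | set(extra))

    pts = [0] + bounds + [n]
    return [_make_block(m, a, b) for a, b in zip(pts[:-1], pts[1:])]


def _make_block(m: np.ndarray, a: int, b: int, level: int = 0) -> Block:
    sub = m[a:b, a:b]
    total = float(np.triu(sub, k=1).sum())
    return Block(start_bin=a, end_bin=b, level=level, total_contacts=total)


def bin_matrix(matrix: ContactMatrix, blocks: list[Block]) -> ContactMatrix:
    """Collapse each block into a single bin of the coarser matrix.

    Off-diagonal coarse entry (a, b) is the total contact mass between
    blocks a and b; the coarse diagonal holds each block's internal mass
    (upper triangle plus diagonal), so total mass in the upper-triangle-
    plus-diagonal sense is conserved across levels.
    """
    m = matrix.values
    n = m.shape[0]
    spans = [(b.start_bin, b.end_bin) for b in blocks]
    if spans[0][0] != 0 or spans[-1][1] != n:
        raise ValueError("blocks do not tile the matrix")
    for (a0, a1), (b0, b1) in zip(spans[:-1], spans[1:]):
        if a1 != b0:
            raise ValueError("blocks do not tile the matrix")
    k = len(blocks)
    coarse = np.zeros((k, k))
    for a in range(k):
        a0, a1 = spans[a]
        sub = m[a0:a1, a0:a1]
        coarse[a, a] = np.triu(sub).sum()
        for b in range(a + 1, k):
            b0, b1 = spans[b]
            mass = m[a0:a1, b0:b1].sum()
            coarse[a, b] = coarse[b, a] = mass
    return ContactMatrix(
        values=coarse,
        resolution_bp=int(round(matrix.resolution_bp * n / k)),
        start_bin=matrix.start_bin,
        chrom=matrix.chrom,
    )


def build_block_tree(matrix: ContactMatrix, config=None) -> BlockTree:
    """Recursive block detection and binning across resolution levels.

    Detect blocks, bin them into a coarser matrix, and repeat on that
    matrix until a single block remains (or the matrix becomes too small
    to split).  The final matrix — the coarsest description of the
    chromosome — is kept as the tree's top.
    """
    from .io import MethodParams  # late import to avoid cycle at module load

    method = config.method if config is not None else MethodParams()
    tree = BlockTree()
    current = matrix
    level = 0
    while True:
        blocks = detect_blocks(
            current,
            window=method.window,
            min_size=method.min_size,
            max_size=method.max_size,
            boundary_threshold=method.boundary_threshold,
        )
        blocks = [Block(b.start_bin, b.end_bin, level, b.total_contacts) for b in blocks]
        if len(blocks) == 1:
            tree.matrices.append(current)
            break
        tree.levels.append(blocks)
        tree.matrices.append(current)
        current = bin_matrix(current, blocks)
        level += 1
    return tree
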