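"""Synthetic ground-truth generators for testing and demonstrations.

Everything the pipeline consumes — block-diagonal contact matrices with
planted TAD boundaries, reference bead chains with known geometry, and
binary feature tracks — can be generated here deterministically, so the
whole package is exercised without any external download.  The planted
matrices emulate the block-diagonal look of real Hi-C data (many
intra-block, few inter-block contacts, integer Poisson counts); the
reference chains provide known 3-D geometry whose synthetic contact
matrix serves as pipeline input for self-consistency checks.
"""

from __future__ import annotations

import numpy as np

from .chain import BeadChain
from .features import FeatureAnnotation
from .io import ContactMatrix

__all__ = [
    "make_planted_matrix",
    "make_reference_chain",
    "make_tracks",
    "write_bed",
    "write_bedgraph",
    "write_bedpe",
]


def make_planted_matrix(
    block_sizes: list[int],
    intra_density: float = 10.0,
    inter_density: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    resolution_bp: int = 5000,
) -> tuple[ContactMatrix, list[int]]:
    """Block-diagonal contact matrix with planted boundaries.

    Intra-block entries draw from Poisson(intra_density), inter-block
    from Poisson(inter_density), plus optional truncated-normal noise.
    Returns the matrix and the planted boundary positions (cumulative
    block ends, excluding 0 and n).
    """
    if intra_density < 0 or inter_density < 0 or noise_sd < 0:
        raise ValueError("densities and noise must be nonnegative")
    rng = np.random.default_rng(seed)
    n = int(sum(block_sizes))
    lam = np.full((n, n), float(inter_density))
    bounds = np.cumsum(block_sizes)
    start = 0
    for end in bounds:
        lam[start:end, start:end] = intra_density
        start = end
    upper = rng.poisson(lam).astype(float)
    if noise_sd > 0:
        upper += np.clip(rng.normal(scale=noise_sd, size=(n, n)), 0, None)
    values = np.triu(upper)
    values = values + np.triu(values, k=1).T
    return (
        ContactMatrix(values=values, resolution_bp=resolution_bp),
        [int(b) for b in bounds[:-1]],
    )


def make_reference_chain(
    n_beads: int,
    style: str = "helix",
    seed: int = 0,
    radius: float = 5.0,
    resolution_bp: int = 5000,
) -> BeadChain:
    """Deterministic reference chain with consecutive beads touching.

    "helix" winds a regular helix (all consecutive spacings equal);
    "random_walk" takes seeded random directions; "hairpin" folds the
    chain back on itself so that beads near the two ends form a
    long-range near-contact pair, convenient for CTCF loop tests.
    """
    if n_beads < 2:
        raise ValueError("need at least 2 beads")
    radii = np.full(n_beads, float(radius))
    spacing = 2.0 * radius
    pos = np.zeros((n_beads, 3))
    if style == "helix":
        # choose helix geometry so consecutive arc chord equals spacing
        turn = 2.0 * np.pi / 10.0
        r_h = spacing / (2.0 * np.sin(turn / 2.0)) * 0.9
        chord = 2.0 * r_h * np.sin(turn / 2.0)
        pitch = np.sqrt(max(spacing**2 - chord**2, 1e-12))
        for i in range(n_beads):
            pos[i] = [r_h * np.cos(i * turn), r_h * np.sin(i * turn), i * pitch]
    elif style == "random_walk":
        rng = np.random.default_rng(seed)
        for i in range(1, n_beads):
            v = rng.normal(size=3)
            pos[i] = pos[i - 1] + spacing * v / np.linalg.norm(v)
    elif style == "hairpin":
        half = n_beads // 2
        gap = 1.2 * spacing  # lateral distance between the two arms
        for i in range(n_beads):
            if i < half:
                pos[i] = [0.0, 0.0, i * spacing]
            else:
                k = i - half
                pos[i] = [gap, 0.0, (half - 1 - k) * spacing]
    else:
        raise ValueError(f"unknown chain style {style!r}")
    return BeadChain.from_arrays(pos, radii, resolution_bp=resolution_bp)


def make_tracks(
    n_bins: int,
    expressed_spans: list[tuple[int, int]] | None = None,
    repressed_spans: list[tuple[int, int]] | None = None,
    ctcf_pairs: list[tuple[int, int]] | None = None,
) -> FeatureAnnotation:
    """Feature annotation from bin-index spans (half-open) and loop pairs."""
    expressed = np.zeros(n_bins, dtype=int)
    repressed = np.zeros(n_bins, dtype=int)
    for a, b in expressed_spans or []:
        if not (0 <= a < b <= n_bins):
            raise ValueError(f"span ({a}, {b}) outside [0, {n_bins})")
        expressed[a:b] = 1
    for a, b in repressed_spans or []:
        if not (0 <= a < b <= n_bins):
            raise ValueError(f"span ({a}, {b}) outside [0, {n_bins})")
        repressed[a:b] = 1
    ctcf = np.zeros((n_bins, n_bins), dtype=int)
    for i, j in ctcf_pairs or []:
        if i == j:
            continue
        ctcf[i, j] = ctcf[j, i] = 1
    return FeatureAnnotation(expressed=expressed, repressed=repressed, ctcf=ctcf)


def write_bed(intervals_bp: list[tuple[int, int]], path, chrom: str = "chr") -> None:
    with open(path, "w") as fh:
        for a, b in intervals_bp:
            fh.write(f"{chrom}\t{a}\t{b}\n")


def write_bedgraph(
    values: np.ndarray, fine_res_bp: int, path, chrom: str = "chr", start_bp: int = 0
) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            a = start_bp + i * fine_res_bp
            fh.write(f"{chrom}\t{a}\t{a + fine_res_bp}\t{v:g}\n")


def write_bedpe(
    pairs_bins: list[tuple[int, int]], resolution_bp: int, path, chrom: str = "chr"
) -> None:
    with open(path, "w") as fh:
        for i, j in pairs_bins:
            a, b = i * resolution_bp, j * resolution_bp
            fh.write(
                f"{chrom}\t{a}\t{a + resolution_bp}\t"
                f"{chrom}\t{b}\t{b + resolution_bp}\n"
            )
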