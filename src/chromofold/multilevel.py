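"""Coarse-to-fine orchestration of the whole reconstruction.

Each diagonal block of the contact matrix is reconstructed independently
as a sub-chain ensemble; every block then collapses into a single bead
of the next, coarser chain whose size is derived from the block's 3-D
structures.  Once the coarsest chain is estimated, the full chromosome
is reassembled top-down by substituting every bead with its sub-chain,
rigidly placed so that its centroid sits at the bead's center and its
end-to-end axis follows the local direction of the coarse chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import Block, BlockTree, build_block_tree
from .chain import BeadChain, GeometryParams, assign_radii, modulate_diameter
from .features import (
    BlockFlags,
    FeatureAnnotation,
    annotate_blocks,
    coarsen_annotation,
    default_ctcf_scalar,
)
from .io import ContactMatrix, RunConfig
from .sampler import AnnealSchedule, derive_seed, initialize_chain, sample_ensemble
from .score import PairSets, ScoreParams, select_pairs

__all__ = ["LevelResult", "coarsen", "reassemble", "run_pipeline"]


@dataclass
class LevelResult:
    """Per-block ensembles at one level plus the derived coarse inputs."""

    level: int
    blocks: list[Block]
    block_chains: dict[int, list[BeadChain]]
    coarse_matrix: ContactMatrix | None = None
    coarse_radii: np.ndarray | None = None


def coarse_bead_radius(chains: list[BeadChain], rule: str = "extent") -> float:
    """Size of the bead replacing a block at the next level.

    "extent": half the maximum pairwise centroid distance plus the mean
    member bead radius, averaged over the ensemble — the sphere loosely
    wrapping the sub-chain.  "gyration" uses the radius of gyration plus
    the mean bead radius instead.
    """
    if not chains:
        raise ValueError("empty ensemble for a block")
    vals = []
    for ch in chains:
        pos = ch.positions
        mean_r = float(np.mean(ch.radii))
        if rule == "extent":
            d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
            vals.append(0.5 * float(d.max()) + mean_r)
        elif rule == "gyration":
            vals.append(ch.radius_of_gyration() + mean_r)
        else:
            raise ValueError(f"unknown coarse radius rule {rule!r}")
    return float(np.mean(vals))


def coarsen(
    block_chains: dict[int, list[BeadChain]],
    fine_matrix: ContactMatrix,
    blocks: list[Block],
    rule: str = "extent",
) -> tuple[ContactMatrix, np.ndarray]:
    """Coarse matrix and coarse bead radii from per-block ensembles."""
    from .blocks import bin_matrix

    coarse = bin_matrix(fine_matrix, blocks)
    radii = np.array(
        [coarse_bead_radius(block_chains[b], rule=rule) for b in range(len(blocks))]
    )
    return coarse, radii


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # 180 degrees about any axis orthogonal to u
        helper = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, helper)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    kmat = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + kmat + kmat @ kmat * ((1 - c) / s**2)


def reassemble(coarse_chain: BeadChain, block_chains: dict[int, list | BeadChain]) -> BeadChain:
    """Substitute every coarse bead with its sub-chain, rigidly placed.

    The sub-chain is translated so its centroid coincides with the
    coarse bead center and rotated so its end-to-end vector follows the
    local coarse-chain direction (previous-to-next bead; endpoints use
    their single neighbor).  Internal sub-chain geometry is untouched.
    """
    n = len(coarse_chain)
    pos = coarse_chain.positions
    beads = []
    for k in range(n):
        sub = block_chains.get(k)
        if sub is None:
            raise ValueError(f"missing sub-chain for coarse bead {k}")
        if isinstance(sub, list):
            sub = sub[0]
        if k == 0:
            tangent = pos[1] - pos[0]
        elif k == n - 1:
            tangent = pos[-1] - pos[-2]
        else:
            tangent = pos[k + 1] - pos[k - 1]
        sub_pos = sub.positions
        centroid = sub_pos.mean(axis=0)
        ete = sub_pos[-1] - sub_pos[0]
        if np.linalg.norm(ete) > 1e-12 and np.linalg.norm(tangent) > 1e-12:
            rot = _rotation_between(ete, tangent)
        else:
            rot = np.eye(3)
        placed = (sub_pos - centroid) @ rot.T + pos[k]
        for p, b in zip(placed, sub.beads):
            beads.append(
                type(b)(center=p, radius=b.radius, bin_index=b.bin_index, feature=b.feature)
            )
    beads.sort(key=lambda b: b.bin_index)
    return BeadChain(
        beads=beads,
        resolution_bp=block_chains[0][0].resolution_bp
        if isinstance(block_chains[0], list)
        else block_chains[0].resolution_bp,
        level=coarse_chain.level - 1 if coarse_chain.level > 0 else 0,
    )


def _flags_to_sets(
    block_values: np.ndarray, flags: BlockFlags, score_params: ScoreParams
) -> PairSets:
    L = select_pairs(block_values, score_params.contact_percentile)
    return PairSets(L=L, chip_active=flags.repressed, rna_active=flags.expressed)


def _estimate_block(
    block_values: np.ndarray,
    flags: BlockFlags,
    radii: np.ndarray,
    features: list[str],
    bin_indices: np.ndarray,
    config: RunConfig,
    geometry: GeometryParams,
    seed: int,
    n_runs: int,
    resolution_bp: int,
    level: int,
) -> list[BeadChain]:
    sets = _flags_to_sets(block_values, flags, config.score)
    schedule = AnnealSchedule(
        t_initial=config.algorithm.t_initial,
        cooling=config.algorithm.cooling,
        iters_per_temp=config.algorithm.iters_per_temp,
        n_temps=config.algorithm.n_temps,
        seed=seed,
        max_angle=config.algorithm.max_angle,
        jitter_fraction=config.algorithm.jitter_fraction,
    )
    template = initialize_chain(
        len(radii), radii, seed=derive_seed(seed, 3),
        resolution_bp=resolution_bp, level=level,
        features=features, bin_indices=bin_indices,
    )
    return sample_ensemble(
        template, block_values, sets, config.score, geometry, schedule, n_runs
    )


def run_pipeline(
    matrix: ContactMatrix,
    annotation: FeatureAnnotation | None = None,
    config: RunConfig | None = None,
) -> tuple[list[BeadChain], BlockTree]:
    """Full multilevel reconstruction of a contact matrix.

    Returns ``config.algorithm.ensemble_size`` full-resolution chains
    (one bead per input bin each) and the block tree used.  Fully
    deterministic for a fixed ``config.algorithm.seed``.
    """
    config = config or RunConfig()
    annotation = annotation or FeatureAnnotation.empty(matrix.n_bins)
    if annotation.n_bins != matrix.n_bins:
        raise ValueError("annotation length does not match matrix dimension")
    n_runs = config.algorithm.ensemble_size
    master_seed = config.algorithm.seed
    tree = build_block_tree(matrix, config)

    # feature annotations per level
    annotations = [annotation]
    for blocks in tree.levels:
        annotations.append(coarsen_annotation(annotations[-1], blocks))

    level_results: list[LevelResult] = []
    radii_prev: np.ndarray | None = None  # radii of the current level's bins
    for level, blocks in enumerate(tree.levels):
        mat = tree.matrices[level]
        ann = annotations[level]
        flags = annotate_blocks(
            ann, blocks,
            rule=config.method.block_feature_rule,
            fraction=config.method.block_feature_fraction,
        )
        ris_kb = mat.resolution_bp / 1000.0
        geometry = config.geometry.at_resolution(ris_kb)
        block_chains: dict[int, list[BeadChain]] = {}
        for bi, blk in enumerate(blocks):
            sub = mat.submatrix(blk.start_bin, blk.end_bin)
            # intra-block CTCF constraints harden the data term
            ctcf_sub = ann.ctcf[blk.start_bin : blk.end_bin, blk.start_bin : blk.end_bin]
            if ctcf_sub.any():
                scalar = config.method.ctcf_scalar or default_ctcf_scalar(sub)
                sub = sub + scalar * ctcf_sub
            if radii_prev is not None:
                radii = radii_prev[blk.start_bin : blk.end_bin].copy()
            else:
                base = geometry.nominal_diameter()
                radii = assign_radii(sub, base)
                feats = ann.bead_features(blk.start_bin, blk.end_bin)
                radii = np.array(
                    [modulate_diameter(r, f) for r, f in zip(radii, feats)]
                )
            feats = ann.bead_features(blk.start_bin, blk.end_bin)
            block_chains[bi] = _estimate_block(
                sub, flags[bi], radii, feats,
                np.arange(blk.start_bin, blk.end_bin),
                config, geometry,
                seed=derive_seed(master_seed, 1_000 * level + bi),
                n_runs=n_runs,
                resolution_bp=mat.resolution_bp,
                level=level,
            )
        coarse_mat, coarse_radii = coarsen(block_chains, mat, blocks)
        level_results.append(
            LevelResult(level, blocks, block_chains, coarse_mat, coarse_radii)
        )
        radii_prev = coarse_radii

    # top level: the coarsest matrix estimated as a single chain
    top_mat = tree.matrices[-1]
    top_ann = annotations[-1]
    ris_kb = top_mat.resolution_bp / 1000.0
    geometry = config.geometry.at_resolution(ris_kb)
    top_values = top_mat.values.copy()
    if top_ann.ctcf.any():
        scalar = config.method.ctcf_scalar or default_ctcf_scalar(top_values)
        top_values = top_values + scalar * np.asarray(top_ann.ctcf)
    if radii_prev is None:
        base = geometry.nominal_diameter()
        radii = assign_radii(top_values, base)
        feats = top_ann.bead_features()
        radii = np.array([modulate_diameter(r, f) for r, f in zip(radii, feats)])
    else:
        radii = radii_prev
    top_flags = BlockFlags(
        expressed=bool(top_ann.expressed.any()),
        repressed=bool(top_ann.repressed.any()),
    )
    top_ensemble = _estimate_block(
        top_values, top_flags, radii, top_ann.bead_features(),
        np.arange(top_mat.n_bins), config, geometry,
        seed=derive_seed(master_seed, 999_983),
        n_runs=n_runs,
        resolution_bp=top_mat.resolution_bp,
        level=len(tree.levels),
    )

    # top-down reassembly, one full structure per ensemble index
    full = []
    for m in range(n_runs):
        chain = top_ensemble[m]
        for lr in reversed(level_results):
            subs = {bi: lr.block_chains[bi][m] for bi in lr.block_chains}
            chain = reassemble(chain, subs)
        full.append(chain)
    return full, tree
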