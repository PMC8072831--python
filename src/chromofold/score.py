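"""Bayesian score function for a candidate sub-chain configuration.

The total score of a configuration ``C`` is

    Xi(C) = Phi_HiC(C) + mu1 * Phi_ChIP(C) + mu2 * Phi_RNA(C) + lambda * Psi(C)

interpreted as a negative log-posterior: lower is better.

* ``Phi_HiC`` is the data-fit term: contact-rich bead pairs are pulled
  toward touching distance, weighted by their contact frequency.
* ``Phi_ChIP`` compacts sub-chains carrying the repressive H3K27me3
  mark by penalising a maximum inter-bead distance above ``d_min``.
* ``Phi_RNA`` expands sub-chains carrying expressed genes by penalising
  a minimum non-consecutive inter-bead distance below ``d_max``.
* ``Psi`` is a soft excluded-volume barrier keeping beads from
  interpenetrating beyond a tolerated fraction of their sizes while
  still allowing partial overlap of consecutive beads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import BeadChain, GeometryParams, d_max, d_min

__all__ = [
    "ScoreParams",
    "PairSets",
    "select_pairs",
    "phi_hic",
    "phi_chip",
    "phi_rna",
    "psi",
    "xi",
]


@dataclass(frozen=True)
class ScoreParams:
    """Weights and shape constants of the score function.

    mu1, mu2, lam
        Weights of the ChIP compaction, RNA expansion and
        excluded-volume terms relative to the Hi-C data fit.
    c
        Scale (1/nm) making the barrier argument dimensionless; ``None``
        defaults to the reciprocal of the mean bead diameter of the
        chain being scored.
    b
        Odd natural exponent tuning the sharpness of the barrier
        transition between overlap and separation.
    contact_percentile
        Percentile of the nonzero contact frequencies of a block above
        which a pair enters the data-fit set L.
    """

    mu1: float = 1.0
    mu2: float = 1.0
    lam: float = 1.0
    c: float | None = None
    b: int = 3
    contact_percentile: float = 75.0

    def __post_init__(self) -> None:
        if self.mu1 < 0 or self.mu2 < 0 or self.lam < 0:
            raise ValueError("term weights must be nonnegative")
        if self.c is not None and self.c <= 0:
            raise ValueError("c must be positive")
        if self.b < 1 or self.b % 2 == 0:
            raise ValueError(f"b must be an odd natural number, got {self.b}")
        if not (0 <= self.contact_percentile < 100):
            raise ValueError("contact_percentile must be in [0, 100)")


@dataclass
class PairSets:
    """Index-pair subsets driving the individual score terms.

    ``L`` holds the high-frequency contact pairs of the block;
    ``chip_active`` / ``rna_active`` record whether the block carries
    the repressive mark / expressed genes, in which case the respective
    term runs over all non-adjacent (resp. non-consecutive) pairs.
    """

    L: np.ndarray  # (m, 2) int array, i < j
    chip_active: bool = False
    rna_active: bool = False

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=int).reshape(-1, 2)


def select_pairs(contacts: np.ndarray, percentile: float) -> np.ndarray:
    """High-contact pair subset L of a block.

    Returns the (i, j) pairs (i < j) whose contact frequency reaches the
    given percentile of the *nonzero* upper-triangle frequencies.
    Linear-interpolation percentile; pairs at or above the cut are kept,
    so a block whose nonzero entries are all equal still yields a
    nonempty L.  An all-zero block yields the empty set.
    """
    m = np.asarray(contacts, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("contact matrix must be square")
    if not (0 <= percentile < 100):
        raise ValueError("percentile must be in [0, 100)")
    iu, ju = np.triu_indices(m.shape[0], k=1)
    vals = m[iu, ju]
    nz = vals[vals > 0]
    if nz.size == 0:
        return np.empty((0, 2), dtype=int)
    cut = np.percentile(nz, percentile)
    keep = vals >= cut
    return np.column_stack([iu[keep], ju[keep]])


def _pair_distances(positions: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = positions.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    d = np.linalg.norm(positions[iu] - positions[ju], axis=1)
    return iu, ju, d


def phi_hic(chain: BeadChain, contacts: np.ndarray, L: np.ndarray) -> float:
    """Hi-C data-fit term: sum over L of n_ij * [d_ij - (r_i + r_j)]^2.

    At ``d_ij = 0`` the term takes the finite value ``n_ij (r_i+r_j)^2``
    (its maximum for an interpenetrating pair); keeping beads apart is
    the barrier term's job, not this one's.
    """
    L = np.asarray(L, dtype=int).reshape(-1, 2)
    if L.size == 0:
        return 0.0
    m = np.asarray(contacts, dtype=float)
    pos = chain.positions
    r = chain.radii
    d = np.linalg.norm(pos[L[:, 0]] - pos[L[:, 1]], axis=1)
    rr = r[L[:, 0]] + r[L[:, 1]]
    w = m[L[:, 0], L[:, 1]]
    return float(np.sum(w * (d - rr) ** 2))


def phi_chip(chain: BeadChain, chip_active: bool, dmin: float) -> float:
    """Compaction term for blocks carrying H3K27me3.

    ``[max d_ij - d_min]^2`` over all non-adjacent pairs (the two main
    diagonals of the block are excluded); zero for unmarked blocks.  The
    penalty vanishes when the sub-chain's diameter shrinks to ``d_min``.
    """
    if dmin <= 0:
        raise ValueError("d_min must be positive")
    if not chip_active:
        return 0.0
    iu, ju, d = _pair_distances(chain.positions)
    nonadj = (ju - iu) > 1
    if not np.any(nonadj):
        return 0.0
    return float((np.max(d[nonadj]) - dmin) ** 2)


def phi_rna(chain: BeadChain, rna_active: bool, dmax: float) -> float:
    """Expansion term for blocks carrying expressed genes.

    ``[min d_ij - d_max]^2`` over non-consecutive pairs; zero for blocks
    without expressed genes.  The penalty is small once every
    non-consecutive pair is at least ``d_max`` apart, i.e. the fiber's
    curvature is low.
    """
    if dmax <= 0:
        raise ValueError("d_max must be positive")
    if not rna_active:
        return 0.0
    iu, ju, d = _pair_distances(chain.positions)
    nonadj = (ju - iu) > 1
    if not np.any(nonadj):
        return 0.0
    return float((np.min(d[nonadj]) - dmax) ** 2)


def psi(chain: BeadChain, params: ScoreParams) -> float:
    """Soft excluded-volume barrier summed over all bead pairs.

    For each pair, with ``x = c * (d_ij - (r_i+r_j))`` the signed,
    dimensionless separation,

        psi_ij = (r_i+r_j)/(2 d_ij) * [1 - x^b / (1 + |x|^b)]

    The odd exponent makes the bracket approach 2 for deep overlap and 0
    for wide separation: the term behaves as ``(r_i+r_j)/d_ij`` as beads
    approach coincidence, equals ``(r_i+r_j)/(2 d_ij)`` at contact
    distance, and decays rapidly to zero beyond it.  ``b`` tunes how
    abrupt the transitions are.
    """
    pos = chain.positions
    r = chain.radii
    return _psi_arrays(pos, r, _resolve_c(params, r), params.b)


def _resolve_c(params: ScoreParams, radii: np.ndarray) -> float:
    if params.c is not None:
        return params.c
    return 1.0 / (2.0 * float(np.mean(radii)))


def _psi_arrays(positions: np.ndarray, radii: np.ndarray, c: float, b: int) -> float:
    iu, ju, d = _pair_distances(positions)
    if np.any(d <= 0):
        raise ValueError("coincident bead centers: barrier is singular at d=0")
    rr = radii[iu] + radii[ju]
    x = c * (d - rr)
    bracket = 1.0 - x**b / (1.0 + np.abs(x) ** b)
    return float(np.sum(rr / (2.0 * d) * bracket))


def xi(
    chain: BeadChain,
    contacts: np.ndarray,
    sets: PairSets,
    params: ScoreParams,
    geometry: GeometryParams,
) -> float:
    """Total score: Phi_HiC + mu1*Phi_ChIP + mu2*Phi_RNA + lam*Psi."""
    total = phi_hic(chain, contacts, sets.L)
    if params.mu1:
        total += params.mu1 * phi_chip(chain, sets.chip_active, d_min(geometry))
    if params.mu2:
        total += params.mu2 * phi_rna(chain, sets.rna_active, d_max(geometry))
    if params.lam:
        total += params.lam * psi(chain, params)
    return float(total)


# ---------------------------------------------------------------------------
# Fast path used by the annealer: everything static about a block is
# precomputed once so that a move costs one vectorized pass.
# ---------------------------------------------------------------------------


@dataclass
class ScoreContext:
    """Precomputed static data for repeated Xi evaluations on one block."""

    iu: np.ndarray
    ju: np.ndarray
    w_hic: np.ndarray          # contact weights aligned with (iu, ju); 0 off L
    nonadj: np.ndarray         # mask of non-adjacent pairs
    chip_active: bool
    rna_active: bool
    dmin: float
    dmax: float
    mu1: float
    mu2: float
    lam: float
    c: float
    b: int
    radii: np.ndarray
    rr: np.ndarray             # r_i + r_j aligned with (iu, ju)

    @classmethod
    def build(
        cls,
        radii: np.ndarray,
        contacts: np.ndarray,
        sets: PairSets,
        params: ScoreParams,
        geometry: GeometryParams,
    ) -> "ScoreContext":
        radii = np.asarray(radii, dtype=float)
        n = radii.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        wmat = np.zeros((n, n))
        if sets.L.size:
            m = np.asarray(contacts, dtype=float)
            wmat[sets.L[:, 0], sets.L[:, 1]] = m[sets.L[:, 0], sets.L[:, 1]]
        w = wmat[iu, ju]
        return cls(
            iu=iu,
            ju=ju,
            w_hic=w,
            nonadj=(ju - iu) > 1,
            chip_active=sets.chip_active,
            rna_active=sets.rna_active,
            dmin=d_min(geometry),
            dmax=d_max(geometry),
            mu1=params.mu1,
            mu2=params.mu2,
            lam=params.lam,
            c=_resolve_c(params, radii),
            b=params.b,
            radii=radii,
            rr=radii[iu] + radii[ju],
        )

    def evaluate(self, positions: np.ndarray) -> float:
        """Xi at the given centers; +inf for near-coincident centers.

        Pairs closer than 1e-6 nm sit past the barrier's singularity;
        the annealer treats the infinite score as an outright rejection.
        """
        d = np.linalg.norm(positions[self.iu] - positions[self.ju], axis=1)
        if d.size and d.min() <= 1e-6:
            return float("inf")
        gap = d - self.rr
        total = float(np.sum(self.w_hic * gap**2))
        if self.chip_active and self.mu1 and np.any(self.nonadj):
            total += self.mu1 * (np.max(d[self.nonadj]) - self.dmin) ** 2
        if self.rna_active and self.mu2 and np.any(self.nonadj):
            total += self.mu2 * (np.min(d[self.nonadj]) - self.dmax) ** 2
        if self.lam:
            x = self.c * gap
            bracket = 1.0 - x**self.b / (1.0 + np.abs(x) ** self.b)
            total += self.lam * float(np.sum(self.rr / (2.0 * d) * bracket))
        return total
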