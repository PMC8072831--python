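"""Approximated simulated annealing over bead-chain configurations.

The solution space of the score function is explored with a Metropolis
sampler under a geometric cooling schedule.  The large-scale move is a
pivot rotation: all beads on one side of a randomly chosen pivot are
rotated rigidly about the pivot's center by a random rotation expressed
in quaternion algebra (numerically stable, no gimbal artefacts); a small
per-bead translation jitter provides local refinement.  The goal is not
a single global optimum but a family of low-score configurations, so
independent seeded runs build an ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain import BeadChain, GeometryParams, initialize_chain
from .score import PairSets, ScoreContext, ScoreParams

__all__ = [
    "AnnealSchedule",
    "Move",
    "propose_move",
    "apply_move",
    "accept",
    "anneal_subchain",
    "sample_ensemble",
    "derive_seed",
]



@dataclass(frozen=True)
class AnnealSchedule:
    """Cooling schedule of the annealer.

    ``t_initial=None`` sets the starting temperature to the standard
    deviation of the score over 100 random initial configurations, so
    early stages accept essentially any move.
    """

    t_initial: float | None = None
    cooling: float = 0.85
    iters_per_temp: int = 200
    n_temps: int = 50
    seed: int = 0
    max_angle: float = np.pi
    jitter_fraction: float = 0.1  # jitter sigma as a fraction of mean radius

    def __post_init__(self) -> None:
        if self.t_initial is not None and self.t_initial <= 0:
            raise ValueError("t_initial must be positive")
        if not (0 < self.cooling < 1):
            raise ValueError("cooling must be in (0, 1)")
        if self.iters_per_temp < 0 or self.n_temps < 0:
            raise ValueError("iteration counts must be nonnegative")


@dataclass
class Move:
    """A pivot rotation plus a translation jitter of the pivot bead."""

    pivot_index: int
    segment: str  # "downstream" | "upstream"
    rotation: np.ndarray  # unit quaternion (w, x, y, z)
    translation_jitter: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation_jitter = np.asarray(self.translation_jitter, dtype=float)
        if self.rotation.shape != (4,):
            raise ValueError("quaternion must have 4 components")
        if abs(np.linalg.norm(self.rotation) - 1.0) > 1e-12:
            raise ValueError("quaternion must be unit norm")
        if self.segment not in ("downstream", "upstream"):
            raise ValueError(f"unknown segment {self.segment!r}")


def quat_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    """Unit quaternion (w, x, y, z) for a rotation about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        if angle != 0:
            raise ValueError("zero axis with nonzero angle")
        return np.array([1.0, 0.0, 0.0, 0.0])
    axis = axis / norm
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def quat_rotate(q: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Rotate row-vectors by the unit quaternion ``q = (w, x, y, z)``."""
    w, qv = q[0], q[1:]
    points = np.asarray(points, dtype=float)
    t = 2.0 * np.cross(qv, points)
    return points + w * t + np.cross(qv, t)


def propose_move(
    chain: BeadChain,
    rng: np.random.Generator,
    max_angle: float,
    jitter_sigma: float = 0.0,
) -> Move:
    """Draw a random pivot move.

    The pivot bead is uniform over the interior beads (endpoints cannot
    anchor a rotation), the rotation axis uniform on the unit sphere,
    the angle uniform in (0, max_angle]; the jitter, when enabled, is an
    isotropic Gaussian displacement of the pivot bead itself.
    """
    n = len(chain)
    if n < 3:
        raise ValueError("pivot moves need at least 3 beads")
    pivot = int(rng.integers(1, n - 1))
    segment = "downstream" if rng.random() < 0.5 else "upstream"
    if max_angle == 0:
        q = np.array([1.0, 0.0, 0.0, 0.0])
    else:
        axis = rng.normal(size=3)
        angle = max_angle * (1.0 - rng.random())  # uniform in (0, max_angle]
        q = quat_from_axis_angle(axis, angle)
    jitter = rng.normal(scale=jitter_sigma, size=3) if jitter_sigma > 0 else np.zeros(3)
    return Move(pivot_index=pivot, segment=segment, rotation=q, translation_jitter=jitter)


def _apply_move_arrays(positions: np.ndarray, move: Move) -> np.ndarray:
    new = positions.copy()
    center = positions[move.pivot_index]
    if move.segment == "downstream":
        sl = slice(move.pivot_index + 1, None)
    else:
        sl = slice(0, move.pivot_index)
    new[sl] = center + quat_rotate(move.rotation, positions[sl] - center)
    new[move.pivot_index] = center + move.translation_jitter
    return new


def apply_move(chain: BeadChain, move: Move) -> BeadChain:
    """Rigidly rotate one side of the pivot about the pivot's center.

    Beads strictly beyond the pivot on the chosen side rotate as a rigid
    body; the jitter displaces the pivot bead only; all other beads are
    untouched.  Pairwise distances within the rotated segment and within
    the fixed segment are preserved exactly.
    """
    return chain.with_positions(_apply_move_arrays(chain.positions, move))


def accept(delta_xi: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: downhill always, uphill with exp(-delta/T)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_xi <= 0:
        return True
    return bool(rng.random() < np.exp(-delta_xi / temperature))


def derive_seed(master_seed: int, index: int) -> int:
    """Splitmix64-style stream seed, folded below 2**31."""
    z = (master_seed + (index + 1) * 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    z = z ^ (z >> 31)
    return int(z % (2**31 - 1))


def _auto_t_initial(
    chain: BeadChain,
    ctx: ScoreContext,
    seed: int,
    n_samples: int = 100,
) -> float:
    scores = []
    for k in range(n_samples):
        trial = initialize_chain(
            len(chain), chain.radii, seed=derive_seed(seed, 1000 + k),
            resolution_bp=chain.resolution_bp, level=chain.level,
        )
        s = ctx.evaluate(trial.positions)
        if np.isfinite(s):
            scores.append(s)
    sd = float(np.std(scores)) if scores else 0.0
    return sd if sd > 0 else 1.0


def anneal_subchain(
    chain: BeadChain,
    contacts: np.ndarray,
    sets: PairSets,
    score_params: ScoreParams,
    geometry: GeometryParams,
    schedule: AnnealSchedule,
) -> tuple[BeadChain, list[tuple[int, float, float]]]:
    """Metropolis annealing of one sub-chain under the full score.

    Runs ``n_temps`` stages of ``iters_per_temp`` steps each, cooling
    geometrically between stages.  Returns the final configuration and a
    trace of ``(stage, temperature, best score found so far)``.  Fully
    reproducible for a fixed schedule seed.
    """
    ctx = ScoreContext.build(chain.radii, contacts, sets, score_params, geometry)
    pos = chain.positions
    n = len(chain)
    rng = np.random.default_rng(schedule.seed)
    temp = schedule.t_initial or _auto_t_initial(chain, ctx, schedule.seed)
    jitter_sigma = schedule.jitter_fraction * float(np.mean(chain.radii))
    current = ctx.evaluate(pos)
    best = current
    trace: list[tuple[int, float, float]] = []
    for stage in range(schedule.n_temps):
        for _ in range(schedule.iters_per_temp):
            if n >= 3 and rng.random() < 0.7:
                move = propose_move(chain, rng, schedule.max_angle)
                cand = _apply_move_arrays(pos, move)
            else:
                # local refinement: jitter a single random bead
                idx = int(rng.integers(0, n))
                cand = pos.copy()
                cand[idx] += rng.normal(scale=jitter_sigma, size=3)
            # reject any proposal with near-coincident centers
            new_score = ctx.evaluate(cand)
            if not np.isfinite(new_score):
                continue
            if accept(new_score - current, temp, rng):
                pos, current = cand, new_score
            best = min(best, current)
        trace.append((stage, temp, best))
        temp *= schedule.cooling
    return chain.with_positions(pos), trace


def sample_ensemble(
    chain: BeadChain,
    contacts: np.ndarray,
    sets: PairSets,
    score_params: ScoreParams,
    geometry: GeometryParams,
    schedule: AnnealSchedule,
    n_runs: int,
    reinitialize: bool = True,
) -> list[BeadChain]:
    """Independent annealing runs building a family of solutions.

    Each run gets a seed derived from the master seed; by default each
    run also starts from its own random initial configuration so the
    ensemble spreads over the solution space rather than around one
    basin.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    out = []
    for k in range(n_runs):
        run_seed = derive_seed(schedule.seed, k)
        start = chain
        if reinitialize:
            start = initialize_chain(
                len(chain), chain.radii, seed=derive_seed(run_seed, 7),
                resolution_bp=chain.resolution_bp, level=chain.level,
                features=chain.features,
                bin_indices=[b.bin_index for b in chain.beads],
            )
        run_sched = AnnealSchedule(
            t_initial=schedule.t_initial,
            cooling=schedule.cooling,
            iters_per_temp=schedule.iters_per_temp,
            n_temps=schedule.n_temps,
            seed=run_seed,
            max_angle=schedule.max_angle,
            jitter_fraction=schedule.jitter_fraction,
        )
        final, _ = anneal_subchain(start, contacts, sets, score_params, geometry, run_sched)
        out.append(final)
    return out


def write_trace(trace: list[tuple[int, float, float]], path) -> None:
    """Dump a score trace as TSV (stage, temperature, best score)."""
    with open(path, "w") as fh:
        fh.write("stage\ttemperature\tbest_score\n")
        for stage, temp, best in trace:
            fh.write(f"{stage}\t{temp:.6g}\t{best:.6g}\n")
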