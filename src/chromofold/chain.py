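"""Bead-chain representation of the chromatin fiber and its geometry.

Chromatin is modelled as an ordered chain of partially penetrable
spherical beads, one bead per genomic bin at the working resolution.
Bead sizes are set in inverse proportion to their contact counts, bounded
by resolution-dependent limits ``d_min``/``d_max`` derived from the
diameter of the chromatin fiber, and modulated by the transcriptional
state of the underlying bin (active chromatin is expanded, repressed
chromatin compacted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Bead",
    "BeadChain",
    "GeometryParams",
    "d_min",
    "d_max",
    "assign_radii",
    "modulate_diameter",
    "initialize_chain",
]

#: Allowed per-bead feature states.
FEATURES = ("active", "repressed", "both", "none")


@dataclass(frozen=True)
class GeometryParams:
    """Geometric constants of the bead-chain model.

    Parameters
    ----------
    d_c:
        Diameter of the chromatin fiber in nm (default 30).
    ris_kb:
        Working genomic resolution in kilobases (default 5).
    base_diameter:
        Nominal bead diameter at this resolution, nm.  ``None`` means
        the midpoint of [d_min, d_max] at the current resolution.
    active_factor, repressed_factor:
        Multiplicative diameter modulation for beads in expressed
        (open, expanded) and repressed (compact) chromatin.
    size_exponent:
        Exponent of the resolution scaling of bead-size bounds.  The
        default 5/6 reflects a near-linear mass-to-size packing of the
        fiber into a bead.
    """

    d_c: float = 30.0
    ris_kb: float = 5.0
    base_diameter: float | None = None
    active_factor: float = 1.1
    repressed_factor: float = 0.9
    size_exponent: float = 5.0 / 6.0

    def __post_init__(self) -> None:
        if self.d_c <= 0:
            raise ValueError(f"d_c must be positive, got {self.d_c}")
        if self.ris_kb <= 0:
            raise ValueError(f"ris_kb must be positive, got {self.ris_kb}")
        if not (self.active_factor > 1.0 > self.repressed_factor > 0.0):
            raise ValueError(
                "need active_factor > 1 > repressed_factor > 0, got "
                f"{self.active_factor}, {self.repressed_factor}"
            )
        if self.base_diameter is not None and self.base_diameter <= 0:
            raise ValueError("base_diameter must be positive")

    def nominal_diameter(self) -> float:
        """Bead diameter used when none is configured explicitly."""
        if self.base_diameter is not None:
            return self.base_diameter
        return 0.5 * (d_min(self) + d_max(self))

    def at_resolution(self, ris_kb: float) -> "GeometryParams":
        """Same constants re-targeted to a different resolution."""
        return replace(self, ris_kb=ris_kb, base_diameter=self.base_diameter)


def d_min(params: GeometryParams) -> float:
    """Minimum admissible bead diameter (nm) at the working resolution.

    ``d_min = d_c * RIS^(5/6) / (6 pi)`` with RIS in kb: the tightest
    packing of a fiber of diameter ``d_c`` carrying RIS kilobases.
    """
    return params.d_c * params.ris_kb**params.size_exponent / (6.0 * math.pi)


def d_max(params: GeometryParams) -> float:
    """Maximum admissible bead diameter (nm); exactly ``2 * d_min``.

    ``d_max = d_c * RIS^(5/6) / (3 pi)`` — the loosest admissible
    packing of the same fiber length.
    """
    return params.d_c * params.ris_kb**params.size_exponent / (3.0 * math.pi)


@dataclass
class Bead:
    """A spherical bead: one genomic bin embedded in 3-D space (nm)."""

    center: np.ndarray
    radius: float
    bin_index: int
    feature: str = "none"

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ValueError(f"center must be a 3-vector, got {self.center.shape}")
        if not np.all(np.isfinite(self.center)):
            raise ValueError("bead center must be finite")
        if not (self.radius > 0):
            raise ValueError(f"bead radius must be positive, got {self.radius}")
        if self.feature not in FEATURES:
            raise ValueError(f"unknown feature {self.feature!r}")


@dataclass
class BeadChain:
    """Ordered chain of beads at one resolution level."""

    beads: list[Bead]
    resolution_bp: int = 5000
    level: int = 0

    def __post_init__(self) -> None:
        if len(self.beads) < 2:
            raise ValueError("a chain needs at least 2 beads")
        idx = [b.bin_index for b in self.beads]
        if any(b >= a for a, b in zip(idx[1:], idx[:-1])):
            raise ValueError("bin_index must be strictly increasing along the chain")

    def __len__(self) -> int:
        return len(self.beads)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of bead centers in nm."""
        return np.array([b.center for b in self.beads], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([b.radius for b in self.beads], dtype=float)

    @property
    def features(self) -> list[str]:
        return [b.feature for b in self.beads]

    def with_positions(self, positions: np.ndarray) -> "BeadChain":
        """Copy of the chain with new centers (radii/metadata unchanged)."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.beads), 3):
            raise ValueError("positions shape mismatch")
        beads = [
            Bead(center=p.copy(), radius=b.radius, bin_index=b.bin_index, feature=b.feature)
            for p, b in zip(positions, self.beads)
        ]
        return BeadChain(beads=beads, resolution_bp=self.resolution_bp, level=self.level)

    def radius_of_gyration(self) -> float:
        pos = self.positions
        return float(np.sqrt(np.mean(np.sum((pos - pos.mean(axis=0)) ** 2, axis=1))))

    @classmethod
    def from_arrays(
        cls,
        positions: np.ndarray,
        radii: np.ndarray,
        bin_indices: np.ndarray | None = None,
        features: list[str] | None = None,
        resolution_bp: int = 5000,
        level: int = 0,
    ) -> "BeadChain":
        positions = np.asarray(positions, dtype=float)
        radii = np.asarray(radii, dtype=float)
        n = len(radii)
        if bin_indices is None:
            bin_indices = np.arange(n)
        if features is None:
            features = ["none"] * n
        beads = [
            Bead(center=positions[i], radius=float(radii[i]),
                 bin_index=int(bin_indices[i]), feature=features[i])
            for i in range(n)
        ]
        return cls(beads=beads, resolution_bp=resolution_bp, level=level)


def assign_radii(block_matrix: np.ndarray, base_diameter: float) -> np.ndarray:
    """Per-bead radii inversely proportional to contact counts.

    Raw bead size is ``1 / (k_i + 1)`` where ``k_i`` is the total number
    of contacts bead *i* makes within its block (the +1 keeps
    contact-free beads finite); sizes are then rescaled so the mean
    diameter equals ``base_diameter``.  Contact-rich beads thus come out
    small (dense fiber), contact-poor beads large (open fiber).
    """
    m = np.asarray(block_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("block matrix must be square")
    if m.shape[0] < 2:
        raise ValueError("a block needs at least 2 beads")
    if base_diameter <= 0:
        raise ValueError("base_diameter must be positive")
    k = m.sum(axis=1) - np.diag(m)  # off-diagonal contact totals
    raw = 1.0 / (k + 1.0)
    diameters = raw * (base_diameter / raw.mean())
    return diameters / 2.0


def modulate_diameter(radius: float, feature: str) -> float:
    """Scale a bead radius by the transcriptional state of its bin.

    Active chromatin (lower volume concentration) is expanded by 10%,
    repressed chromatin (higher concentration) compacted by 10%; bins
    carrying both marks, or neither, are left unchanged.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if feature not in FEATURES:
        raise ValueError(f"unknown feature {feature!r}")
    if feature == "active":
        return 1.1 * radius
    if feature == "repressed":
        return 0.9 * radius
    return radius


def initialize_chain(
    n_beads: int,
    radii: np.ndarray,
    seed: int,
    resolution_bp: int = 5000,
    level: int = 0,
    features: list[str] | None = None,
    bin_indices: np.ndarray | None = None,
) -> BeadChain:
    """Random initial configuration with consecutive beads touching.

    Beads are laid down sequentially along random directions with
    consecutive spacing ``r_i + r_{i+1}``; directions that would land a
    bead on top of an earlier one are re-drawn (best effort, bounded
    retries), giving a loosely self-avoiding starting curve.
    Deterministic for a fixed seed.
    """
    if n_beads < 2:
        raise ValueError("need at least 2 beads")
    radii = np.asarray(radii, dtype=float)
    if radii.shape != (n_beads,):
        raise ValueError("radii length must equal n_beads")
    rng = np.random.default_rng(seed)
    pos = np.zeros((n_beads, 3))
    for i in range(1, n_beads):
        spacing = radii[i - 1] + radii[i]
        cand = pos[i - 1]
        for _ in range(64):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            cand = pos[i - 1] + spacing * v
            if i == 1:
                break
            # keep clearance from all beads before the immediate predecessor
            clearance = np.linalg.norm(pos[: i - 1] - cand, axis=1)
            if np.all(clearance > 0.5 * (radii[: i - 1] + radii[i])):
                break
        pos[i] = cand
    return BeadChain.from_arrays(
        pos, radii, bin_indices=bin_indices, features=features,
        resolution_bp=resolution_bp, level=level,
    )
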