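"""Readers and writers for contact matrices, structures and run configs.

Contact matrices come in as dense whitespace/tab-delimited text (no
header, ``#`` comments allowed), as NumPy ``.npy`` arrays, or from a
minimal single-resolution HDF5 container laid out like a cooler file
(``bins/…``, ``pixels/…``).  Reconstructed structures go out as XYZ,
minimal PDB-like text (one pseudo-atom per bead) or JSON; the JSON
dialect round-trips coordinates, radii, resolution and feature flags.
Genomic coordinates are 0-based half-open bins; all structure
coordinates are nanometres.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

from .chain import Bead, BeadChain, GeometryParams
from .score import ScoreParams

__all__ = [
    "ContactMatrix",
    "MethodParams",
    "AlgorithmParams",
    "RunConfig",
    "read_contact_matrix",
    "write_contact_matrix",
    "write_structure",
    "read_structure",
    "load_config",
    "save_config",
]

_SYMMETRY_RTOL = 1e-8


@dataclass
class ContactMatrix:
    """Symmetric nonnegative contact-frequency matrix with bin metadata."""

    values: np.ndarray
    resolution_bp: int = 5000
    start_bin: int = 0
    chrom: str = "chr"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"contact matrix must be square, got {v.shape}")
        if v.shape[0] < 2:
            raise ValueError("contact matrix needs at least 2 bins")
        if np.any(np.isnan(v)):
            raise ValueError("contact matrix contains NaN")
        if np.any(v < 0):
            raise ValueError("contact matrix contains negative entries")
        if not np.allclose(v, v.T, rtol=_SYMMETRY_RTOL, atol=0):
            raise ValueError("contact matrix is not symmetric")
        # average away floating-point asymmetry within tolerance
        self.values = 0.5 * (v + v.T)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def submatrix(self, start: int, end: int) -> np.ndarray:
        return self.values[start:end, start:end]

    def bin_span_bp(self, i: int) -> tuple[int, int]:
        """Genomic [start, end) of bin i, in bp."""
        a = (self.start_bin + i) * self.resolution_bp
        return a, a + self.resolution_bp


@dataclass(frozen=True)
class MethodParams:
    """Block detection and pair-selection settings (METHOD group)."""

    window: int = 5
    min_size: int = 4
    max_size: int = 40
    boundary_threshold: float = 0.5
    block_feature_rule: str = "any"   # "any" | "fraction"
    block_feature_fraction: float = 0.5
    ctcf_scalar: float | None = None  # None: 90th pct of nonzero entries

    def __post_init__(self) -> None:
        if self.block_feature_rule not in ("any", "fraction"):
            raise ValueError("block_feature_rule must be 'any' or 'fraction'")


@dataclass(frozen=True)
class AlgorithmParams:
    """Simulated-annealing settings (ALGORITHM group)."""

    t_initial: float | None = None
    cooling: float = 0.85
    iters_per_temp: int = 200
    n_temps: int = 50
    seed: int = 0
    ensemble_size: int = 10
    max_angle: float = float(np.pi)
    jitter_fraction: float = 0.1
    contact_alpha: float = 1.2  # synthetic-contact threshold multiplier


@dataclass
class RunConfig:
    """Full parameter set of a reconstruction run.

    Groups mirror how practitioners think about the method: geometric
    constants of the fiber, the score weights, the block-detection
    method settings, and the annealing algorithm settings.  Every field
    has a documented default, so an empty config is a valid run.
    """

    geometry: GeometryParams = field(default_factory=GeometryParams)
    score: ScoreParams = field(default_factory=ScoreParams)
    method: MethodParams = field(default_factory=MethodParams)
    algorithm: AlgorithmParams = field(default_factory=AlgorithmParams)
    chip_threshold: float = 300.0  # binarization cut on binned ChIP signal


def read_contact_matrix(
    path: str | Path,
    resolution_bp: int = 5000,
    format_hint: str = "tsv",
    chrom: str = "chr",
    start_bin: int = 0,
) -> ContactMatrix:
    """Load a dense contact matrix from TSV, .npy or cooler-like HDF5.

    Asymmetries up to 1e-8 relative are averaged away; anything larger
    is an error, as are negative or NaN entries and non-square input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_hint == "tsv":
        values = np.loadtxt(path, comments="#", ndmin=2)
    elif format_hint == "npy":
        values = np.load(path)
    elif format_hint == "cool":
        values = _read_cooler_like(path)
    else:
        raise ValueError(f"unknown format_hint {format_hint!r}")
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"contact matrix must be square, got shape {values.shape}")
    return ContactMatrix(
        values=values, resolution_bp=resolution_bp, start_bin=start_bin, chrom=chrom
    )


def _read_cooler_like(path: Path) -> np.ndarray:
    """Densify a minimal single-resolution cooler-style HDF5 container."""
    import h5py

    with h5py.File(path, "r") as fh:
        n = fh["bins/start"].shape[0]
        b1 = fh["pixels/bin1_id"][:]
        b2 = fh["pixels/bin2_id"][:]
        count = fh["pixels/count"][:]
    dense = np.zeros((n, n))
    dense[b1, b2] = count
    dense[b2, b1] = count
    return dense


def write_contact_matrix(matrix: ContactMatrix, path: str | Path) -> None:
    """Write the dense matrix as TSV with a provenance comment line."""
    header = (
        f"# chrom={matrix.chrom} resolution_bp={matrix.resolution_bp} "
        f"start_bin={matrix.start_bin}"
    )
    np.savetxt(path, matrix.values, fmt="%.10g", delimiter="\t", header=header, comments="")


def write_structure(chain: BeadChain, path: str | Path, format: str = "json") -> None:
    """Write one record per bead, in chain order, with center (nm) and radius."""
    pos = chain.positions
    if not np.all(np.isfinite(pos)):
        raise ValueError("chain contains non-finite coordinates")
    path = Path(path)
    if format == "xyz":
        lines = [str(len(chain)), f"bead chain level={chain.level}"]
        for b in chain.beads:
            x, y, z = b.center
            lines.append(f"C {x:.9f} {y:.9f} {z:.9f} {b.radius:.9f}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "pdb":
        lines = []
        for k, b in enumerate(chain.beads, start=1):
            x, y, z = b.center  # columns carry nm, not Angstrom
            lines.append(
                f"HETATM{k:5d}  C   BED A{k:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b.radius:6.2f}           C"
            )
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        doc = {
            "resolution_bp": chain.resolution_bp,
            "level": chain.level,
            "beads": [
                {
                    "bin_index": b.bin_index,
                    "center_nm": [float(c) for c in b.center],
                    "radius_nm": float(b.radius),
                    "feature": b.feature,
                }
                for b in chain.beads
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
    else:
        raise ValueError(f"unknown structure format {format!r}")


def read_structure(path: str | Path, format: str = "json") -> BeadChain:
    """Read back a structure written by :func:`write_structure`."""
    path = Path(path)
    if format == "json":
        doc = json.loads(path.read_text())
        beads = [
            Bead(
                center=np.array(b["center_nm"], dtype=float),
                radius=b["radius_nm"],
                bin_index=b["bin_index"],
                feature=b.get("feature", "none"),
            )
            for b in doc["beads"]
        ]
        return BeadChain(beads=beads, resolution_bp=doc["resolution_bp"], level=doc["level"])
    if format == "xyz":
        lines = path.read_text().strip().splitlines()
        n = int(lines[0])
        beads = []
        for k, line in enumerate(lines[2 : 2 + n]):
            parts = line.split()
            beads.append(
                Bead(
                    center=np.array([float(v) for v in parts[1:4]]),
                    radius=float(parts[4]) if len(parts) > 4 else 1.0,
                    bin_index=k,
                )
            )
        return BeadChain(beads=beads)
    raise ValueError(f"unsupported read format {format!r}")


# ---------------------------------------------------------------------------
# Configuration files: JSON document with sections geometry/score/method/
# algorithm, or a flat key-value text with dotted keys ("score.mu1 = 2").
# ---------------------------------------------------------------------------

_SECTIONS = {
    "geometry": GeometryParams,
    "score": ScoreParams,
    "method": MethodParams,
    "algorithm": AlgorithmParams,
}
_STR_FIELDS = {"block_feature_rule"}


def load_config(path: str | Path) -> RunConfig:
    """Parse a configuration file; unspecified keys take their defaults.

    Unknown keys produce a warning and are ignored; a non-numeric value
    for a numeric key is an error.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.strip()
    if not stripped:
        return RunConfig()
    if stripped.startswith("{"):
        raw = json.loads(text)
    else:
        raw = _parse_keyvalue(text)
    return _config_from_dict(raw)


def _parse_keyvalue(text: str) -> dict:
    out: dict = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"cannot parse config line: {line!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        target = out
        *parts, leaf = key.split(".")
        for part in parts:
            target = target.setdefault(part, {})
        target[leaf] = val
    return out


def _coerce(name: str, value, pytype) -> object:
    if name in _STR_FIELDS:
        return str(value)
    if isinstance(value, str):
        low = value.strip().lower()
        if low in ("none", "null", ""):
            return None
        if low in ("true", "false"):
            return low == "true"
        try:
            return float(value) if "." in value or "e" in low else int(value)
        except ValueError as exc:
            raise ValueError(f"non-numeric value {value!r} for key {name!r}") from exc
    if value is None or isinstance(value, (bool, int, float)):
        return value
    raise ValueError(f"unsupported value {value!r} for key {name!r}")


def _config_from_dict(raw: dict) -> RunConfig:
    cfg_kwargs = {}
    for section, cls in _SECTIONS.items():
        sec_raw = raw.pop(section, {})
        if not isinstance(sec_raw, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        for key, val in sec_raw.items():
            if key not in known:
                warnings.warn(f"ignoring unknown config key {section}.{key}")
                continue
            kwargs[key] = _coerce(key, val, known[key].type)
        cfg_kwargs[section] = cls(**kwargs)
    top = {}
    for key, val in raw.items():
        if key == "chip_threshold":
            top["chip_threshold"] = float(_coerce(key, val, float))
        else:
            warnings.warn(f"ignoring unknown config key {key}")
    return RunConfig(**cfg_kwargs, **top)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Serialize a config as JSON; ``load_config`` round-trips it."""
    doc = {
        "geometry": asdict(config.geometry),
        "score": asdict(config.score),
        "method": asdict(config.method),
        "algorithm": asdict(config.algorithm),
        "chip_threshold": config.chip_threshold,
    }
    Path(path).write_text(json.dumps(doc, indent=1))
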