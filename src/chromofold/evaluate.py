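"""Synthetic contact matrices from ensembles, and correlation reports.

Reconstruction quality is assessed by the round trip the method is
meant to close: from an ensemble of configurations, count for each bin
pair in how many members the beads touch (within a tolerance factor),
and correlate that synthetic contact matrix with the observed one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .chain import BeadChain
from .io import ContactMatrix

__all__ = [
    "synthetic_contacts",
    "pearson",
    "pool_ensembles",
    "block_report",
]


def synthetic_contacts(
    ensemble: list[BeadChain], alpha: float = 1.2
) -> ContactMatrix:
    """Contact matrix counted from an ensemble of configurations.

    Entry (i, j) is the number of ensemble members in which beads i and
    j lie within ``alpha * (r_i + r_j)`` of each other (boundary
    inclusive).  The diagonal is zeroed: self-contacts are
    uninformative.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    n = len(ensemble[0])
    if any(len(ch) != n for ch in ensemble):
        raise ValueError("all ensemble chains must have the same length")
    counts = np.zeros((n, n))
    for ch in ensemble:
        pos = ch.positions
        r = ch.radii
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        thresh = alpha * (r[:, None] + r[None, :])
        counts += (d <= thresh).astype(float)
    np.fill_diagonal(counts, 0.0)
    return ContactMatrix(
        values=counts,
        resolution_bp=ensemble[0].resolution_bp,
    )


def pearson(
    a: np.ndarray | ContactMatrix,
    b: np.ndarray | ContactMatrix,
    mask: str = "upper_triangle",
) -> float:
    """Pearson correlation between two matrices over the selected entries.

    Default compares upper triangles excluding the diagonal.  Constant
    input makes the coefficient undefined and raises.
    """
    av = a.values if isinstance(a, ContactMatrix) else np.asarray(a, float)
    bv = b.values if isinstance(b, ContactMatrix) else np.asarray(b, float)
    if av.shape != bv.shape:
        raise ValueError("matrices must have the same shape")
    if mask == "upper_triangle":
        iu, ju = np.triu_indices(av.shape[0], k=1)
        x, y = av[iu, ju], bv[iu, ju]
    elif mask == "all":
        x, y = av.ravel(), bv.ravel()
    else:
        raise ValueError(f"unknown mask {mask!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def pool_ensembles(matrices: list[ContactMatrix]) -> ContactMatrix:
    """Elementwise sum of per-ensemble contact matrices."""
    if not matrices:
        raise ValueError("nothing to pool")
    shape = matrices[0].values.shape
    if any(m.values.shape != shape for m in matrices):
        raise ValueError("shape mismatch while pooling")
    total = np.zeros(shape)
    for m in matrices:
        total += m.values
    return ContactMatrix(
        values=total,
        resolution_bp=matrices[0].resolution_bp,
        start_bin=matrices[0].start_bin,
        chrom=matrices[0].chrom,
    )


def block_report(
    observed: ContactMatrix,
    ensemble: list[BeadChain],
    blocks,
    flags=None,
    alpha: float = 1.2,
) -> pd.DataFrame:
    """Per-block correlation table mirroring the typical evaluation report.

    Columns: block id, bin span, genomic size (kb), total contacts,
    feature flags, pooled-ensemble correlation and mean per-member
    correlation (the two natural ways of summarizing an ensemble).
    """
    synth = synthetic_contacts(ensemble, alpha=alpha)
    rows = []
    for k, blk in enumerate(blocks):
        a, b = blk.start_bin, blk.end_bin
        obs = observed.values[a:b, a:b]
        syn = synth.values[a:b, a:b]
        try:
            corr_pooled = pearson(obs, syn)
        except ValueError:
            corr_pooled = np.nan
        per_member = []
        for ch in ensemble:
            sub = BeadChain(beads=ch.beads[a:b]) if b - a >= 2 else None
            if sub is None:
                continue
            m = synthetic_contacts([sub], alpha=alpha).values
            try:
                per_member.append(pearson(obs, m))
            except ValueError:
                pass
        feat = ""
        if flags is not None:
            parts = []
            if flags[k].expressed:
                parts.append("Expr genes")
            if flags[k].repressed:
                parts.append("H3K27M3")
            if flags[k].ctcf:
                parts.append("CTCF")
            feat = ", ".join(parts)
        rows.append(
            {
                "block": k,
                "start_bin": a,
                "end_bin": b,
                "size_kb": (b - a) * observed.resolution_bp / 1000.0,
                "total_contacts": blk.total_contacts,
                "features": feat,
                "corr_pooled": corr_pooled,
                "corr_member_mean": float(np.mean(per_member)) if per_member else np.nan,
            }
        )
    return pd.DataFrame(rows)
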