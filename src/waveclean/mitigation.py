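"""Medoid-referenced attenuation of flagged scaleogram columns.

The buffer's medoid — the raw coefficient vector minimising the summed
Euclidean distance to all other buffered vectors — stands in for the
prototypical clean-signal column.  Each flagged column is multiplied
element-wise (Hadamard product) by a mitigator vector in ``[0, 1]``: per
scale, the complement of the column's distance from the medoid relative
to the largest such distance seen in the buffer.  Columns far from the
medoid at some scale are therefore attenuated aggressively at that scale,
columns close to it barely at all.  Flagged columns are first widened by
the expansion step, since artefact energy spills into neighbouring
coefficients that may individually sit below the anomaly threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forest import SlidingBuffer
from .scaleogram import CoefficientVector, Scaleogram

__all__ = [
    "MitigatorVector",
    "compute_medoid",
    "expand_timestamps",
    "mitigator_vector",
    "apply_mitigation",
]


@dataclass
class MitigatorVector:
    """Per-scale attenuation factors in [0, 1] for one column."""

    values: np.ndarray
    column_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0.0) or np.any(self.values > 1.0):
            raise ValueError("mitigator entries must lie in [0, 1]")


def compute_medoid(buffer: SlidingBuffer) -> CoefficientVector:
    """Most representative raw vector of a full buffer.

    Uses the buffer's incrementally maintained distance sums; the result
    is cached until the buffer changes.  FIFO ordering makes the argmin
    tie-break equal to "earliest (window_index, column_index)".
    """
    if not buffer.is_full:
        raise ValueError(
            f"buffer holds {len(buffer)}/{buffer.capacity} windows; the "
            "medoid needs a full buffer"
        )
    cached = buffer._medoid_cache
    if cached is not None:
        return cached
    V = buffer.raw_matrix()
    idx = int(np.argmin(buffer.distance_sums()))
    window_index, column_index = buffer.vector_ids()[idx]
    medoid = CoefficientVector(
        values=V[idx].copy(),
        column_index=column_index,
        window_index=window_index,
        normalized=False,
    )
    buffer._medoid_cache = medoid
    return medoid


def expand_timestamps(
    AT: np.ndarray, expansion_step: int, n_columns: int
) -> np.ndarray:
    """Widen each flagged column by ``expansion_step`` on both sides.

    The union of the intervals, clipped to ``[0, n_columns)``, sorted and
    deduplicated.  ``expansion_step == 0`` returns ``AT`` unchanged.
    """
    AT = np.asarray(AT, dtype=np.int64)
    if AT.size == 0:
        return AT.copy()
    if expansion_step < 0:
        raise ValueError("expansion_step must be >= 0")
    offsets = np.arange(-expansion_step, expansion_step + 1)
    expanded = (AT[:, None] + offsets[None, :]).ravel()
    expanded = expanded[(expanded >= 0) & (expanded < n_columns)]
    return np.unique(expanded)


def _max_distances(
    V: np.ndarray, medoid_values: np.ndarray
) -> np.ndarray:
    # per-scale maximum absolute deviation from the medoid over the buffer
    return np.abs(V - medoid_values).max(axis=0)


def mitigator_vector(
    a: CoefficientVector,
    medoid: CoefficientVector,
    buffer: SlidingBuffer,
) -> MitigatorVector:
    """Attenuation factors for one raw column.

    Per scale ``j``: ``1 - |a[j] - medoid[j]| / maxdist[j]`` clamped into
    ``[0, 1]``, where ``maxdist[j]`` is the largest deviation from the
    medoid at scale ``j`` among buffered vectors; scales with zero spread
    get factor 1 (no reduction).
    """
    if len(buffer) == 0:
        raise ValueError("buffer is empty")
    if a.dimension != medoid.dimension:
        raise ValueError("column and medoid dimensions differ")
    maxdist = _max_distances(buffer.raw_matrix(), medoid.values)
    with np.errstate(divide="ignore", invalid="ignore"):
        mtg = 1.0 - np.abs(a.values - medoid.values) / maxdist
    mtg = np.where(maxdist == 0.0, 1.0, mtg)
    return MitigatorVector(
        values=np.clip(mtg, 0.0, 1.0), column_index=a.column_index
    )


def apply_mitigation(
    raw_scaleogram: Scaleogram,
    AT_exp: np.ndarray,
    buffer: SlidingBuffer,
) -> Scaleogram:
    """Hadamard-attenuate every column in ``AT_exp`` of a raw scaleogram.

    Columns outside ``AT_exp`` are bit-identical to the input; attenuated
    entries never grow in magnitude (the mitigator lies in ``[0, 1]``).
    """
    if raw_scaleogram.normalized:
        raise ValueError("mitigation operates on the raw scaleogram")
    AT_exp = np.asarray(AT_exp, dtype=np.int64)
    out = raw_scaleogram.copy()
    if AT_exp.size == 0:
        return out
    if not buffer.is_full:
        raise ValueError("mitigation needs a full buffer")
    medoid = compute_medoid(buffer)
    maxdist = _max_distances(buffer.raw_matrix(), medoid.values)
    cols = out.matrix[:, AT_exp]  # (dim, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        mtg = 1.0 - np.abs(cols - medoid.values[:, None]) / maxdist[:, None]
    mtg = np.where(maxdist[:, None] == 0.0, 1.0, mtg)
    out.matrix[:, AT_exp] = cols * np.clip(mtg, 0.0, 1.0)
    return out
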