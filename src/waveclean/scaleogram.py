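"""Scaleogram container, cross-level normalization and column access.

A scaleogram is a time-by-scale matrix of wavelet coefficients: one row
per detail level (level 1 on top) plus a final approximation row, with
coarse-level coefficients replicated along time so that every row has
``samples_per_window / 2`` columns.  Because coefficient magnitude grows
with decomposition level, each row ``m`` is divided by ``2**m`` before
anomaly detection so all scales carry comparable weight (the
approximation row uses ``2**M``, mirroring its replication factor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Scaleogram",
    "CoefficientVector",
    "normalize",
    "denormalize",
    "columns",
    "from_columns",
    "render",
]


@dataclass
class Scaleogram:
    """Time x scale coefficient matrix for one EEG window.

    ``matrix`` has ``levels + 1`` rows (detail levels 1..M, then the
    approximation) and ``samples_per_window / 2`` columns.  Column ``j``
    covers samples ``[2j, 2j + 2)`` of the window.
    """

    matrix: np.ndarray
    levels: int
    normalized: bool = False
    window_index: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("scaleogram matrix must be two-dimensional")
        if self.matrix.shape[0] != self.levels + 1:
            raise ValueError(
                f"expected {self.levels + 1} rows (levels + approximation), "
                f"got {self.matrix.shape[0]}"
            )

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def copy(self) -> "Scaleogram":
        return Scaleogram(
            matrix=self.matrix.copy(),
            levels=self.levels,
            normalized=self.normalized,
            window_index=self.window_index,
        )


@dataclass
class CoefficientVector:
    """One scaleogram column: per-scale coefficients at one time index."""

    values: np.ndarray
    column_index: int
    window_index: int = 0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("coefficient vector must be one-dimensional")
        if self.column_index < 0:
            raise ValueError("column_index must be >= 0")

    @property
    def dimension(self) -> int:
        return len(self.values)


def _scale_factors(levels: int) -> np.ndarray:
    # 2^m for detail rows m = 1..M, then 2^M for the approximation row.
    return np.concatenate(
        [2.0 ** np.arange(1, levels + 1), [2.0**levels]]
    )[:, None]


def normalize(scaleogram: Scaleogram) -> Scaleogram:
    """Divide row ``m`` by ``2**m`` (approximation row by ``2**M``).

    Returns a new scaleogram; the input is left untouched.
    """
    if scaleogram.normalized:
        raise ValueError("scaleogram is already normalized")
    out = scaleogram.copy()
    out.matrix /= _scale_factors(scaleogram.levels)
    out.normalized = True
    return out


def denormalize(scaleogram: Scaleogram) -> Scaleogram:
    """Exact inverse of :func:`normalize`."""
    if not scaleogram.normalized:
        raise ValueError("scaleogram is not normalized")
    out = scaleogram.copy()
    out.matrix *= _scale_factors(scaleogram.levels)
    out.normalized = False
    return out


def columns(scaleogram: Scaleogram) -> list[CoefficientVector]:
    """Split a scaleogram into its per-time coefficient vectors."""
    return [
        CoefficientVector(
            values=scaleogram.matrix[:, j].copy(),
            column_index=j,
            window_index=scaleogram.window_index,
            normalized=scaleogram.normalized,
        )
        for j in range(scaleogram.n_columns)
    ]


def from_columns(
    vectors: list[CoefficientVector], levels: int, window_index: int = 0
) -> Scaleogram:
    """Reassemble a scaleogram from its columns (inverse of :func:`columns`)."""
    if not vectors:
        raise ValueError("no columns to assemble")
    matrix = np.stack([v.values for v in vectors], axis=1)
    return Scaleogram(
        matrix=matrix,
        levels=levels,
        normalized=vectors[0].normalized,
        window_index=window_index,
    )


def render(scaleogram: Scaleogram, path: str) -> None:
    """Write a quick-look image of the scaleogram (time x level).

    Cosmetic helper for visual inspection only.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(
        np.abs(scaleogram.matrix),
        aspect="auto",
        interpolation="nearest",
        cmap="viridis",
    )
    ax.set_xlabel("coefficient-time column")
    ax.set_ylabel("scale (level 1 .. M, approximation last)")
    title = "normalized scaleogram" if scaleogram.normalized else "scaleogram"
    ax.set_title(f"{title}, window {scaleogram.window_index}")
    fig.colorbar(im, ax=ax, label="|coefficient|")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
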