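"""Multi-level DWT with streaming boundary handling, and the scaleogram
replication / de-replication steps.

Boundary strategy
-----------------
Wavelets near window edges see samples outside the window (the cone of
influence).  In an online setting the left edge of the current window can
be protected by prepending the previous window, but nothing exists to the
right yet, so the signal is extended by a straight line continuing the
first derivative at the edge (smooth padding).  Concretely, the transform
runs on the 4n-sample extension

    [ left linear pad | previous window | current window | right linear pad ]

with a periodized dyadic DWT, and the quarter of each coefficient level
that is time-aligned with the current window is kept.  The pads absorb
wrap-around effects so they never touch the current window's coefficients.
The discarded three quarters are retained as *boundary context*: writing
the (possibly mitigated) current-window coefficients back into that
context before inverting makes reconstruction of an untouched window
exact to machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from .config import EEGWindow, PipelineConfig
from .scaleogram import Scaleogram

__all__ = [
    "DWTCoefficients",
    "decompose",
    "reconstruct",
    "replicate",
    "dereplicate",
    "level_bands",
]


@dataclass
class DWTCoefficients:
    """Wavelet coefficients of one window, trimmed to dyadic lengths.

    ``detail_levels[m - 1]`` holds the level-``m`` detail coefficients
    (length ``samples_per_window / 2**m``); ``approximation`` has length
    ``samples_per_window / 2**M``.  ``boundary_context``, when present,
    stores the full coefficient arrays of the padded 4n-sample extension
    from which these were trimmed, enabling exact reconstruction.
    """

    detail_levels: list[np.ndarray]
    approximation: np.ndarray
    wavelet_name: str
    level_bands: list[tuple[float, float]]
    window_index: int = 0
    boundary_context: list[np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.detail_levels = [
            np.asarray(d, dtype=np.float64) for d in self.detail_levels
        ]
        self.approximation = np.asarray(self.approximation, dtype=np.float64)
        n = len(self.detail_levels[0]) * 2 if self.detail_levels else 0
        for m, d in enumerate(self.detail_levels, start=1):
            if len(d) != n // (2**m):
                raise ValueError(
                    f"level {m} has {len(d)} coefficients, expected {n // 2**m}"
                )
        if len(self.approximation) != n // (2 ** len(self.detail_levels)):
            raise ValueError("approximation length inconsistent with depth")

    @property
    def n_levels(self) -> int:
        return len(self.detail_levels)

    @property
    def samples_per_window(self) -> int:
        return 2 * len(self.detail_levels[0])


def level_bands(sampling_rate: float, levels: int) -> list[tuple[float, float]]:
    """Frequency range (Hz) covered by each detail level.

    Level 1 covers ``[S_r/4, S_r/2]``; each deeper level halves the band.
    """
    return [
        (sampling_rate / 2 ** (m + 1), sampling_rate / 2**m)
        for m in range(1, levels + 1)
    ]


def _edge_slope(x: np.ndarray, side: str, fit: int = 16) -> float:
    """First derivative at an edge, least-squares over ``fit`` samples.

    A short fit keeps the smooth-padding line faithful to the local
    derivative while averaging down sample-to-sample noise, which a long
    extension would otherwise amplify.
    """
    k = min(fit, len(x))
    seg = x[:k] if side == "left" else x[-k:]
    if k < 2:
        return 0.0
    return float(np.polyfit(np.arange(k), seg, 1)[0])


def _relaxed_line_right(
    x: np.ndarray, length: int, tau: float
) -> np.ndarray:
    """Straight-line continuation of the right edge, relaxing to the edge
    value with time constant ``tau`` so the extension stays signal-scale."""
    i = np.arange(1, length + 1)
    return x[-1] + _edge_slope(x, "right") * i * np.exp(-(i - 1) / tau)


def _relaxed_line_left(x: np.ndarray, length: int, tau: float) -> np.ndarray:
    i = np.arange(length, 0, -1)
    return x[0] - _edge_slope(x, "left") * i * np.exp(-(i - 1) / tau)


def _circular_pads(
    body: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Left and right pads (each ``n`` samples) closing the 4n circle.

    The transform uses a periodized DWT, so the extension wraps: the
    right pad must flow back into the left pad without a jump.  Each pad
    starts as the smooth (first-derivative straight line) continuation of
    its edge, relaxed toward the edge value, and the two are crossfaded
    across the combined 2n pad region so the circle is continuous.
    """
    tau = max(4.0, n / 8.0)
    right = _relaxed_line_right(body, 2 * n, tau)
    left = _relaxed_line_left(body, 2 * n, tau)
    w = np.linspace(1.0, 0.0, 2 * n)
    pad = w * right + (1.0 - w) * left
    return pad[n:], pad[:n]  # (left pad, right pad) in array order


def decompose(
    current: EEGWindow,
    previous: EEGWindow | None,
    config: PipelineConfig,
) -> DWTCoefficients:
    """Decompose the current window with streaming boundary handling.

    The transform runs on ``<left pad, previous, current, right pad>``
    (each block ``samples_per_window`` long); when ``previous`` is absent
    (the first window of a stream) the left half is entirely smooth
    padding.  Per level, the quarter of coefficients aligned with the
    current window is returned; the rest is kept as boundary context.
    """
    n = config.samples_per_window
    x = np.asarray(current.samples, dtype=np.float64)
    if len(x) != n:
        raise ValueError(f"window has {len(x)} samples, expected {n}")
    if config.mother_wavelet not in pywt.wavelist(kind="discrete"):
        raise ValueError(f"unknown discrete wavelet: {config.mother_wavelet!r}")

    if previous is not None:
        prev = np.asarray(previous.samples, dtype=np.float64)
        if len(prev) != n:
            raise ValueError("previous window has inconsistent length")
        body = np.concatenate([prev, x])
    else:
        # first window of a stream: the left context is itself smooth
        # padding (straight-line continuation of the left edge)
        tau = max(4.0, n / 8.0)
        body = np.concatenate([_relaxed_line_left(x, n, tau), x])
    left_pad, right_pad = _circular_pads(body, n)
    extended = np.concatenate([left_pad, body, right_pad])

    M = config.levels
    # coeffs = [cA_M, cD_M, ..., cD_1] over the 4n-sample extension.
    # pywt advises against depths where every coefficient feels the
    # boundary; the full dyadic pyramid is intentional here and the pads
    # absorb the boundary, so the advisory warning is silenced.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(
            extended, config.mother_wavelet, mode="periodization", level=M
        )

    details: list[np.ndarray] = []
    for m in range(1, M + 1):
        full = coeffs[M - m + 1]
        k = n // (2**m)
        details.append(full[2 * k : 3 * k].copy())
    k_app = n // (2**M)
    approx = coeffs[0][2 * k_app : 3 * k_app].copy()

    return DWTCoefficients(
        detail_levels=details,
        approximation=approx,
        wavelet_name=config.mother_wavelet,
        level_bands=level_bands(config.sampling_rate, M),
        window_index=current.window_index,
        boundary_context=[c.copy() for c in coeffs],
    )


def reconstruct(
    coeffs: DWTCoefficients, config: PipelineConfig
) -> np.ndarray:
    """Invert the DWT back to a time-domain window.

    With boundary context attached (the normal streaming path) the
    current-window coefficients are written back into the context of the
    padded extension before inverting, so an untouched decomposition
    reproduces the window to machine precision.  Without context, the
    trimmed coefficients are inverted standalone as a periodized DWT.
    """
    n = config.samples_per_window
    M = coeffs.n_levels
    if coeffs.samples_per_window != n:
        raise ValueError("coefficient lengths inconsistent with config")

    if coeffs.boundary_context is not None:
        full = [c.copy() for c in coeffs.boundary_context]
        for m in range(1, M + 1):
            k = n // (2**m)
            full[M - m + 1][2 * k : 3 * k] = coeffs.detail_levels[m - 1]
        k_app = n // (2**M)
        full[0][2 * k_app : 3 * k_app] = coeffs.approximation
        signal = pywt.waverec(full, coeffs.wavelet_name, mode="periodization")
        return signal[2 * n : 3 * n]

    arrays = [coeffs.approximation] + [
        coeffs.detail_levels[m - 1] for m in range(M, 0, -1)
    ]
    return pywt.waverec(arrays, coeffs.wavelet_name, mode="periodization")[:n]


def replicate(coeffs: DWTCoefficients) -> Scaleogram:
    """Expand coefficients into the equal-width scaleogram matrix.

    Level-``m`` coefficients are each repeated ``2**(m-1)`` times along
    time; the approximation row uses the level-``M`` factor.  Every row
    then has ``samples_per_window / 2`` columns.
    """
    M = coeffs.n_levels
    rows = [
        np.repeat(coeffs.detail_levels[m - 1], 2 ** (m - 1))
        for m in range(1, M + 1)
    ]
    rows.append(np.repeat(coeffs.approximation, 2 ** (M - 1)))
    return Scaleogram(
        matrix=np.stack(rows),
        levels=M,
        normalized=False,
        window_index=coeffs.window_index,
    )


def dereplicate(
    scaleogram: Scaleogram,
    template: DWTCoefficients | None = None,
    sampling_rate: float | None = None,
    wavelet_name: str = "sym4",
) -> DWTCoefficients:
    """Undo the replication: keep the first of every ``2**(m-1)`` entries.

    The scaleogram must be on the raw coefficient scale.  ``template``
    (typically the coefficients the scaleogram was built from) supplies
    the wavelet name, frequency bands and boundary context; otherwise
    they are reconstructed from ``sampling_rate`` / ``wavelet_name``.
    """
    if scaleogram.normalized:
        raise ValueError("de-normalize the scaleogram before de-replicating")
    M = scaleogram.levels
    cols = scaleogram.n_columns
    details = []
    for m in range(1, M + 1):
        step = 2 ** (m - 1)
        if cols % step != 0:
            raise ValueError(
                f"column count {cols} not divisible by 2^{m - 1}"
            )
        details.append(scaleogram.matrix[m - 1, ::step].copy())
    approx = scaleogram.matrix[M, :: 2 ** (M - 1)].copy()

    if template is not None:
        name = template.wavelet_name
        bands = template.level_bands
        context = template.boundary_context
    else:
        name = wavelet_name
        bands = level_bands(sampling_rate if sampling_rate else 2.0 * cols, M)
        context = None
    return DWTCoefficients(
        detail_levels=details,
        approximation=approx,
        wavelet_name=name,
        level_bands=bands,
        window_index=scaleogram.window_index,
        boundary_context=context,
    )
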