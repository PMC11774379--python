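"""Pipeline configuration and sliding-window segmentation.

The online denoiser consumes a continuous single-channel EEG signal as a
sequence of fixed-length, non-overlapping windows.  The window length
(milliseconds) together with the sampling rate fixes the number of samples
per window, which must support a full dyadic wavelet pyramid; all other
pipeline parameters (buffer capacity, forest size, anomaly threshold,
expansion step) live on :class:`PipelineConfig`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "EEGWindow",
    "validate_config",
    "max_frequency",
    "slide_windows",
]


@dataclass
class PipelineConfig:
    """All tunable parameters of the online denoising pipeline.

    Defaults are the blink instantiation: 1-second windows at 1024 Hz,
    sym4 mother wavelet, a 20-window sliding buffer, a 100-tree extended
    isolation forest trained on 512-vector sub-samples, anomaly threshold
    0.55 and an expansion step of 35 coefficient columns.

    Parameters
    ----------
    window_ms :
        Real-time window length in milliseconds.
    sampling_rate :
        Sampling rate of the recording in Hz.
    mother_wavelet :
        PyWavelets name of the mother wavelet (e.g. ``"sym4"``).
    buffer_capacity :
        Number of past windows held in the sliding learning buffer.
    if_subsample :
        Vectors drawn (without replacement) to grow each isolation tree.
    if_trees :
        Number of trees in the extended isolation forest.
    anomaly_threshold :
        Score threshold in (0, 1) above which a coefficient vector is
        flagged anomalous.
    expansion_step :
        Number of neighbouring coefficient columns on each side of a
        flagged column that are also mitigated.
    extension_level :
        Extended-forest extension level in ``[0, dim - 1]``; ``None``
        selects the fully extended setting ``dim - 1``.
    max_level :
        Optional cap on the wavelet decomposition depth; ``None`` means
        the full pyramid ``log2(samples_per_window)``.
    seed :
        Base seed for every stochastic component.
    min_anomalies_for_positive :
        Minimum number of flagged columns for a window to count as a
        detection when classifying windows.
    """

    window_ms: float = 1000.0
    sampling_rate: float = 1024.0
    mother_wavelet: str = "sym4"
    buffer_capacity: int = 20
    if_subsample: int = 512
    if_trees: int = 100
    anomaly_threshold: float = 0.55
    expansion_step: int = 35
    extension_level: int | None = None
    max_level: int | None = None
    seed: int = 0
    min_anomalies_for_positive: int = 1

    # Derived sizes, filled in by validate().
    samples_per_window: int = field(default=0, init=False, repr=False)
    columns_per_window: int = field(default=0, init=False, repr=False)
    levels: int = field(default=0, init=False, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> "PipelineConfig":
        """Check every invariant and fill the derived sizes.

        Returns the (mutated) config itself so calls can be chained.
        Raises ``ValueError`` on any violation.
        """
        if self.window_ms <= 0 or self.sampling_rate <= 0:
            raise ValueError("window_ms and sampling_rate must be positive")

        exact = self.window_ms * self.sampling_rate / 1000.0
        n = round(exact)
        if abs(exact - n) > 1e-9 or n < 2:
            raise ValueError(
                f"window of {self.window_ms} ms at {self.sampling_rate} Hz "
                f"does not contain an integer number of samples ({exact})"
            )

        if self.max_level is None:
            levels = int(math.log2(n))
            if 2**levels != n:
                raise ValueError(
                    f"samples per window ({n}) must be a power of 2 for a "
                    "full dyadic decomposition; set max_level to cap the "
                    "depth for multiple-of-power-of-2 lengths"
                )
        else:
            levels = int(self.max_level)
            if levels < 1:
                raise ValueError("max_level must be >= 1")
            if n % (2**levels) != 0:
                raise ValueError(
                    f"samples per window ({n}) is not divisible by "
                    f"2^max_level (2^{levels})"
                )

        if not 0.0 < self.anomaly_threshold < 1.0:
            raise ValueError("anomaly_threshold must lie strictly in (0, 1)")
        if self.expansion_step < 0:
            raise ValueError("expansion_step must be >= 0")
        if self.buffer_capacity < 1:
            raise ValueError("buffer_capacity must be >= 1")
        if self.if_trees < 1:
            raise ValueError("if_trees must be >= 1")
        if self.min_anomalies_for_positive < 1:
            raise ValueError("min_anomalies_for_positive must be >= 1")

        columns = n // 2
        if self.if_subsample < 2:
            raise ValueError("if_subsample must be >= 2")
        if self.if_subsample > self.buffer_capacity * columns:
            raise ValueError(
                f"if_subsample ({self.if_subsample}) exceeds the buffer "
                f"population ({self.buffer_capacity} x {columns} vectors)"
            )

        rows = levels + 1  # detail levels plus the approximation row
        if self.extension_level is not None and not (
            0 <= self.extension_level <= rows - 1
        ):
            raise ValueError(
                f"extension_level must lie in [0, {rows - 1}]"
            )

        self.samples_per_window = n
        self.columns_per_window = columns
        self.levels = levels
        return self

    # ------------------------------------------------------------------
    @property
    def scaleogram_rows(self) -> int:
        """Number of scaleogram rows: detail levels plus approximation."""
        return self.levels + 1

    @property
    def resolved_extension_level(self) -> int:
        if self.extension_level is None:
            return self.scaleogram_rows - 1
        return self.extension_level

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        """Return a fresh, validated copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class EEGWindow:
    """One fixed-length segment of a single EEG channel (microvolts)."""

    samples: np.ndarray
    window_index: int
    start_sample: int
    channel_label: str = "EEG"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("window samples must be one-dimensional")
        if self.window_index < 0:
            raise ValueError("window_index must be >= 0")


def validate_config(config: PipelineConfig) -> PipelineConfig:
    """Functional alias for :meth:`PipelineConfig.validate`."""
    return config.validate()


def max_frequency(window_ms: float, sampling_rate: float) -> float:
    """Highest frequency (Hz) meaningfully resolvable from one window.

    By Nyquist, a window of ``window_ms`` milliseconds sampled at
    ``sampling_rate`` Hz resolves frequencies up to
    ``window_ms * sampling_rate / 1000 * 0.5``.
    """
    if window_ms <= 0 or sampling_rate <= 0:
        raise ValueError("window_ms and sampling_rate must be positive")
    return window_ms * sampling_rate / 1000.0 * 0.5


def slide_windows(
    signal: np.ndarray,
    config: PipelineConfig,
    channel_label: str = "EEG",
) -> list[EEGWindow]:
    """Cut a continuous signal into consecutive non-overlapping windows.

    A trailing remainder shorter than one window is dropped (and logged):
    in the online setting it would never be completed.
    """
    signal = np.asarray(signal, dtype=np.float64)
    n = config.samples_per_window
    if signal.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if len(signal) < n:
        raise ValueError(
            f"signal ({len(signal)} samples) is shorter than one window ({n})"
        )
    count = len(signal) // n
    dropped = len(signal) - count * n
    if dropped:
        logger.info("dropping %d-sample trailing remainder (< 1 window)", dropped)
    return [
        EEGWindow(
            samples=signal[i * n : (i + 1) * n],
            window_index=i,
            start_sample=i * n,
            channel_label=channel_label,
        )
        for i in range(count)
    ]
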