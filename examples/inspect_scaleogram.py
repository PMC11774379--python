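"""Decompose one EEG window and inspect its scaleogram.

Shows the dyadic coefficient layout (level m holds n / 2^m detail
coefficients covering [S_r/2^(m+1), S_r/2^m] Hz), the replication that
equalises row widths, and the per-level normalization; optionally writes
a quick-look image.
"""

import sys

import numpy as np

from waveclean import (
    PipelineConfig,
    decompose,
    generate_recording,
    normalize,
    replicate,
    slide_windows,
)
from waveclean.scaleogram import render

config = PipelineConfig(seed=0)  # 1 s windows at 1024 Hz, sym4, full depth
recording = generate_recording(duration_s=5.0, sampling_rate=1024.0, seed=0)
windows = slide_windows(recording.contaminated, config)

coeffs = decompose(windows[1], windows[0], config)
print(f"decomposition depth: {coeffs.n_levels} levels")
for m, (detail, band) in enumerate(zip(coeffs.detail_levels, coeffs.level_bands), 1):
    print(f"  level {m:2d}: {len(detail):4d} coefficients, "
          f"[{band[0]:6.1f}, {band[1]:6.1f}] Hz")
print(f"  approximation: {len(coeffs.approximation)} coefficient(s), "
      f"[0.0, {config.sampling_rate / 2 ** (coeffs.n_levels + 1):.1f}] Hz")

scal = replicate(coeffs)
print(f"scaleogram: {scal.n_rows} rows x {scal.n_columns} columns "
      f"(each column = 2 samples of the window)")
norm = normalize(scal)
print(f"raw row magnitudes:        {np.round(np.abs(scal.matrix).mean(axis=1), 2)}")
print(f"normalized row magnitudes: {np.round(np.abs(norm.matrix).mean(axis=1), 2)}")
# Raw magnitudes grow with level (low frequencies dominate EEG); after
# dividing row m by 2^m all scales carry comparable weight.

if len(sys.argv) > 1:
    render(norm, sys.argv[1])
    print(f"wrote scaleogram image to {sys.argv[1]}")
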