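# Methods

## Signal model and scope

The pipeline assumes the additive model `x(n) = s(n) + v(n)`: observed
EEG is a neural signal plus instantaneously propagated artefact. It is
strictly online — at any moment only the current window and a bounded
buffer of past windows exist — and strictly single-channel;
multi-channel recordings are processed channel-wise. The instantiation
shipped here targets eye blinks: large positive transients of 100–400 ms
with energy below ~20 Hz. Other artefact classes (saccades, muscle,
cardiac) would need their own instantiation (window length, mother
wavelet, threshold) and are out of scope.

## Windowing and decomposition

Windows are non-overlapping and fixed at `window_ms` (default 1000 ms);
a trailing remainder shorter than one window is dropped, since the
online setting never completes it. The sample count per window must be
a power of two (or a multiple of one when `max_level` caps the depth)
for the dyadic filter cascade. The default depth is the full pyramid
`M = log2(n)` — 10 levels for 1024 samples — on the grounds that the
cascade runs until the low-pass output cannot be halved again; the final
approximation row (the residual 0–`S_r/2^(M+1)` Hz band) is carried
through the scaleogram, the anomaly vectors and mitigation, so the
entire signal energy stays inside one uniform column pipeline.

### Boundary handling

Wavelets near window edges read samples outside the window (the cone of
influence). The left edge is protected by prepending the previous
window; the right edge, where no data exists yet, is extended by smooth
padding — a straight line continuing the edge's first derivative. Two
implementation choices matter:

- The transform actually runs on a 4n-sample extension
  `[left pad | previous | current | right pad]` under a *periodized*
  DWT, which keeps every level's coefficient count exactly dyadic and
  the inverse exact. The pads absorb the periodic wrap, so wrap-around
  never touches the current window's coefficients.
- A naive straight-line pad of n samples amplifies sample-to-sample
  noise in the edge slope by three orders of magnitude and corrupts the
  deep (low-frequency) coefficients. The pads therefore estimate the
  edge slope by a 16-sample least-squares fit and relax the line toward
  the edge value with time constant `n/8` samples, crossfading the two
  pad halves so the periodization circle stays continuous. Smooth-
  padding semantics hold near the edges, where they matter; far from the
  edges the pad is a benign signal-scale bridge.

Per level, the quarter of coefficients time-aligned with the current
window is kept; the remainder is retained as *boundary context*.
Reconstruction writes the (possibly attenuated) current-window
coefficients back into that context before inverting, which makes
`reconstruct(decompose(w))` exact to machine precision (~1e-12
relative; the tested contract is 1e-8). A consequence worth noting:
with context attached, reconstruction is affine rather than homogeneous-
linear in the window's own coefficients — zeroing every coefficient of
the current window removes the window's contribution but not what its
neighbours' deep-level basis functions carry into it. Coefficients
built standalone (without context) invert as an ordinary periodized
DWT, and there zeroing everything yields exactly zero.

## Scaleogram and normalization

Level-`m` coefficients are repeated `2^(m-1)` times (the approximation
row `2^(M-1)`), giving an `(M+1) × n/2` matrix whose column `j`
corresponds to samples `[2j, 2j+2)`. Rows are then divided by `2^m`
(approximation by `2^M`, mirroring its replication factor — the source
method is silent on this row). The division rests on an empirical
property of EEG: raw coefficient magnitude roughly doubles per level,
i.e. background power falls as ~1/f². Under that spectrum the
normalized rows have comparable scale and every frequency band
contributes comparably to the anomaly geometry. Under a shallower 1/f
spectrum the same division over-suppresses low-frequency rows — exactly
the band where blinks live — and detection degrades noticeably; this is
a real sensitivity of the method, reproducible with the generator's
`spectral_exponent` parameter.

## Extended isolation forest

Artefact columns are rare and far from the bulk of recent activity, so
isolation depth separates them without labels or distributional
assumptions. Trees are grown per window from the buffer's normalized
columns: `if_trees` trees (default 100), each on `if_subsample` columns
(default 512) drawn uniformly without replacement. Splits are oblique:
slope drawn from a standard normal with `dim − 1 − el` randomly chosen
coordinates zeroed (`el = dim − 1` by default, the fully extended,
bias-minimizing setting; `el = 0` recovers the axis-parallel original),
intercept uniform inside the node's bounding box, branch rule
`(x − intercept) · slope ≤ 0`. Growth stops at one point, identical
points, or depth `⌈log2(if_subsample)⌉`; truncated leaves contribute
the standard correction `c(size) = 2H(size−1) − 2(size−1)/size`. The
score `2^(−E[h]/c(if_subsample))` lies in (0, 1): ~0.5 for unremarkable
columns, near 1 for easily isolated ones. The anomaly threshold
`t_a = 0.55` is deliberately slightly stricter than the 0.5 rule of
thumb. Flagging is strict (`> t_a`).

The forest is retrained after every window once the buffer is full; the
buffer stores *pre-denoising* columns only, so mitigation output never
feeds back into training. Trees live in flat arrays over an implicit
complete binary tree, and both growth and scoring are vectorized level
by level; a full retrain-plus-score cycle costs ~0.2 s per 1-second
window on one core, comfortably inside the pseudo-real-time budget
(per-window wall time is logged and a warning is emitted if it exceeds
the window length — informational, since the bound is
hardware-dependent).

During cold start (fewer than `buffer_capacity` windows seen) windows
pass through untouched and only fill the buffer: no forest can be
trained, and silence is the only behaviour consistent with the method.

## Mitigation

The buffer medoid — the raw column minimising the summed Euclidean
distance to all other buffered columns (ties: earliest window/column;
running distance sums are maintained incrementally on append) — stands
in for the prototypical clean column. Each flagged column, widened by
`expansion_step` columns per side (set union, clipped to the window),
is multiplied element-wise by `mtg = 1 − |a − medoid| / maxdist`,
computed per scale with `maxdist` the largest per-scale deviation from
the medoid inside the buffer. The distance is taken per row rather than
as a scalar norm: the attenuation must be a vector for the Hadamard
product, and per-scale attenuation is what lets a blink's low-frequency
rows shrink while its untouched high-frequency rows survive. Entries
are clamped to [0, 1] and rows with zero buffer spread are left at 1;
both guards prevent sign flips and division by zero on degenerate
buffers. Attenuated coefficients never grow in magnitude, though the
time-domain amplitude can locally increase after inversion because
neighbouring scales interact in the inverse transform.

## Synthetic data

The generator emulates a contaminated frontal channel:

- Background: Gaussian noise with power ∝ 1/f^α (flat below 0.5 Hz,
  emulating an acquisition high-pass), α = 2 by default — the regime
  the normalization is built for (see above) and typical of low-band
  frontal EEG — plus a 10 Hz alpha oscillation at 20% of the RMS;
  total scaled to 15 µV RMS.
- Blinks: positive squared-cosine pulses, widths uniform in 100–400 ms,
  amplitude 80 µV ± 20%, Poisson arrivals at 12/min with a 500 ms
  refractory gap. The ~5× blink-to-background amplitude ratio sits
  below the "order of magnitude" ceiling real frontal channels show. A
  squared-cosine template rather than a sampled sym4 atom keeps
  detection tests from trivially favouring the chosen mother wavelet.
  A `double_blinks` flag emits pulse pairs 300 ms apart to reproduce
  the known hard case.
- `contaminated = clean + artefact` exactly, with peak samples and
  widths recorded, so oracle metrics need no estimation.

What the generator does *not* model: non-Gaussian burst activity,
saccades and muscle artefact, electrode pops, line noise,
non-stationary background drift, volume conduction. Passing tests on
this data demonstrates the pipeline's mechanics under its own
assumptions, not clinical-grade performance on real recordings.

## Evaluation

Ground truth without labels comes from a VEOG-style peak detector: FIR
band-pass 1–10 Hz (windowed-sinc, ~1 s odd-length impulse response,
zero-phase application), rectify, square-root; threshold
`(max − std)/k`; local maxima at least 500 ms apart. A sweep over
`k ∈ {1.5, 2, 2.5, 3, 4, 6}` stops early when the accepted count fails
to improve for 2 consecutive steps (patience). Because the
sqrt-compressed 1–10 Hz statistic is deliberately permissive, accepted
peaks must additionally pass a plausible-blink filter — the
single-channel stand-in for multi-channel topographic confirmation: a
matched filter whitened against the 1/f² background model (content
above 100 Hz dropped, alpha band softened) over a Hann template bank at
100/160/250/400 ms, each width channel standardized by its robust MAD
scale, acceptance at z ≥ 5.0. Under the generator's study conditions
blink peaks score z ≳ 5.2 and background maxima ≲ 4.8; the residual
failure mode is a blink landing on a deep background trough that
destructively cancels it — information genuinely lost in a single
channel.

Windows are classified with the standard confusion convention, with
*detection* as the positive class: a window is positive when at least
`min_anomalies_for_positive` columns were flagged (default 1, kept
configurable because a single flagged column is a noisy criterion), a
blink window when it contains ≥ 1 accepted peak. Accuracy is
`(TP+TN)/total`. Only post-warm-up windows enter the counts:
cold-start windows are pass-through by construction and measure
nothing.

SNR on synthetic data is the oracle form
`10·log10(Σs² / Σ(x−s)²)` dB against the known clean signal, capped at
+100 dB for numerically zero residuals. For real recordings, where no
clean reference exists, `proxy_snr` (band-power ratio 15–40 Hz over
0.5–8 Hz) is provided and clearly labelled a proxy; no acceptance
property relies on it. Before/after SNR distributions per category are
compared with the base-2 Jensen–Shannon divergence on 30 shared
equal-width bins: 0 for identical distributions (true negatives, which
are bit-identical, score exactly 0), 1 for disjoint ones.

## Numerical and design choices

- Score formulas follow the standard isolation-forest forms; the
  normalizer is `c(n) = 2H(n−1) − 2(n−1)/n` with `H(i) = ln i + γ`.
- Forest seeds derive per window from the base seed via
  `SeedSequence([seed, window_index])`; identical seed and input give
  bit-identical anomaly lists and output.
- Windows whose anomaly list is empty skip the inverse transform
  entirely and return the original sample array, making pass-through
  exact by construction rather than within floating-point tolerance.
- The medoid requires a full buffer; `expansion_step = 0` degenerates
  to mitigating exactly the flagged columns; `t_a = 1` flags nothing.
- Default problem sizes in tests and the acceptance script (60 s
  recordings, 3–10 seeds) were chosen to exercise every stage at the
  full blink instantiation while keeping a complete run in minutes on
  one core.

## Known limitations

- Detection quality depends on the buffer being mostly clean; a buffer
  dominated by artefact inverts the notion of "normal". The method
  assumes artefacts are rare in any 20-second span.
- The right window edge remains the weak spot: nothing real exists
  beyond it, so blinks at the very end of a window are found less
  reliably — visible in the synthetic studies as occasional misses on
  boundary-straddling blinks.
- Small configurations (short buffers, few columns) flag background
  noticeably more often; the clean-window pass-through rates reported
  by the acceptance script hold at the full instantiation, not at
  arbitrarily scaled-down ones.
- Consecutive blinks inside one window partially mask each other, and
  the per-level normalization assumes a steep (~1/f²) background; both
  are inherited properties of the method, demonstrable with the
  generator's `double_blinks` and `spectral_exponent` switches.
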