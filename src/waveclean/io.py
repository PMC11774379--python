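"""Recording readers/writers, run outputs and config files.

CSV recordings use one header row of channel labels and one column per
channel, amplitudes in microvolts; the sampling rate comes from a flag
or a YAML sidecar (same stem, ``.yaml``).  EDF/BDF files are read
through MNE and converted to microvolts.  Run outputs are plain text:
the denoised signal (CSV), flagged intervals (CSV, half-open sample
spans), a per-window log and the fully resolved configuration (YAML),
so a run can be replayed exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import PipelineConfig
from .forest import AnomalyReport
from .pipeline import DenoiseRun

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "read_recording",
    "write_recording_csv",
    "write_outputs",
    "load_config",
    "save_config",
]


@dataclass
class Recording:
    """Multi-channel recording in microvolts (channels processed independently)."""

    data: np.ndarray  # (n_channels, n_samples)
    sampling_rate: float
    channel_labels: list[str]
    source_path: str = ""
    format_tag: str = "array"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channel_labels.index(label)]
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in {self.channel_labels}"
            ) from None


def _sidecar_rate(path: Path) -> float | None:
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        if isinstance(meta, dict) and "sampling_rate" in meta:
            return float(meta["sampling_rate"])
    return None


def read_recording(
    path: str | Path,
    fmt: str = "auto",
    sampling_rate: float | None = None,
) -> Recording:
    """Load a recording from CSV/TSV, EDF or BDF.

    CSV needs a sampling rate (argument or ``.yaml`` sidecar); EDF/BDF
    carry their own.  Amplitudes are returned in microvolts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        suffix = path.suffix.lower().lstrip(".")
        fmt = {"csv": "csv", "tsv": "csv", "txt": "csv", "edf": "edf", "bdf": "bdf"}.get(
            suffix, ""
        )
        if not fmt:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")

    if fmt == "csv":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        frame = pd.read_csv(path, sep=sep)
        rate = sampling_rate if sampling_rate is not None else _sidecar_rate(path)
        if rate is None:
            raise ValueError(
                "CSV recordings need a sampling rate (argument or .yaml sidecar)"
            )
        return Recording(
            data=frame.to_numpy(dtype=np.float64).T,
            sampling_rate=float(rate),
            channel_labels=[str(c) for c in frame.columns],
            source_path=str(path),
            format_tag="csv",
        )

    if fmt in ("edf", "bdf"):
        import mne

        reader = mne.io.read_raw_edf if fmt == "edf" else mne.io.read_raw_bdf
        raw = reader(str(path), preload=True, verbose="error")
        rates = {info["sfreq"] for info in [raw.info]}
        if len(rates) != 1:
            raise ValueError("channels with mismatched sampling rates")
        return Recording(
            data=raw.get_data() * 1e6,  # Volts -> microvolts
            sampling_rate=float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
            source_path=str(path),
            format_tag=fmt,
        )

    raise ValueError(f"unknown format {fmt!r}")


def write_recording_csv(path: str | Path, recording: Recording) -> None:
    """One column per channel, microvolts, plus a sampling-rate sidecar."""
    path = Path(path)
    frame = pd.DataFrame(
        recording.data.T, columns=recording.channel_labels
    )
    frame.to_csv(path, index=False, float_format="%.6f")
    path.with_suffix(".yaml").write_text(
        yaml.safe_dump({"sampling_rate": recording.sampling_rate})
    )


def _intervals_from_reports(
    reports: list[AnomalyReport], config: PipelineConfig
) -> pd.DataFrame:
    """Merge flagged columns into half-open [start, end) sample intervals."""
    rows = []
    n = config.samples_per_window
    for report in reports:
        cols = report.AT_exp if report.AT_exp.size else report.AT
        if not cols.size:
            continue
        breaks = np.flatnonzero(np.diff(cols) > 1)
        starts = np.r_[cols[0], cols[breaks + 1]]
        ends = np.r_[cols[breaks], cols[-1]] + 1
        for a, b in zip(starts, ends):
            span = (report.AT >= a) & (report.AT < b)
            rows.append(
                {
                    "window_index": report.window_index,
                    "start_sample": report.window_index * n + 2 * int(a),
                    "end_sample": report.window_index * n + 2 * int(b),
                    "n_flagged_columns": int(span.sum()),
                    "max_score": float(report.scores[report.AT[span]].max())
                    if span.any()
                    else float("nan"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "window_index",
            "start_sample",
            "end_sample",
            "n_flagged_columns",
            "max_score",
        ],
    )


def write_outputs(
    out_dir: str | Path,
    run: DenoiseRun,
    channel_label: str = "EEG",
) -> dict[str, Path]:
    """Write a run's denoised signal, intervals, log and config echo."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    denoised = out_dir / f"denoised_{channel_label}.csv"
    write_recording_csv(
        denoised,
        Recording(
            data=run.denoised_signal[None, :],
            sampling_rate=run.config.sampling_rate,
            channel_labels=[channel_label],
        ),
    )

    intervals = out_dir / f"intervals_{channel_label}.csv"
    _intervals_from_reports(run.reports, run.config).to_csv(
        intervals, index=False, float_format="%.6f"
    )

    log = out_dir / f"windows_{channel_label}.csv"
    pd.DataFrame(
        {
            "window_index": [w.window_index for w in run.windows],
            "modified": [w.modified for w in run.windows],
            "n_anomalies": [r.n_anomalies for r in run.reports],
            "latency_ms": [w.latency_s * 1000.0 for w in run.windows],
        }
    ).to_csv(log, index=False, float_format="%.3f")

    config_path = out_dir / "config.yaml"
    save_config(config_path, run.config)
    return {
        "denoised": denoised,
        "intervals": intervals,
        "windows": log,
        "config": config_path,
    }


_CONFIG_FIELDS = [f.name for f in dataclasses.fields(PipelineConfig) if f.init]


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Read a YAML config file; keyword overrides win over file values."""
    values = yaml.safe_load(Path(path).read_text()) or {}
    # derived sizes echoed by save_config are re-derived, not read back
    for derived in ("samples_per_window", "columns_per_window", "levels"):
        values.pop(derived, None)
    unknown = set(values) - set(_CONFIG_FIELDS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)


def save_config(path: str | Path, config: PipelineConfig) -> None:
    """Write the fully resolved configuration, enabling exact replay."""
    payload = {name: getattr(config, name) for name in _CONFIG_FIELDS}
    payload.update(
        {
            "samples_per_window": config.samples_per_window,
            "columns_per_window": config.columns_per_window,
            "levels": config.levels,
        }
    )
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
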