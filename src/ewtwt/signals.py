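"""Uniformly sampled 1-D signals and their plain-text (CSV) serialisation.

A :class:`Signal` is the universal currency of the package: clean ECG,
motion-artifact noise, noisy mixtures and denoised outputs are all Signals in
different roles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Signal", "read_signal_csv", "write_signal_csv"]


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled real-valued waveform.

    Parameters
    ----------
    samples : array-like
        Amplitudes in arbitrary units (typically mV for ECG).
    fs : float
        Sampling rate in Hz; strictly positive.
    label : str, optional
        Free-text identifier carried through the pipeline.
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float)
        if x.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {x.shape}")
        if x.size == 1:
            raise ValueError("a signal needs at least 2 samples")
        if x.size and not np.all(np.isfinite(x)):
            raise ValueError("samples contain non-finite values")
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise ValueError(f"sampling rate must be positive and finite, got {self.fs}")
        object.__setattr__(self, "samples", x)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "Signal":
        """Return a new Signal sharing this one's sampling rate."""
        return Signal(samples, self.fs, self.label if label is None else label)


def read_signal_csv(path, fs: float | None = None, label: str | None = None) -> Signal:
    """Read a signal from CSV.

    Accepts either a single amplitude column (``fs`` required) or two columns
    ``time, amplitude`` (sampling rate inferred from the time grid). A header
    row is detected automatically.
    """
    df = pd.read_csv(path, comment="#")
    # If the "header" parses as numbers the file had none; re-read headerless.
    try:
        [float(c) for c in df.columns]
        df = pd.read_csv(path, comment="#", header=None)
    except (TypeError, ValueError):
        pass
    if df.shape[1] == 1:
        if fs is None:
            raise ValueError("single-column CSV needs an explicit sampling rate")
        x = df.iloc[:, 0].to_numpy(dtype=float)
    elif df.shape[1] >= 2:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        x = df.iloc[:, 1].to_numpy(dtype=float)
        dt = np.diff(t)
        if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time column is not uniformly sampled")
        inferred = 1.0 / dt[0]
        if fs is not None and not np.isclose(fs, inferred, rtol=1e-6):
            raise ValueError(f"stated fs={fs} disagrees with time column ({inferred:.6g} Hz)")
        fs = inferred
    else:
        raise ValueError("empty CSV")
    return Signal(x, float(fs), label if label is not None else str(path))


def write_signal_csv(sig: Signal, path) -> None:
    """Write ``time, amplitude`` columns with a header."""
    pd.DataFrame({"time": sig.times, "amplitude": sig.samples}).to_csv(path, index=False)
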