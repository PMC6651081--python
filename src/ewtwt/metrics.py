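"""Signal-quality metrics for denoiser evaluation.

All four metrics operate on aligned sample sequences: Pearson correlation
(Corr), mean squared error (MSE), percentage root-mean-square difference
(PRD), and SNR improvement (SNR_imp) in dB — the ratio of input-noise energy
to residual-noise energy after denoising.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .signals import Signal

__all__ = ["MetricsReport", "corr", "mse", "prd", "snr_imp", "evaluate_denoising"]


def _pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x.samples if isinstance(x, Signal) else x, dtype=float).ravel()
    y = np.asarray(y.samples if isinstance(y, Signal) else y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    return x, y


def corr(x, y) -> float:
    """Pearson correlation coefficient; errors on constant inputs."""
    x, y = _pair(x, y)
    if x.size < 2:
        raise ValueError("correlation needs at least 2 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant sequence")
    return float(np.corrcoef(x, y)[0, 1])


def mse(x, y) -> float:
    """Mean of squared differences."""
    x, y = _pair(x, y)
    if x.size == 0:
        raise ValueError("empty sequences")
    return float(np.mean((x - y) ** 2))


def prd(x, y) -> float:
    """Percentage RMS difference, ``100 * sqrt(sum (x-y)^2 / sum x^2)``."""
    x, y = _pair(x, y)
    denom = float(np.sum(x * x))
    if denom == 0:
        raise ValueError("PRD undefined for an all-zero reference")
    return float(100.0 * np.sqrt(np.sum((x - y) ** 2) / denom))


def snr_imp(x, x_noisy, y) -> float:
    """SNR improvement in dB: ``10 log10(||x_noisy - x||^2 / ||y - x||^2)``.

    Positive when denoising helped.  Perfect denoising (zero residual) yields
    ``+inf`` with a warning.
    """
    x, x_noisy = _pair(x, x_noisy)
    _, y = _pair(x, y)
    num = float(np.sum((x_noisy - x) ** 2))
    den = float(np.sum((y - x) ** 2))
    if num == 0:
        raise ValueError("SNR improvement undefined when the noisy input equals the reference")
    if den == 0:
        warnings.warn("zero residual noise; SNR improvement is infinite")
        return math.inf
    return float(10.0 * np.log10(num / den))


@dataclass(frozen=True)
class MetricsReport:
    """Corr/MSE/PRD/SNR_imp for one (clean, noisy, denoised) triple."""

    corr: float
    mse: float
    prd: float
    snr_imp: float
    n: int

    def __post_init__(self):
        if self.mse < 0 or self.prd < 0:
            raise ValueError("mse and prd must be nonnegative")
        if abs(self.corr) > 1 + 1e-12:
            raise ValueError("correlation out of range")

    def as_dict(self) -> dict:
        return {"corr": self.corr, "mse": self.mse, "prd": self.prd,
                "snr_imp": self.snr_imp}


def evaluate_denoising(clean, noisy, denoised) -> MetricsReport:
    """All four metrics of a denoiser run against the clean reference.

    When the noisy input equals the reference exactly there is no input noise
    to improve on and ``snr_imp`` is reported as NaN.
    """
    x, y = _pair(clean, denoised)
    try:
        improvement = snr_imp(clean, noisy, denoised)
    except ValueError:
        improvement = math.nan
    return MetricsReport(
        corr=corr(clean, denoised),
        mse=mse(clean, denoised),
        prd=prd(clean, denoised),
        snr_imp=improvement,
        n=x.size,
    )
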