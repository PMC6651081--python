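# Methods

## The model

A noisy single-lead ECG record is modelled as an additive mixture
`x(t) = c(t) + m(t)` of a clean cardiac signal `c(t)` and a motion artifact
`m(t)`. The working assumption — which holds for electrode-motion,
muscle-tension and respiration interference — is spectral: the artifact's
energy concentrates below roughly 1 Hz, while the diagnostically relevant
P-QRS-T content lives above it. The method is therefore a *data-adaptive
band separation followed by in-band denoising*, not a generic smoother: it
promises to leave everything above the separating boundary untouched.

### Empirical wavelet transform

Given the FFT magnitude spectrum on the normalized frequency axis `[0, π]`,
boundaries are placed at midpoints between consecutive retained local
maxima. The Meyer-type filters on a boundary set `0 < Λ₁ < … < Λ_K < π` use
transition half-widths `τ = γΛ`; writing `β(u) = u⁴(35 − 84u + 70u² − 20u³)`
(the standard Meyer taper, with `β(u) + β(1−u) = 1`):

- scaling filter: `Φ(ω) = 1` for `|ω| ≤ (1−γ)Λ₁`, a `cos(π/2·β(·))` roll-off
  across the transition band, `0` beyond `(1+γ)Λ₁`;
- wavelet `Ψₙ`: a matching `sin` edge at `Λₙ` and `cos` edge at `Λₙ₊₁`; the
  last wavelet extends flat to `π` (a high-pass).

Because `cos² + sin²` edges meet at identical taper arguments, the squared
filter responses sum to one everywhere as long as transition bands do not
overlap. `γ = "auto"` uses 0.9 × the largest overlap-free ratio
`min (Λₙ₊₁ − Λₙ)/(Λₙ₊₁ + Λₙ)` (the pair `(Λ_K, π)` included). The partition
of unity makes the frame tight, hence exactly invertible; the test suite
checks `Φ² + ΣΨₙ² = 1` to 1e−10 and round-trip reconstruction to 1e−8
relative L2 on random banks and signals of odd, even and power-of-two
lengths (observed errors are at machine precision, ~1e−15).

Coefficients are computed as spectral multiplications `cₙ = F⁻¹[X·Ψₙ]`
(real by filter symmetry) and each time-domain mode is the coefficient
sequence filtered once more, `fₙ = F⁻¹[X·Ψₙ²]`, so modes sum to the input
exactly. Filters are built on the exact FFT grid of the input — no padding,
since padding would shift boundary bins; the DC bin always belongs to the
scaling filter.

### Boundary detection

Raw ECG spectra are jagged, so the magnitude spectrum is smoothed by a
centred moving average (window `len(spectrum)/100`, minimum 3 bins, forced
odd; configurable) before peak-picking. A bin is a local maximum if strictly
greater than both neighbours; plateaus count once at their leftmost bin.
Maxima are ranked by smoothed magnitude, the top `n_segments` are re-sorted
by frequency, and midpoints between consecutive ones become boundaries.
Boundaries below `min_boundary_hz` (default 0.3 Hz) are discarded and their
segments merged: a split *inside* the artifact band separates nothing.
If the spectrum has fewer interior maxima than needed, the detector falls
back to an equal-energy segmentation and flags it (`method="equal_energy"`)
rather than failing. A fixed boundary list (e.g. `[1.0]` Hz) bypasses
detection entirely; adaptive detection re-derives boundaries per record.

### Threshold selection

`estimate_sigma` is the Gaussian MAD estimator `median(|d|)/0.6745`.
For `heursure` the coefficients are normalized by σ and the sparsity
statistic `α = (Σxᵢ² − N)/N` is compared against
`β = (log₂N)^{3/2}/√N`: sparse vectors (`α < β`) get the universal
threshold `σ√(2 ln N)` — SURE is unreliable there — while dense vectors get
`min(universal, SURE minimiser)`. The SURE risk of candidate `t` is
`N − 2·#{|xᵢ| ≤ t} + Σ min(xᵢ², t²)`, scanned over the sorted absolute
coefficients; the implementation uses the algebraically identical
cumulative-sum form and is pinned against a brute-force scan in the tests.
The criterion exponent 3/2 and the `1/√N` scaling are the standard form of
this rule; with a `1/N` scaling the rule would misclassify roughly a
quarter of pure-noise vectors at N = 1024, contradicting its purpose.
`sqtwolog`, `rigrsure`, `minimaxi` and `none` (threshold 0 everywhere,
useful to verify transparency) are also provided.

### The pipeline and its two denoising configurations

The full pipeline thresholds the *coefficient sequence* of the
noise-dominant mode(s) (default: the approximation mode only) and
reconstructs through the inverse frame. Re-applying the band filter after
thresholding keeps the output band-limited, which is what guarantees the
spectral contract: above `(1+γ)·Λ₁` the output spectrum equals the input
spectrum to machine precision. For the tight frame this reconstruction is
identical to summing the re-filtered denoised mode with the untouched
modes — both paths are implemented and tested for equality.

Two deliberately different wavelet configurations exist:

- **Generic `wavelet_denoise` (and the DWT baseline):** `sym8`, depth
  `min(4, maximum usable)`, soft heursure thresholds per detail level, noise
  scale from the finest detail level, approximation untouched. This is the
  conventional additive-white-noise setup and is what a practitioner means
  by "DWT denoising" of a whole record.
- **Noise-mode denoising inside the pipeline:** maximum usable depth,
  *per-level* noise scale, and the approximation coefficients thresholded
  too. The noise-dominant mode is coloured and noise-dominated in every
  band: a finest-level σ estimate would be near zero (the mode has no
  high-frequency content, so nothing would be removed), and at shallow
  depth the whole artifact would hide inside the untouched approximation.
  Estimating σ per level treats each band's own coefficient scale as the
  noise level, which is exactly right for a mode that is noise by
  construction, and thresholding the deep approximation removes the slow
  baseline component as well.

A consequence visible in the simulation study: on the synthetic battery the
EWT-only variant (discard the noise mode outright) can edge out the full
pipeline in mean SNR improvement, because the synthetic noise mode contains
almost no recoverable ECG and any thresholding residue is pure artifact. On
real records, where QRS energy leaks into the low band, retaining the
thresholded mode is what preserves R-peak morphology — that benefit is
outside what this generator emulates. Similarly, the DWT baseline's
improvement on the battery is ≈ 0 dB: the mixtures contain no white
high-frequency noise for it to remove, and the sub-1 Hz artifact sits in
its untouched approximation band. The battery reproduces the *ordering*
(EWT-based methods ≥ DWT), not any absolute baseline performance.

## Synthetic study conditions

The generator emulates the standard simulation protocol for this problem:
clean records at the MIT-BIH sampling rate, artifact noise added at a
chosen SNR.

- **Clean ECG** (`make_clean_ecg`): per beat, five Gaussian bumps
  (P 0.15 / −200 ms / 25 ms; Q −0.10 / −30 ms / 10 ms; R 1.0 / 0 / 11 ms;
  S −0.12 / +30 ms / 10 ms; T 0.35 / +220 ms / 55 ms — amplitude relative
  to R, offset from the R peak, Gaussian width), beat-to-beat intervals
  jittered by a 5% variability fraction, zero-meaned and peak-normalized.
  Defaults: 360 Hz, 30 s, 72 bpm. Under 0.1% of its energy lies below
  0.67 Hz and under 2% below 1.2 Hz, matching the premise that clean ECG
  has negligible sub-1 Hz content.
- **Motion artifact** (`make_motion_artifact`): zero-phase 4th-order
  Butterworth band-pass (0.05–0.8 Hz) of white Gaussian noise plus a
  detrended, low-passed random-walk baseline, normalized to unit variance;
  ≈ 99% of its energy lies below 1 Hz. This matches the sub-1 Hz
  concentration of electrode-motion noise, not any specific recording
  sample-for-sample.
- **Mixing** (`mix_at_snr`): the noise is rescaled so
  `10·log₁₀(Σc²/Σm²)` equals the requested SNR exactly (`+inf` is the
  noise-free sentinel). Default study condition: 0 dB.

Each seeded draw is fully deterministic (NumPy `default_rng` with derived
streams for ECG and noise). Because the generator's artifact is Gaussian
within its band, wavelet thresholding of the noise mode removes it almost
completely; real motion artifacts have impulsive, non-Gaussian segments
that survive thresholding more often. Passing tests therefore demonstrate
the mechanism and the orderings, not clinical-grade performance bounds.

## Numerical choices and degenerate inputs

- Boundary handling for the DWT: symmetric (half-sample) extension,
  reconstruction trimmed to the input length — pinned for reproducibility.
- `σ = 0` with nonzero coefficients returns threshold 0 with a degeneracy
  flag and a warning rather than failing.
- Ties in peak-picking resolve to the leftmost plateau bin; SURE candidate
  ties resolve to the first minimum of the risk scan.
- Constant signals have undefined correlation and raise; identical
  noisy/reference pairs make SNR improvement undefined (reported as NaN by
  the aggregate evaluator, an error from the bare metric).
- The pipeline requires ≥ 64 samples; fixed boundaries must lie below the
  Nyquist frequency; gamma values that would overlap transition bands name
  the offending boundary pair in the error.

## Problem sizes

The test suite and `scripts/acceptance.py` use 30 s records at 360 Hz
(10 800 samples), 20 seeds for the simulation study, 50 random banks for
the frame checks and 100 vectors for the threshold oracle — sizes at which
every property under test is already asymptotically stable; the whole suite
runs in a few seconds.

## Known limitations

- Whole-record processing only; no windowed/streaming mode.
- Single-channel; no multi-lead fusion or QRS annotation.
- The heursure criterion is the standard form; printed variants of the rule
  differ in typesetting across the literature, and the tests pin this
  package's form rather than claiming bit-equivalence with any other
  implementation.
- Only the local-maxima/midpoint segmentation rule is provided (no
  scale-space or histogram variants).
- WFDB/PhysioNet input is not built in; users with such data can convert
  records to CSV for the CLI or pass arrays directly to the library.
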