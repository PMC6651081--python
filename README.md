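# ewtwt — motion-artifact removal for ECG signals

Electrocardiograms recorded by wearable and non-contact (capacitively
coupled) monitoring systems are routinely contaminated by **motion
artifacts** — low-frequency interference from electrode movement, muscle
activity and breathing, with spectral energy concentrated below about 1 Hz,
right underneath the clinically useful P-QRS-T content (roughly 1–40 Hz).
`ewtwt` removes such artifacts with an adaptive two-stage method:

1. **Empirical wavelet transform (EWT).** The Fourier magnitude spectrum of
   the noisy record is segmented at data-driven boundaries: local maxima of
   the (smoothed) spectrum are ranked by magnitude and the midpoints
   `Λᵢ = (ωᵢ + ωᵢ₊₁)/2` between consecutive retained maxima become segment
   boundaries. A Meyer-type tight-frame filter bank — one scaling (low-pass)
   filter `Φ` and band-pass wavelets `Ψₙ`, with transition half-width
   `τₙ = γ·ωₙ` — is built on these segments, so that
   `Φ(ω)² + Σₙ Ψₙ(ω)² = 1` on the whole grid and the decomposition is
   perfectly invertible. The lowest-frequency (approximation) mode captures
   the artifact; the detail modes carry the ECG.
2. **Wavelet thresholding (WT).** The noise-dominant mode is denoised by
   multilevel discrete-wavelet thresholding with the *heursure* rule: the
   universal threshold `σ√(2 ln N)` when the sparsity statistic
   `α = (Σxᵢ² − N)/N` falls below `(log₂N)^{3/2}/√N`, otherwise the
   minimiser of Stein's unbiased risk estimate. The signal is then rebuilt
   through the inverse frame, so everything above the boundary band passes
   through untouched.

Denoising quality is quantified by four standard metrics: Pearson
correlation (Corr), mean squared error (MSE), percentage RMS difference
(PRD) and SNR improvement (SNR_imp, dB). A synthetic generator produces
clean P-QRS-T waveforms and band-limited artifact noise mixed at an exact
target SNR, so the whole method is testable without downloading any data.

## Worked example

```python
import ewtwt as ew

# a 30 s, 360 Hz synthetic ECG mixed with sub-1 Hz artifact noise at 0 dB
spec = ew.SyntheticSpec(fs=360.0, duration_s=30.0, target_snr_db=0.0, seed=1)
clean, noisy, _ = ew.make_noisy_pair(spec)

result = ew.ewt_wt_denoise(noisy, boundaries_hz=[1.0])
report = ew.evaluate_denoising(clean, noisy, result.denoised)
print(f"corr {report.corr:.3f}  prd {report.prd:.1f}%  snr_imp {report.snr_imp:.1f} dB")
print(f"noisy corr {ew.corr(noisy, clean):.3f}")
```

prints

```
corr 0.992  prd 12.6%  snr_imp 18.0 dB
noisy corr 0.718
```

i.e. with the spectral boundary fixed at 1.0 Hz the pipeline removes enough
of the artifact to raise the correlation with the clean reference from 0.72
to 0.99 and improve the SNR by 18 dB, while distorting the retained ECG by
only 12.6% RMS. `result` also records the detected/used boundaries, the
extracted modes, the threshold decisions and full provenance. Omitting
`boundaries_hz` enables adaptive boundary detection; `run_comparison`
benchmarks the pipeline against discarding the noise mode outright (`ewt`)
and a full-signal DWT-thresholding baseline (`dwt`).

The estimators compose with scikit-learn:

```python
den = ew.EWTWTDenoiser(fs=360.0, boundaries_hz=[1.0])
y = den.fit_transform(noisy.samples)   # 1-D denoised samples
```

And the same pipeline is available from the shell:

```bash
ewtwt simulate --fs 360 --duration 30 --snr 0 --seed 42 \
    --out-clean clean.csv --out-noisy noisy.csv
ewtwt denoise --input noisy.csv --boundary 1.0 --output denoised.csv \
    --json-report report.json
ewtwt evaluate --clean clean.csv --noisy noisy.csv --denoised denoised.csv
```

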