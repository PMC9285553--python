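# dtiphantom

Multicentre diffusion-phantom quality assurance for cardiac DTI sequences:
a synthetic multi-tube PVP phantom DWI generator, log-linear diffusion
tensor estimation, and the complete accuracy / precision / repeatability /
reproducibility statistics stack used to compare pulse sequences across
imaging sites.

## Who this is for

Groups validating diffusion MRI protocols — in particular
motion-compensated spin-echo (SE) and stimulated-echo (STEAM) sequences for
cardiac DTI — against a product pulsed-gradient spin-echo (PGSE) reference,
using an isotropic ice-water phantom with tubes of 0–20%
polyvinylpyrrolidone (PVP). The package simulates such a study end to end
with known ground truth, and runs the same central analysis on the
simulated (or any NIfTI + FSL `.bval`/`.bvec`) data, so every statistic in
the QA report can be checked against what was injected.

## The model and statistics

**Signal model.** Each tube is an isotropic Gaussian diffusion standard:
S = S₀ · exp(−b ĝᵀD ĝ) with D = MD·I. The acquisition follows the
standardised protocol: one low-b volume (b_low 0–76 s/mm² depending on
sequence) plus six icosahedral directions at b = 100, 300, 450 s/mm², 30
repetitions, two scans per site. Magnitude noise is Rician,
√((S+n₁)² + n₂²), calibrated so the temporal SNR definition below hits a
requested target.

**Tensor fit.** Voxel-wise ordinary least squares of ln S against the
b-matrix elements over all repetitions jointly (no prior averaging), then
eigen-decomposition λ₁ ≥ λ₂ ≥ λ₃ with

- MD = (λ₁ + λ₂ + λ₃)/3
- FA = √(½) · √[((λ₁−λ₂)² + (λ₁−λ₃)² + (λ₂−λ₃)²) / (λ₁² + λ₂² + λ₃²)]

Eigenvalues are not clamped; non-positive signals are excluded per voxel.

**QA statistics.**

- accuracy ∂ⱼₖ = (M̄Dⱼₖ − M̄D_ref,ⱼ)/M̄D_ref,ⱼ × 100%, against either the
  water reference D_ref (quadratic extrapolation of literature
  self-diffusion data to 0 °C) or the PGSE cross-site consensus;
- precision CV_ROI = σ/μ × 100% across ROI voxels of scan 1;
- SNR = temporal mean/SD over repetitions of the direction-averaged
  b = 100 s/mm² images;
- drift = last − first of the 5-repetition moving average of the
  per-repetition MD series; stability = SD across repetitions;
- RMSD between scans per b-value combination, with the minimum-RMSD
  combination selected for reconstruction;
- Bland–Altman mean difference and 95% limits of agreement (±1.96 SD),
  bootstrap (1000 resamples, percentile 95% CI) of between-scan
  differences;
- grouped CV of MD across scans, across sites per sequence group, and
  across sequence pairs;
- one-sample t, Shapiro–Wilk, Welch t and Wilcoxon rank-sum tests (exact
  midrank enumeration for combined n ≤ 20).

## Worked example

```python
import numpy as np
from dtiphantom import (NoiseModel, add_rician_noise, default_layout,
                        fit_tensor_lls, protocol_scheme, select_bvalues,
                        simulate_signal, snr_map, tube_masks)
from dtiphantom.qa import snr_roi_mean

layout = default_layout(grid_shape=(48, 48, 1))        # 7 tubes, 0-20% PVP
stack = simulate_signal(layout, protocol_scheme(0.0, 30))
mask = tube_masks(layout)[1]                           # tube 1 = pure water
noisy = add_rician_noise(stack, NoiseModel("rician", 20.0, seed=0),
                         reference_mask=mask)
print(round(snr_roi_mean(snr_map(noisy), mask), 1))    # 20.9
field = fit_tensor_lls(select_bvalues(noisy, (100, 450)), roi_mask=mask)
md = np.nanmean(field.md[mask & field.valid])
print(f"{md * 1e3:.3f}")                               # 1.120
```

The measured SNR (20.9) matches the requested level, and the fitted tube-1
MD (1.120 × 10⁻³ mm²/s) sits within 0.4% of the 1.124 × 10⁻³ mm²/s ground
truth — the Rician noise floor is negligible at this SNR.

The `examples/` directory holds one short script per capability (phantom
and protocol construction, tensor fitting, noise/SNR behaviour, the water
reference, a full multicentre study, and the b-value-combination sweep);
each prints the numbers it computes and a line on how to read them.

A thin CLI wraps the same pipeline for on-disk studies:

```bash
dtiphantom simulate --out study/ --seed 1          # NIfTI + bval/bvec + manifest
dtiphantom analyse --study study/ --out results/   # QA tables, report
dtiphantom report --qatable results/qatable.csv
```

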