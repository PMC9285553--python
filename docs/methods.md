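# Methods

## The problem

Multicentre validation of diffusion MRI sequences rests on scanning a
standardised, temperature-controlled isotropic phantom at every site and
comparing the recovered mean diffusivity (MD) against known references.
This package implements that workflow twice over: a synthetic generator
that produces diffusion-weighted stacks with the statistical structure such
a study assumes (so the pipeline can be validated against injected ground
truth), and the central analysis itself (tensor fitting plus the accuracy,
precision, repeatability and reproducibility statistics).

## Phantom and forward model

The default phantom is seven 50-ml tubes of aqueous polyvinylpyrrolidone
(PVP) at 0, 2.5, 5, 7.5, 10, 15 and 20% w/v, standing vertically in an
ice-water bath at 0 °C. Tube 1 (pure water) has an external gold standard:
the self-diffusion coefficient of water. The PVP tubes have no independent
ground truth; their default diffusivities are the cross-site product-sequence
consensus values, (1.124, 1.046, 0.953, 0.899, 0.839, 0.713, 0.607) × 10⁻³
mm²/s, with the 1.113 × 10⁻³ mm²/s water value available as an alternative
for tube 1.

Signals follow the monoexponential tensor model S = S₀·exp(−b ĝᵀDĝ). The
tubes are isotropic (D = MD·I) by default; an axially symmetric tensor
with prescribed MD and FA (principal axis along the tube axis, z) is
available for anisotropy experiments. Voxel membership is by voxel-centre
inclusion in the tube circle — no sub-voxel partial-volume mixing, which is
acceptable because the analysis ROIs stay well inside the tube edge. S₀ is
flat (1000 a.u.) across tubes; a per-tube override exists as a hook for
relaxation-weighting experiments but is not used by default, since T1/T2
differences between PVP concentrations are outside this package's scope.

The acquisition scheme is the standardised protocol: per repetition, one
low-b volume plus six icosahedral directions — the printed set
[0.5257, 0.8507, 0] etc., renormalised to unit length because the printed
values have norm ≈ 1.00004 and the b-matrix trace must equal the nominal
b-value — at shells b = 100, 300, 450 s/mm², repeated 30 times (570
volumes). The low-b value is sequence-dependent (0 for the product PGSE
protocol, 2–5 s/mm² for motion-compensated SE, 16–76 s/mm² for STEAM,
whose crushers and long diffusion times impose substantial residual
weighting). Low-b volumes carry the placeholder direction (0, 0, 1); for
isotropic media the choice is immaterial, and users analysing real
scanner data should check their vendor's convention.

## Noise model and SNR calibration

Magnitude noise is Rician: each value S becomes √((S+n₁)² + n₂²) with n₁,
n₂ i.i.d. zero-mean Gaussians of scale σ. The QA pipeline defines SNR
temporally: the six b = 100 s/mm² direction images of each repetition are
averaged, and SNR is the mean over repetitions divided by the sample SD
over repetitions of that average. Averaging six independent images divides
the noise SD by √6, so the generator calibrates σ = √6 · S_ref / SNR_target,
with S_ref the mean noise-free b = 100 signal in tube 1. `target_snr` is
therefore the SNR the pipeline will *measure* (verified to within ~5% in
tests), not the per-image ratio. Default targets are the sequence-group
levels 23.3 (PGSE), 19.9 (SE) and 20.8 (STEAM).

At these levels the log-domain tensor fit keeps MD nearly unbiased (the
leading-order Rician bias cancels in ln S; measured tube-1 bias < 0.4% at
SNR 20 over 30 repetitions), while FA acquires the familiar positive bias
that grows monotonically as SNR falls. At very low SNR (≤ 2) the noise
floor flattens the decay and MD is biased low.

## Study design and site effects

A study is a set of (site, sequence, scan) arms. Each physical site
scans the product PGSE sequence plus one custom sequence, so arms are keyed
by the (site, sequence) pair; scans 1 and 2 are generated with independent
noise. The default design mirrors a ten-site study: ten PGSE arms, five SE
arms (low-b 5, 2, 2, 0, 5 s/mm²) and five STEAM arms (low-b 42, 76, 39, 20,
16 s/mm²), STEAM arms single-slice (multislice stimulated-echo imaging was
not generally available), others three slices of 8 mm at 2.5 mm in-plane
on a 48 × 48 grid.

Systematic site effects are injected multiplicatively on the true
diffusivities: a per-arm MD bias (default drawn N(0, 2%) — the scale of
reported intersite CVs), a scan-2 shift (default N(0, 1%), matching ~1%
interscan CV), and an optional per-repetition signal drift applied as
(1 + d)^(rep−1) to all volumes of a repetition. Note that a drift common to
all volumes of a repetition is absorbed almost entirely by the fitted S₀;
a drift that affects only the diffusion-weighted volumes (instability of
the DW signal relative to the low-b anchor) is what shows up as an MD
trend, and with DW signal *loss* the apparent MD trends upward. Per-arm
random streams derive deterministically from the master seed via
`numpy.random.SeedSequence([seed, arm_index, scan])`.

What the generator deliberately does not emulate: Gibbs ringing, EPI
distortion, SENSE unfolding, concomitant-field shading, gradient
miscalibration, vibration and convection, relaxation differences between
tubes, and motion. Passing tests on synthetic data therefore demonstrate
the correctness of the estimators and statistics, not robustness to those
real-world artifacts; on real data the ROI radius (below) and the low-b
exclusion are the main defences.

## Segmentation

ROIs are circles of fixed radius around each tube centre, on all selected
slices. The default radius is 8 mm — inside a ~13 mm tube radius, excluding
the edge band where ringing dominates in real data; the radius is a free
parameter and results should be reported alongside it. Centres come from
the study config / layout, or are detected from the mean low-b image (Otsu
threshold, connected components, intensity centroids, optimal assignment to
expected positions). ROIs must be pairwise disjoint; centres closer than
twice the radius are rejected outright. The voxel containing each centre is
always included so ROIs are never empty.

## Tensor estimation

Ordinary (unweighted) least squares of ln S on
[1, −b_xx, −b_yy, −b_zz, −2b_xy, −2b_xz, −2b_yz] per voxel, using all
repetitions jointly without prior averaging. Non-positive signals cannot
enter the log and are dropped per voxel; voxels with fewer than 7 usable
measurements (or a rank-deficient reduced design) are marked invalid and
carry NaN metrics. Eigenvalues are sorted descending and *not* clamped at
zero: MD and FA are computed from the raw eigenvalues, so noisy voxels can
show FA > 1 — this matches the direct-fit convention and is documented for
users comparing against clamped pipelines. Degenerate all-zero voxels are
invalid rather than FA = 0/0.

b-value subsets for reconstruction are selected by exact b-value match
(the label `b_low` resolves to the scheme's low-b value); subsets leaving
fewer than 7 volumes per repetition are rejected as under-determined.

## QA statistics

All SDs are sample SDs (n−1); this convention is applied uniformly since
the source definitions do not specify it. Accuracy is
(M̄D − M̄D_ref)/M̄D_ref × 100% with M̄D averaged across the ROI and both
scans; the reference is either the water D_ref (tube 1) or the per-tube
PGSE consensus (mean across PGSE sites and both scans). Precision is the
within-ROI CV of scan 1. Drift smooths the per-repetition series with a
5-repetition moving average using valid windows only (no edge padding, so
"final minus initial" needs no extrapolation) and reports last − first,
absolutely and as % of the first value. The temporal SNR definition is
given above; noise-free data have zero temporal SD and are flagged
infinite, excluded from ROI means.

The b-combination sweep refits tensors for the seven candidate
combinations (b_low with each shell, the three shell pairs, and all four),
takes the tube-1 ROI-mean MD per scan and site, and computes the RMSD
between scan-1 and scan-2 values across sites. Exactly one combination is
selected: minimum RMSD, with ties resolved first *away from
low-b-containing combinations* (the low-b data are the unreliable ones —
crusher-dependent b_low and shading artifacts — which is the reason the
sweep exists) and then towards the larger b-value range. A pure
largest-range rule would prefer (b_low, …, 450) over (100, 450) whenever
b_low = 0 and RMSDs tie, which inverts the intent.

The equilibration check implements the scout rule: consecutive scout-scan
ADC means must agree within 3% (last vs previous).

## Agreement statistics

Bland–Altman operates on per-(site, tube) ROI means (scan 2 − scan 1), one
point per site — not per voxel — with limits of agreement mean ± 1.96 SD
and an OLS regression of difference on pair average as the
proportional-bias check (R² is NaN for degenerate inputs). The bootstrap
resamples the differences with replacement at original size (default 1000
resamples), takes the mean of each resample, and reports the median and
percentile 2.5/97.5 CI (no BCa correction — none is specified by the
definitions this mirrors); two results are "significantly different" iff
their 95% CIs are disjoint, a deliberately conservative rule (measured
type-I error well below 5%). Bootstraps are computed per (sequence, tube);
pooling across tubes is possible by concatenating differences.

Grouped CVs of MD (ROI- and scan-averaged unless the grouping is over
scans): across scans per (site, sequence, tube) then averaged; across
sites per (sequence, tube) then averaged over tubes; across sequence pairs
per (site, tube) where a site has both sequences. For the SE-vs-STEAM pair
no site has both, so the CV is computed over the pooled site values of
either sequence — a combined intersite/intersequence CV, which is how that
comparison is defined in this design. Groups with fewer than two members
are skipped with a warning. No multiple-testing correction is applied
anywhere (fixed α = 0.05), stated here explicitly.

The rank-sum test uses midranks for ties and enumerates the full
permutation distribution when the combined sample size is ≤ 20 (C(20,10) ≈
1.8 × 10⁵ assignments; two-sided p as the fraction of assignments at least
as extreme as observed). Larger samples use the normal approximation with
tie-corrected variance. Welch's t-test uses Welch–Satterthwaite degrees of
freedom.

## Water reference

D_ref comes from a second-order polynomial fit D(T) = c₀ + c₁T + c₂T² to
the Mills (1973) tracer measurements of water self-diffusion (1–45 °C),
shipped as a citable CSV fixture and converted from 10⁻⁹ m²/s to mm²/s on
load; the 0 °C value is always computed from the fit, never hard-coded.
The fit over the full table gives D(0 °C) = 1.1102 × 10⁻³ mm²/s, within
0.25% of the commonly quoted 1.113 × 10⁻³ mm²/s (which temperatures were
fitted for that value is not recorded, hence the 0.5% test tolerance). The
fit's fractional sensitivity at 0 °C is ≈ 3.5%/°C; claims of ~5%/°C
circulate in the QA literature, but neither the Mills data (local slope
1→5 °C ≈ 3.6%/°C) nor the Speedy–Angell parameterisation of supercooled
water supports a value that high, so this package reports the computed
3.5%/°C. Either way the steep slope is why the ice bath and the 3%
equilibration rule matter. Evaluation more than 5 °C outside the fitted
range warns.

## Numerical choices and problem sizes

Voxel grids are (x, y, z) with mm coordinates from the grid corner and
voxel centres at (i + 0.5)·voxel size. Batched voxels sharing a full
design matrix are solved with one `lstsq`; voxels with excluded
measurements fall back to per-voxel solves. Eigen-decomposition uses
`eigvalsh` (symmetric input by construction). Tests and the acceptance
script run the study at a single slice per arm (the statistics operate on
ROI means, which a second slice would only replicate) with the full 570
volumes and all ten sites; the default API grid is 48 × 48 × 3. Bootstrap
and simulation seeds are explicit everywhere; identical inputs and seeds
give identical outputs end to end.

## Known limitations

- No artifact physics (see the generator section): the synthetic study is
  a best case for ROI homogeneity statistics.
- The FA of the phantom is identically zero, so CV of FA is unstable and
  deliberately not part of the grouped-CV report.
- The rank-sum enumeration is O(C(n, n₁)) and intended for the small group
  sizes of site comparisons.
- Accuracy against the PVP tubes is relative to a consensus, not an
  independent physical ground truth; only tube 1 has one.
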