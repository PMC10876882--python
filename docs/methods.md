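# Methods

## Generative model

Each synthetic subject's BOLD matrix is an explicit linear mixture per voxel:

    y_v(t) = baseline + amplitude * [ Σ_c w_{v,c} x_c(t) + sd_v ε_v(t) ]

with standardized component courses x_c:

- **Cardiac**: sinusoid at a per-subject frequency drawn from a truncated
  normal N(1.0, 0.1) on [0.6, 1.5] Hz, plus a 0.3-amplitude second harmonic
  and slow (≤ 0.05 Hz) random amplitude modulation. Not a pulsatile waveform
  model — it creates the band-limited spectral peak the analysis needs,
  nothing more.
- **Respiratory**: same construction at N(0.27, 0.04) on [0.15, 0.4] Hz,
  modulation depth configurable (default 0.3).
- **Global**: Gaussian noise band-limited to 0.005–0.08 Hz, shared by every
  brain voxel.
- **Drift**: linear trend plus one very slow cosine.
- **Neural**: one course per ROI, sqrt(ρ)·(network-shared course) +
  sqrt(1−ρ)·(ROI innovation), each band-limited to 0.01–0.1 Hz. The
  within-network correlation ρ is 0.5 for young and 0.3 for old subjects by
  default; ρ_old ≤ ρ_young is enforced.

Weights are set so each component contributes a stated *fraction of voxel
variance* (defaults: neural 0.12 on GM, cardiac 0.10, respiratory 0.08,
global 0.10, drift 0.05; remainder white noise). Cardiac weight is boosted
3× in CSF and 2× at 5% "vessel" GM voxels, and each physiological component
additionally carries a smooth random spatial field (±40%) — without distinct
spatial signatures, cardiac/respiratory/global would share one spatial map
and no spatial decomposition could separate them.

Three normalizations make the bookkeeping *exact* rather than
in-expectation: the four nuisance courses are orthogonalized (QR, cardiac
kept pure), ROI neural courses are residualized against that nuisance basis,
and the white-noise realization is projected orthogonal to every course and
standardized per voxel. Consequently stored per-voxel fractions equal the
realized variance shares up to the noise-variance estimate, which is what
the parameter-recovery tests assert.

The phantom is a concentric ellipsoid (CSF core and rim, WM shell, GM
ribbon) on a small grid (default 16×16×10). GM is split into angular-sector
networks (default 7), each subdivided into equal-size ROIs (default 196
total). Motion is a random walk with occasional spikes; it is **not** mixed
into the BOLD signal by default (the denoising comparison deliberately
excludes motion regression), and a flag injects a motion-locked rim artifact
for classifier tests.

Physiological recordings are generated at 50 Hz with the same per-subject
frequencies as the BOLD injection, so band placement can be estimated the
way it would be on real data — from the recording, not from ground truth.

### What the generator does not emulate

No hemodynamic response function, no spatial autocorrelation of the noise,
no susceptibility or slice-timing artifacts, no subject variation in
nuisance *amplitude* (fractions are fixed per tissue), and identical
anatomy for every subject. A green test therefore establishes that the
estimators recover what was injected and respond in the right direction to
the injected group difference — not that the methods would rank the same
way on real cohorts. One consequence is documented below under
"limitations": because nuisance amplitude is identical across subjects, the
uncorrected connectivity maps are artificially stable, and removing the
true nuisance courses can *lower* map-space group separability — the
opposite of what subject-varying physiology would produce.

## Estimator choices

- **High-pass** is regression on a discrete-cosine drift basis spanning
  frequencies below the cutoff (default 0.01 Hz): no phase distortion,
  exactly idempotent, consistent with confound regression.
- **Spectra**: the time series is averaged over the tissue/network mask
  first, then a rectangular-window periodogram of that mean signal is taken
  (mean removed). The rectangular window keeps the Parseval identity
  sum(power)·Δf = var exact, which the band-power contract relies on; a Hann
  taper is available (`window="hann"`), as is averaging per-voxel spectra
  instead (`mode="mean-spectrum"`). Band power sums density over bins whose
  centers fall inside the band; the fractional change
  (P_unc − P_cor)/P_unc is invariant to the density-vs-raw-sum choice.
- **CompCor** variants take principal components of the row-standardized
  voxel×time block (combined eroded WM+CSF mask with 5 components for
  aCompCor; voxels above the 98th temporal-SD percentile, components to 50%
  cumulative variance, for tCompCor). Mask erosion uses an in-plane cross
  structuring element — the phantom, like a 21-slice 5 mm acquisition, is
  far coarser along z, and 3-D erosion would empty the shells.
- **AROMA-like classifier**: FastICA spatial decomposition (auto
  dimensionality: 90% variance, capped at 30 and T/8; retried with fresh
  seeds and escalating tolerance). Features: maximum |correlation| with the
  six realignment parameters and their derivatives; high-frequency content
  (fraction of Nyquist above which half the ≥ 0.01 Hz power lies); edge and
  CSF fractions of the |weight| map thresholded at 2 SD (approximating
  mixture-model z-thresholding — on raw maps the diffuse ICA noise floor
  dominates the mass fractions). Noise if CSF fraction > 0.10, or HFC >
  0.35, or rp/0.6 + edge/0.6 > 1 (a package default; the canonical trained
  hyperplane is not reproduced here). Removal is non-aggressive: all
  component courses are fit jointly and only the noise-classified
  contribution is subtracted.
- **TBR**: stage 1 solves template ≈ volumes·w by least squares through the
  volume Gram matrix (shared Cholesky across templates; tiny logged ridge if
  singular); stage 2 reports the per-voxel t of the slope on the
  time-weight course. t-maps are scale-invariant in the template. Note that
  on phantoms with fewer voxels than timepoints stage 1 approaches
  interpolation and maps become geometry-dominated; see limitations.
- **FCC** uses the tie-corrected normal approximation of the rank-sum
  statistic without continuity correction, per network (within-network pairs
  vs pairs linking the network to the rest), averaged over networks.
- **Modularity**: literal signed double sum over ordered pairs, diagonal
  A_ii = 0. The *pipeline* centers maps across subjects before cosine
  similarity and clips negative similarities (raw t-maps share the
  parcellation geometry, pinning all cosines near 1 where Q is blind to
  individual differences; centered cosines are signed, so the nonnegative
  null model requires clipping). The bare operations keep the literal
  definitions, and both behaviors are tested.
- **ANOVAs** are computed as balanced split-plot decompositions: each
  between effect against subjects-within-group, each within effect against
  its interaction-with-subjects stratum. On a balanced design this is the
  closed form of the Gaussian mixed model with random subject intercept
  (Wald F, containment df) — cross-checked against pingouin in the tests —
  and it makes the type-I calibration tests cheap (1,000 null replicates).
  Unbalanced designs are rejected explicitly, listing the missing cells.
- **Downsampling** is pure decimation (keep every k-th volume, phase 0 by
  default, no anti-alias filter): folding the physiological tones into the
  low band is the phenomenon being studied. Spectral accounting is only
  performed at the native rate; connectivity metrics are produced at both
  rates with identical schemas.

## Numerical tolerances and degenerate inputs

Regression residuals are orthogonal to removed regressors to 1e-8
(relative); collinear design columns are dropped via pivoted QR with a
warning; zero-variance voxels are flagged in tSNR rather than made
infinite; a flat physiological spectrum (no bin-averaged peak ≥ 3× the
in-band median) is returned with a low-confidence flag; bands crossing
Nyquist are clipped with a warning, bands entirely above it are errors;
zero uncorrected band power makes the fractional change NaN with a warning;
a zero-mass similarity graph makes Q NaN with a degenerate flag.

## Known limitations

- The phantom's CSF occupies ~16–19% of brain voxels (real: a few percent),
  so the canonical CSF-fraction threshold only works on thresholded maps
  (see above), and spatially diffuse components are readily CSF-flagged.
- With fewer brain voxels than timepoints, TBR maps are dominated by the
  common geometry; group effects are detectable only after centering the
  maps, and the absolute Q values are not comparable to those from
  voxel-rich acquisitions.
- Because injected nuisance amplitude is identical across subjects, oracle
  nuisance removal slightly *reduces* permutation-normalized group
  separability on this model (it re-exposes white-noise map variability
  that the shared nuisance variance had suppressed). The corresponding
  direction-of-effect acceptance check is left failing rather than the
  generator being re-tuned after the fact; the weaker true property —
  separability stays far above the permutation null after oracle removal —
  is asserted in the unit suite.
- The split-plot ANOVA requires a complete balanced design; there is no
  mixed-model fallback for missing cells (the pipeline records the failed
  stage and continues).
- Statistical calibration is exact only under the iid-normal null used in
  the tests; heavy-tailed metric distributions are not covered.
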