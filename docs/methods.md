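# Methods

## Scope and model

The package quantifies two things from multi-channel fluorescence images
of immunostained brain tissue: (i) the areal density of synaptic puncta
and of bipartite synapses (pre/post colocalized puncta) in randomly
sampled fields, and (ii) the spatial distribution of postsynaptic density
around individual astrocyte cores. Raw cohort micrographs are not
distributable, so every stage is exercised against synthetic scenes with
exact ground truth; the synthetic generator is first-class, tested code
and defines the study conditions under which the pipeline's claims are
verified.

## Synthetic scenes

Puncta are isotropic 2D Gaussian spots with σ = radius/2, truncated at 3σ,
rendered onto `background_level` plus i.i.d. Gaussian noise plus sparse
large blobs (σ 1–2.5 µm at 40% punctum amplitude) that emulate residual
tissue autofluorescence. Placement is a homogeneous Poisson process per
channel; for domain scenes the postsynaptic rate is modulated by a
piecewise-linear radial profile around the core (realised by thinning at
the profile maximum, i.e. an exact inhomogeneous Poisson draw).
Colocalization is generated explicitly: a fraction `coloc_fraction` of
presynaptic puncta (exactly `round(f·N_pre)`) receives a postsynaptic
partner whose centroid is displaced by isotropic Gaussian jitter
(`coloc_jitter_um`, default 0.1 µm) and whose radius is drawn
independently, since the two markers are distinct proteins. The
postsynaptic channel's own Poisson rate adds *unmatched* puncta on top.

Ground truth (centroids, radii, matched pairs) is drawn from RNG streams
that are separate from the rendering streams, so it is bit-identical
across rendering settings, clipping and noise. Each channel uses a
substream keyed by a SHA-256 digest of its name and purpose, derived from
one master seed: channel-level reproducibility survives edits to the spec
list.

Defaults and why:

- `punctum_radius_um = 0.15` (SD 0.03): σ = 0.075 µm ⇒ FWHM ≈ 0.18 µm, a
  diffraction-limited confocal punctum.
- field 50 × 50 µm at 0.049 µm/px for synapse-counting fields; domain
  scenes default to 280 µm fields so that the full 17-bin layout
  (outermost bin edge at 133.5 µm from the core) lies inside the image;
  smaller fields are supported and exercise the clipping / missing-bin
  policy.
- `background_level = 500`, `noise_sd = 50`, `blob_density = 5·10⁻⁴/µm²`
  (16-bit scale): moderate SNR ≈ amplitude/noise = 160, chosen once as
  plausible for antigen-retrieved archival tissue; no published values
  exist for these nuisance levels, and the recovery tests are run both
  with and without them.
- Intensities clip at the 16-bit ceiling; the clipped fraction is logged
  and never alters ground truth.

What the generator does **not** emulate: 3D stacks and out-of-focus light,
bleaching, non-Gaussian PSF tails, spatially structured autofluorescence,
staining gradients, and segmentation-relevant astrocyte morphology (cores
are operator-provided coordinates, as in practice). Passing tests
therefore demonstrate correctness of the measurement pipeline under
idealized optics, not robustness to every tissue artifact.

## Preprocessing chain

Fixed order: background subtraction → bandpass → despeckle → sharpen →
threshold; tests pin the composition.

- Background: grey opening with a flat disk (the morphological reading of
  the rolling ball), radius default 50 px. For radii > 16 px the
  background is estimated on a block-mean-downscaled image and resized
  back (the ImageJ "shrink" convention); the interpolated estimate is
  clamped under the signal so the subtraction never goes negative.
- Bandpass: difference of Gaussians with σ = structure_size/2, pass band
  3–40 px by default.
- Despeckle: 3 × 3 median, reflecting boundaries.
- Sharpen: 3 × 3 kernel, centre 12 and neighbours −1, normalized by 4
  (sums to 1), clipped at 0.
- Threshold: Yen's maximum-correlation criterion on a 256-bin histogram of
  the min-max normalized image; the mask is strict `> threshold`
  (deterministic tie policy). A constant image raises.

Numeric settings of the original macro toolchain are not published, so all
of these are configuration with logged defaults; the test suite uses a
band of 2–20 px and a 25 px background radius at its 0.05 µm/px sampling,
i.e. the same physical scales at half the acquisition sampling density.

**Blank-field guard.** Yen's criterion assumes a bimodal histogram; on a
signal-free field it will split the noise distribution and mark several
percent of pixels as foreground. The chain therefore never lets the final
threshold fall below a noise floor: `noise_floor_sigmas` (default 5) times
the sharpening kernel's white-noise gain times the robust spread
(1.4826·MAD) of the bandpassed stage. On fields with real puncta the Yen
threshold sits one to two orders of magnitude above this floor, so the
guard only acts on (near-)blank inputs.

## Puncta detection and bipartite calling

Puncta are 8-connected components (the common particle-analyzer
convention, pinned by a flood-fill oracle test) with physical area inside
`[min_area_um2, max_area_um2]`; border-touching components are kept;
components whose centroid falls in the exclusion mask are dropped and the
excluded area leaves the density denominator. Defaults 0.05–2.0 µm²: the
lower bound admits a single diffraction-limited punctum (thresholded
footprint ≈ 0.07–0.13 µm²) while rejecting single-pixel residue; the
upper bound rejects somatic/vascular blobs. Both are logged on every run.

The overlap fraction of a presynaptic punctum is the share of its *own*
pixels that are postsynaptic foreground — the presynaptic area is the
denominator, which makes the presynaptic count an upper bound for the
bipartite count and the call monotone in the threshold. A pair is emitted
iff the fraction is ≥ θ (default 0.33, inclusive — a 100-px punctum with
exactly 33 px covered is called). Overlap is computed against the raw
postsynaptic mask by default; a flag restricts it to size-filtered
postsynaptic puncta instead. The best-overlapping postsynaptic punctum id
is attached for traceability (ties → lowest id).

Measured behaviour at the study conditions (λ = 0.4/µm², clean scenes,
0.05 µm/px): detected density recovers ~92% of truth; the missing ~7% is
dominated by true coincidence merging — two puncta closer than their
footprints fuse into one component, which is intrinsic to
connected-component detection and affects any particle-counting analysis
at this density.

## Domain layout and distributions

`build_bin_layout` places one 27 µm bin on the core and four bins per
outer class at the cardinal directions at centre-to-core distances
30/60/90/120 µm. Distances are bin-centre distances: this is the only
reading in which 27 µm bins nearly tile adjacent rings. Cardinal
placement keeps bins disjoint at these spacings; the angle set is
configurable (the source arrangement is not uniquely documented). Note a
212 µm field with a centred core cannot contain the cardinal out ring
(it needs 267 µm); such bins are flagged *missing* — not zero — and class
means average the available bins, avoiding a zero-bias at field edges.
The domain circle (radius 71 µm, half the ~142 µm literature diameter)
contains exactly the 9 center/close/mid bins, classified by bin centre.

Soma exclusion: a disc of `soma_radius_um` (default 7.5 µm, a typical
protoplasmic astrocyte soma; logged on every run) around the core is
excluded from both counts and denominators.

Bin densities use valid-area denominators (in-field, non-excluded pixel
area); the geometry-only fast path (`bin_densities_from_points`) computes
exact polygon areas (bin ∩ field − soma disc) with shapely and is used
for simulation studies where rendering/detection is not under test.

## Statistics

- Two-group comparisons are gated per sample by Shapiro-Wilk at α = 0.05;
  the parametric branch is the Welch (unequal-variance) t-test —
  consistent with choosing Games-Howell downstream — and the
  nonparametric branch is Mann-Whitney U (exact for n ≤ 20 without ties,
  normal approximation with tie correction otherwise).
- Holm-Sidak: step-down Sidak via statsmodels, monotone and capped at 1;
  the three-way p = 0.05 family adjusts its smallest member to
  1 − 0.95³ = 0.142625 (closed-form test).
- Two-way ANOVA: fixed effects with interaction, type-II F tests on
  `density ~ cohort × distance_class`, with a Brown-Forsythe Levene check
  (median-centred) across cohorts reported alongside.
- Games-Howell (authored here; cross-checked against an independent
  reference implementation in tests): per pair SE = √(s₁²/n₁ + s₂²/n₂),
  Welch-Satterthwaite df, T = |Δ|/SE, p = P(Q_{k,df} > T√2) from scipy's
  studentized-range distribution, CI = Δ ± q_{1−α;k,df}/√2 · SE. At k = 2
  it reproduces the Welch t-test p (identity used as an acceptance check);
  identical constant groups short-circuit to p = 1.
- Repeated-measures ANOVA: classical within-subject decomposition,
  F = MS_class/MS_error with df (k−1), (k−1)(n−1). Effect size
  ω² = df_t(MS_t − MS_e)/(SS_total + MS_subject); negative estimates are
  reported as computed (standard small-sample behaviour; the null mean is
  ~0). Post hoc: paired t over all class pairs, Holm-Sidak adjusted.
  Classes unmeasurable for some astrocyte (clipped rings) are dropped
  from the within-subject table with a logged warning.
- Trait correlations: Pearson R with two-sided p per diagnosis cohort and
  trait; the ordinal neuropil-thread grade (0–5) enters as numeric, with
  Spearman available behind a flag. Degenerate inputs (n < 3 or zero
  variance) yield NaN rather than a spurious coefficient.

Calibration: every test's type-I error at α = 0.05 is verified to lie in
[0.035, 0.065] over 2000 null replicates (normal data, assumptions met);
the two-way cohort p-value is additionally checked for null uniformity.

## Pipeline

One YAML config drives `simulate → quantify → domain → stats`; CLI flags
override the config seed and output directory. Every run writes a
manifest (seed, parameter hash, package version, the size filter and
overlap threshold actually used) and logs all default-filled parameters —
none of the unpublished settings are ever silent. Reruns with identical
config are byte-identical. Input CSVs are schema-checked before any
computation, and invalid thresholds or profiles fail at config parse.

Problem sizes: the test suite and the acceptance script run the image
pipeline on 15–30 µm fields at 0.05 µm/px and domain simulations on the
ground-truth fast path (50 replicate cohort studies at n = 12 astrocytes
per cohort), which keeps the full suite under two minutes on one CPU while
preserving the physical scales of the acquisition geometry. The bundled
demo runs full 280 µm domain images at 0.15 µm/px with 0.3 µm puncta at
0.1/µm² — a deliberately coarser sampling whose ~90% detection recovery is
dominated by the same coincidence-merging effect as at full resolution.

## Known limitations

- Coincidence merging bounds density recovery at high punctum densities;
  no watershed splitting is attempted (detection is deliberately the
  plain component/size-filter algorithm).
- The overlap denominator convention (presynaptic area) is one of two
  defensible readings of the colocalization rule; the alternative
  (size-filtered postsynaptic puncta as overlap target) is available via
  `restrict_to_post_puncta`.
- ω² uses the subject-variance-inclusive denominator; other published
  variants differ by O(1/n) terms.
- 2D only; densities are per-area, not per-volume.
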