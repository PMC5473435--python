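# Methods

## Model

A lambda stack is a C×H×W array of photon counts, channel *c* covering the
half-open wavelength bin `[start + c·step, start + (c+1)·step)` nm. Nominal
acquisition ranges name the outer bin **edges**: 418–584 nm in 9.8 nm steps
is 17 channels (span/step = 16.94, rounded), 418–700 nm is 29. The channel
count is always `round(span/step)`; a centre-based reading cannot reproduce
both counts, which is why the edge convention is built in.

Each pixel's counts are modelled as independent Poisson draws around a
nonnegative linear mixture of component emission spectra:

    y ~ Poisson(S a + b)

where the columns of S are reference spectra normalised to unit area (channel
values summing to 1), `a ≥ 0` are the per-pixel abundances, and `b` an
optional background spectrum. Because the columns are unit-area, an abundance
is the component's total expected photon count at that pixel. Maximising the
Poisson likelihood is equivalent to minimising the generalised
Kullback–Leibler divergence

    D(y | m) = Σ_c [ y_c ln(y_c/m_c) − y_c + m_c ],   m = S a + b,

with the convention 0·ln 0 = 0.

Assumptions: emission spectra of the pure states are constant across the
image (no environment-dependent line-shape changes beyond the two discrete
states); detector counts are shot-noise limited (no read noise, no gain
dialects); mixing is linear (no FRET, no inner-filter effects, and
autoquenching is outside the model).

## Decomposition

Both modes use the standard multiplicative KL-NMF updates, which never
increase the objective they majorise:

    a_k ← a_k · [Σ_c S_ck y_c/m_c] / [Σ_c S_ck]            (abundances)
    S_ck ← S_ck · [Σ_n (y_cn/m_cn) a_kn] / [Σ_n a_kn]       (spectra, blind)

* **Fixed mode** (known references): abundances only. Default 10 sweeps —
  the recommended practice for fixed-spectra decomposition of lambda stacks;
  the iteration count is a parameter and convergence-critical tests use
  more (noiseless agreement with a direct NNLS solve reaches ≤1e-3 relative
  error per pixel within 200–500 sweeps for 2–4 well-separated components).
* **Blind mode**: spectra initialised from randomly chosen usable seed
  pixels (channel-smoothed with a 3-bin uniform filter), abundances
  uniformly at total/K; each sweep updates all-pixel abundances, then the
  spectra using every `subsample_stride`-th usable pixel (default stride 2,
  a speed measure), then renormalises spectra to unit area, pushing the
  scale into the abundances. Components are reported in discovered order;
  permutation/scale matching against ground truth happens only in tests.

**Objective bookkeeping (blind).** With a strided spectrum update the
full-image KL is not guaranteed monotone (the spectrum step
majorise-minimises only the subsample's KL; in practice a ~0.02% creep can
appear near convergence). The recorded `objective_history` is therefore the
KL over the spectrum-update pixel set, which *both* steps provably never
increase — abundance updates decrease every pixel's KL term individually, so
they decrease any subset sum. At stride 1 this is exactly the full-image
objective.

**Masking.** A pixel is *background* when its channel **sum** is strictly
below `background_threshold` (default 50 counts); it is excluded from
fitting and reported with all-zero abundances. The sum convention (rather
than per-channel) matches the total-intensity thresholding used downstream
by the fraction mapper. A pixel is *saturated* when any single channel
reaches `saturation_threshold` (default 4000); saturated pixels are flagged
and excluded from blind-mode spectrum estimation but still receive
abundances — clipped counts bias spectrum estimates, whereas dropping the
pixels from the abundance images would punch holes in the maps.

**Background spectrum** (`minimal-values` mode, default): the per-channel
minimum over non-saturated pixels joins the basis as one extra *fixed*
unit-area column whose abundance is fitted per pixel and dropped from the
output. When that minimum is identically zero (any truly dark pixel exists)
no component is added.

**Segregation bias**: an optional penalty `β Σ_n Σ_{k≠l} a_kn a_ln`
discouraging co-localised components; its gradient `β (Σ_l a_ln − a_kn)`
joins the update denominator. The default β = 0 makes the term exactly
inert; the functional form is this package's own stand-in for the
similarly-named option in earlier unmixing tools, whose exact form is not
published, and is only guaranteed equivalent at β = 0.

**Numerics**: ε = 1e-12 guards every logarithm and denominator; blind-mode
spectra are clipped at ε before renormalisation. All randomness flows
through `numpy.random.default_rng(seed)`; identical (stack, params, seed)
give bit-identical outputs.

## Fraction mapping and GP

For a two-component decomposition, `f = I1/(I1+I2)` with the **first
component the apolar one** by package-wide convention, so `f` is the apolar
(ordered) share. `f1 + f2 = 1` wherever defined, which is why one number per
pixel suffices. `GP = 2f − 1` identically, and on raw two-channel input this
coincides with `(I_blue − I_green)/(I_blue + I_green)` to machine precision.

Pixels with zero total (or background-masked) have an **undefined** fraction,
stored as NaN — never 0 or 0.5, which would masquerade as a real polarity.
Rendering shows them black; histograms and statistics exclude them.

Rendering uses a discrete LUT over [0, 1] with integer relative bin widths;
bins are half-open `[lo, hi)`, the last closed at 1, so binning is exhaustive
and non-overlapping. The default six-colour LUT has widths 2,3,3,3,3,2 over
a denominator of 16 (edges 0, 2/16, 5/16, 8/16, 11/16, 14/16, 1) and is
oriented **blue = high fraction** (most apolar/ordered), red = low. Flipping
this orientation inverts the meaning of every image, so it is fixed and
documented rather than configurable by accident. Colour saturation scales
linearly with total intensity, clipped at a ceiling (default: the image's
maximum defined total); no gamma.

2D intensity histograms cover the included (defined, non-background) pixels,
so the histogram total equals the included-pixel count; axes are linear by
default with a log1p-spaced option. Gates are simple polygons in (I1, I2)
space; the boundary counts as inside (shapely `intersects`), and gated
renderings black out everything outside the polygon.

## Band ratios (flow-cytometry emulation)

Filter codes decode as centre/width bandpasses — 450/50 → [425, 475] nm,
530/30 → [515, 545] nm — and long-passes as `[cut, ∞)`; the 505LP ∩ 530/30
intersection is computed generally even though it equals [515, 545] here.
A channel contributes its value times the fraction of its wavelength bin
covered by the (merged) passbands, making band intensity additive over
disjoint filters and linear in the spectrum. The 450/530 ratio is
scale-invariant per cell and strictly increasing in the apolar mixing
weight on the default grid. Ensemble summaries report the mean of per-cell
ratios as the primary statistic (per-cell ratios are invariant to staining
intensity) with the ratio of mean intensities alongside. Absolute values
are instrument-relative; no cross-experiment numbers are asserted.

## Synthetic scenes

The generator emulates the acquisition geometry — 100 nm pixels, 512×512
default field, 9.8 nm channels from 418 nm — and a two-state probe with
unit-area Gaussian emission models peaking at 440 nm (apolar) and 490 nm
(polar), FWHM 50 nm. True laurdan spectra are asymmetric; a Gaussian
suffices because every downstream computation is line-shape agnostic, and
two parameters keep the ground truth controllable.

* **MLV scene**: disjoint disks, each a single pure component — the phantom
  analogue of recording reference spectra on vesicles of defined
  composition. ROI-averaging a noiseless vesicle recovers its reference
  spectrum exactly.
* **Cell scene**: annular plasma membrane (2 px thick), cytoplasm, bright
  circular lipid droplets, empty nucleus. Compartment apolar fractions
  default to PM 0.75 — the literature estimate that ~three quarters of the
  live-cell PM is in ordered domains — with cytoplasm 0.30 and droplet 0.95
  as plausible placeholders (no published quantitative values exist for
  those compartments; they are conventions of this generator, not
  measurements). Per-pixel expected totals default to 500 (PM), 250
  (cytoplasm) and 900 (droplets) counts — shot-noise-limited but clearly
  above the 50-count background threshold, comparable to a bright
  two-photon acquisition.
* **Two-dye scene**: four components on the wide grid (440/490 nm pair plus
  a red-shifted 580/630 nm pair standing in for a droplet co-stain).
  Droplets carry both apolar states, internal membranes both polar states,
  and the PM carries only the first dye's apolar state — the second dye does
  not stain the PM, which the four-component decomposition must reproduce
  as exact zeros there.

Scenes are bit-reproducible from (parameters, seed); noiseless expected
stacks satisfy the linear mixing identity exactly; Poisson noise is applied
as an explicit separate step. What the phantoms do **not** emulate: real
morphology (circles and annuli only), 3D optics and PSF blur (an optional
Gaussian blur of expected counts exists, default off), photobleaching,
autoquenching kinetics, motion, read noise, or spectral miscalibration.
Passing tests on these phantoms therefore demonstrate correctness of the
estimator under its own noise model, not robustness to every property of
real microscope data.

## Problem sizes

Unit tests run on 64×64–96×96 scenes; the conservation and
fraction-recovery checks use the full 512×512 default phantom. The
acceptance script uses 512×512 for fraction conservation/recovery, 64×64
for the NNLS cross-checks (an exact per-pixel solve is quadratic-programming
per pixel and need not be large to be conclusive), and 96×96 at high SNR
(peak totals 800) for blind-mode recovery.

## Known limitations

* Blind-mode identifiability is up to permutation and scale, as for any NMF;
  with heavily overlapping spectra and low SNR the discovered components can
  mix. Fixed mode with measured references is the recommended path, matching
  how the method is used in practice.
* The minimal-values background component is a heuristic: it captures a
  spatially uniform additive background only.
* The multiplicative updates converge linearly; spurious components decay
  geometrically but slowly when spectra overlap strongly. Iteration counts
  are parameters for exactly this reason.
* Fractions are a relative measure of probe environment, not a calibrated
  order parameter: reference-spectrum choice shifts the absolute values,
  which is inherent to the method.
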