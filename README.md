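# specfrac

Poisson spectral unmixing and fraction mapping for lambda stacks of
solvatochromic membrane probes.

## The problem

Laurdan-family probes (laurdan, C-laurdan, M-laurdan) report the polarity of
their lipid environment: embedded in apolar, ordered (Lo/gel) bilayers they
emit around **440 nm**; in polar, water-exposed, disordered (Ld) bilayers the
emission red-shifts to around **490 nm**. Classically this is summarised by
the generalised polarisation computed from just two detection channels,

```
GP = (I440 − I490) / (I440 + I490).
```

A spectral detector records much more than two channels — a *lambda stack*
of C narrow wavelength bins per pixel (e.g. 17 channels of 9.8 nm from
418 nm). Using all of them, each pixel's spectrum can be decomposed into
nonnegative contributions of reference components, which separates the
apolar and polar states of a probe far more cleanly than the two-channel GP,
and also unmixes co-stains (e.g. a red droplet marker) in the same pass.

`specfrac` implements that workflow end to end for people analysing
membrane-order imaging data — plus a ground-truthed synthetic scene
generator so every stage is testable without a microscope.

## The model

Counts at pixel *n* are modelled as independent Poisson draws around a
linear mixture of unit-area component spectra (columns of **S**):

```
y_n ~ Poisson(S a_n + b),     a_n ≥ 0,
```

with `b` an optional background spectrum (per-channel minimum over
non-saturated pixels). Maximum likelihood is equivalent to minimising the
generalised Kullback–Leibler divergence `D(y | S a + b)`, done with the
classic multiplicative KL-NMF updates — abundances only when the reference
spectra are known (*fixed* mode), alternating spectrum/abundance updates
when they are not (*blind* mode).

For a two-component (apolar-first) decomposition, the **fraction map** is

```
f = I_apolar / (I_apolar + I_polar)  ∈ [0, 1],      GP = 2 f − 1,
```

undefined (and rendered black) where the total is zero. Fractions are
colour-coded through a discrete LUT (default: six colours with relative bin
widths 2,3,3,3,3,2; blue = most apolar/ordered) and brightness-scaled by
total intensity. 2D intensity histograms with polygonal gates project
intensity-space selections back onto the image, flow-cytometry style; a
separate module integrates spectra through the standard 450/50 and
505LP+530/30 cytometer filters to form the GP-like 450/530 ratio.

## Worked example

Simulate a 512×512 cell phantom (100 nm pixels, plasma-membrane ring at
apolar fraction 0.75, cytoplasm at 0.30, bright apolar droplets, Poisson
shot noise), unmix it against the 440/490 nm reference pair, and read the
compartment fractions back:

```python
import numpy as np
import specfrac as sf

grid = sf.build_channel_grid(418, 584, 9.8)      # 17 channels of 9.8 nm
refs = sf.two_state_references(grid)             # apolar 440 nm, polar 490 nm

expected, phantom = sf.make_cell_scene(grid, seed=0)
stack = sf.add_poisson_noise(expected, seed=1)

maps = sf.unmix_fixed(stack, refs, sf.UnmixParams(n_iterations=100))
fmap = sf.fraction_map(maps)

pm = phantom.compartment_mask("plasma_membrane")
cyto = phantom.compartment_mask("cytoplasm")
print(f"median apolar fraction, PM ring:   {np.nanmedian(fmap.fraction[pm]):.3f}")
print(f"median apolar fraction, cytoplasm: {np.nanmedian(fmap.fraction[cyto]):.3f}")
print(f"median GP, PM ring:                {np.nanmedian(fmap.gp()[pm]):.3f}")
```

prints

```
median apolar fraction, PM ring:   0.749
median apolar fraction, cytoplasm: 0.300
median GP, PM ring:                0.498
```

i.e. the decomposition recovers the configured compartment polarities from
shot-noised data, and the PM's GP of ≈0.5 is exactly `2·0.75 − 1`.

The same chain is available from the shell:

```
specfrac synth --kind cell --size 256 --seed 0 --out scene/
specfrac unmix --stack scene/stack.tif --refs scene/reference_spectra.csv --out unmixed/
specfrac fractionmap --abundances unmixed/abundances.tif --out frac/
```

Other subcommands: `gp` (two-channel baseline), `gate` (intensity-space
gating), `ratio` (450/530 band summaries), `pipeline` (one YAML config for
the whole chain). Every run writes a `manifest.json` with parameters, seeds
and input digests.

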