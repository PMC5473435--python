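"""Spectral channel grids, emission spectra and small optical utilities.

A lambda stack is acquired through a spectral detector that bins emitted
light into contiguous wavelength channels.  This module holds the channel
geometry (:class:`ChannelGrid`), binned emission spectra
(:class:`EmissionSpectrum`), ordered collections of reference spectra used
as an unmixing basis (:class:`ReferenceSet`), and the handful of spectral
operations the rest of the package builds on: normalisation, resampling
between grids, Gaussian model spectra for the two-state solvatochromic
probes, ROI spectrum extraction and the diffraction-limited lateral
resolution estimate.

Conventions
-----------
* All wavelengths are nanometres.  No other units are accepted.
* Channel ``i`` of a grid occupies the half-open interval
  ``[start + i*step, start + (i+1)*step)``; its centre is
  ``start + (i + 0.5)*step``.  The nominal acquisition range such as
  "418-584 nm" refers to the outer bin *edges*.
* Spectra are stored per channel (binned); "unit area" means the channel
  values sum to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ChannelGrid",
    "EmissionSpectrum",
    "ReferenceSet",
    "build_channel_grid",
    "normalize_spectrum",
    "resample_spectrum",
    "gaussian_emission",
    "roi_mean_spectrum",
    "lateral_resolution",
    "two_state_references",
    "four_component_references",
]

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class ChannelGrid:
    """Spectral binning of an acquisition: first edge, bin width, bin count."""

    start_nm: float
    step_nm: float
    n_channels: int

    def __post_init__(self) -> None:
        if not self.step_nm > 0:
            raise ValueError(f"step_nm must be positive, got {self.step_nm}")
        if int(self.n_channels) != self.n_channels or self.n_channels < 1:
            raise ValueError(f"n_channels must be a positive integer, got {self.n_channels}")

    def __len__(self) -> int:
        return int(self.n_channels)

    @property
    def centers(self) -> np.ndarray:
        """Channel centre wavelengths (nm)."""
        return self.start_nm + (np.arange(self.n_channels) + 0.5) * self.step_nm

    @property
    def edges(self) -> np.ndarray:
        """The n_channels + 1 bin edges (nm)."""
        return self.start_nm + np.arange(self.n_channels + 1) * self.step_nm

    @property
    def end_nm(self) -> float:
        """Upper edge of the last channel (nm)."""
        return self.start_nm + self.n_channels * self.step_nm

    def channel_of(self, wavelength_nm: float) -> int:
        """Index of the channel whose half-open bin contains ``wavelength_nm``."""
        idx = int(np.floor((wavelength_nm - self.start_nm) / self.step_nm))
        if idx < 0 or idx >= self.n_channels:
            raise ValueError(f"{wavelength_nm} nm outside grid range "
                             f"[{self.start_nm}, {self.end_nm}) nm")
        return idx


def build_channel_grid(start_nm: float, end_nm: float, step_nm: float) -> ChannelGrid:
    """Build the grid covering ``[start_nm, end_nm]`` in bins of ``step_nm``.

    The endpoints are outer bin edges and the channel count is the rounded
    span/step ratio, matching how spectral detectors report a nominal range
    (e.g. 418-584 nm in 9.8 nm steps gives 17 channels).
    """
    if not step_nm > 0:
        raise ValueError(f"step_nm must be positive, got {step_nm}")
    if not end_nm > start_nm:
        raise ValueError(f"end_nm ({end_nm}) must exceed start_nm ({start_nm})")
    n = int(round((end_nm - start_nm) / step_nm))
    if n < 1:
        raise ValueError("span shorter than half a channel; no channels fit")
    return ChannelGrid(start_nm=float(start_nm), step_nm=float(step_nm), n_channels=n)


@dataclass(frozen=True)
class EmissionSpectrum:
    """A binned emission spectrum on a channel grid."""

    grid: ChannelGrid
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size != self.grid.n_channels:
            raise ValueError(f"spectrum has {vals.size} values for a "
                             f"{self.grid.n_channels}-channel grid")
        if not np.all(np.isfinite(vals)):
            raise ValueError("spectrum values must be finite")
        if np.any(vals < 0):
            raise ValueError("spectrum values must be nonnegative")
        if not np.any(vals > 0):
            raise ValueError("spectrum is identically zero")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.centers


def normalize_spectrum(spec: EmissionSpectrum, mode: str = "unit-area") -> EmissionSpectrum:
    """Rescale a spectrum so that it sums to 1 (``unit-area``) or peaks at 1
    (``unit-max``).  Shape is preserved up to the scale factor."""
    vals = spec.values
    if mode == "unit-area":
        denom = vals.sum()
    elif mode == "unit-max":
        denom = vals.max()
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    if denom <= 0:
        raise ValueError("cannot normalise a degenerate (all-zero) spectrum")
    return replace(spec, values=vals / denom)


def resample_spectrum(spec: EmissionSpectrum, target: ChannelGrid) -> EmissionSpectrum:
    """Resample a spectrum onto another grid.

    Values are linearly interpolated in channel-centre wavelength; target
    channels whose centres fall outside the source centre range are set to 0.
    Raises if the wavelength ranges of the two grids do not overlap.
    """
    src = spec.grid
    if target.end_nm <= src.start_nm or target.start_nm >= src.end_nm:
        raise ValueError("target grid wavelength range is disjoint from the source grid")
    sc = src.centers
    tc = target.centers
    out = np.interp(tc, sc, spec.values)
    out[(tc < sc[0]) | (tc > sc[-1])] = 0.0
    out = np.clip(out, 0.0, None)
    if not np.any(out > 0):
        raise ValueError("resampled spectrum is identically zero (ranges barely overlap)")
    return EmissionSpectrum(grid=target, values=out, name=spec.name)


def gaussian_emission(peak_nm: float, fwhm_nm: float, grid: ChannelGrid,
                      name: str = "") -> EmissionSpectrum:
    """Unit-area Gaussian model spectrum evaluated at the channel centres.

    The solvatochromic probes emit around 440 nm in apolar (ordered,
    dehydrated) bilayers and around 490 nm in polar (water-exposed) ones; a
    two-parameter Gaussian is a sufficient stand-in because the downstream
    unmixing is agnostic to line shape.
    """
    if not fwhm_nm > 0:
        raise ValueError(f"fwhm_nm must be positive, got {fwhm_nm}")
    sigma = fwhm_nm / _FWHM_TO_SIGMA
    z = (grid.centers - peak_nm) / sigma
    vals = np.exp(-0.5 * z * z)
    total = vals.sum()
    if total <= 0:
        raise ValueError("Gaussian underflows on this grid (peak far outside range)")
    return EmissionSpectrum(grid=grid, values=vals / total,
                            name=name or f"gauss{peak_nm:g}")


def roi_mean_spectrum(stack, roi_mask: np.ndarray, name: str = "roi_mean") -> EmissionSpectrum:
    """Mean spectrum over the pixels selected by a binary ROI mask.

    This is how reference curves are extracted from images of vesicles of
    defined composition: draw an ROI on one vesicle and average per channel.
    ``stack`` is any object with ``counts`` (C, H, W) and ``grid`` attributes.
    """
    mask = np.asarray(roi_mask, dtype=bool)
    counts = stack.counts
    if mask.shape != counts.shape[1:]:
        raise ValueError(f"ROI mask shape {mask.shape} does not match image "
                         f"shape {counts.shape[1:]}")
    n_sel = int(mask.sum())
    if n_sel == 0:
        raise ValueError("ROI selects no pixels")
    vals = counts[:, mask].mean(axis=1).astype(float)
    return EmissionSpectrum(grid=stack.grid, values=vals, name=name)


def lateral_resolution(wavelength_nm: float, numerical_aperture: float) -> float:
    """Best-case lateral optical resolution, ``0.4 * wavelength / NA`` in nm.

    At 500 nm emission through an NA 1.2 objective this is about 167 nm —
    roughly two 100 nm pixels, which is why single-pixel heterogeneity in
    fraction maps cannot be interpreted as sub-resolution membrane domains.
    """
    if not wavelength_nm > 0 or not numerical_aperture > 0:
        raise ValueError("wavelength and numerical aperture must be positive")
    return 0.4 * wavelength_nm / numerical_aperture


@dataclass(frozen=True)
class ReferenceSet:
    """Ordered reference spectra on a shared grid — the unmixing basis.

    By convention the *apolar* (ordered-phase) component comes first, so the
    downstream fraction map reports the apolar share of the signal.
    """

    spectra: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        spectra = tuple(self.spectra)
        object.__setattr__(self, "spectra", spectra)
        if len(spectra) < 1:
            raise ValueError("reference set needs at least one spectrum")
        grid0 = spectra[0].grid
        for s in spectra[1:]:
            if s.grid != grid0:
                raise ValueError("all reference spectra must share one channel grid")
        names = [s.name for s in spectra]
        if len(set(names)) != len(names):
            raise ValueError(f"reference names must be unique, got {names}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def grid(self) -> ChannelGrid:
        return self.spectra[0].grid

    @property
    def names(self) -> list:
        return [s.name for s in self.spectra]

    def matrix(self) -> np.ndarray:
        """Unit-area spectra as a (channels, components) matrix."""
        cols = [normalize_spectrum(s, "unit-area").values for s in self.spectra]
        return np.stack(cols, axis=1)

    def resampled(self, target: ChannelGrid) -> "ReferenceSet":
        return ReferenceSet(tuple(resample_spectrum(s, target) for s in self.spectra))


def two_state_references(grid: ChannelGrid, peak_apolar_nm: float = 440.0,
                         peak_polar_nm: float = 490.0, fwhm_nm: float = 50.0) -> ReferenceSet:
    """Default two-state basis for a laurdan-family probe: apolar component
    peaking at 440 nm, polar (water-exposed) component peaking at 490 nm."""
    return ReferenceSet((
        gaussian_emission(peak_apolar_nm, fwhm_nm, grid, name="apolar"),
        gaussian_emission(peak_polar_nm, fwhm_nm, grid, name="polar"),
    ))


def four_component_references(grid: ChannelGrid) -> ReferenceSet:
    """Four-component basis for a double-stain experiment: a blue-shifted
    probe pair (440/490 nm, laurdan-like) and a red-shifted probe pair
    (580/630 nm, Nile-Red-like), each with an apolar and a polar state."""
    return ReferenceSet((
        gaussian_emission(440.0, 50.0, grid, name="dye1_apolar"),
        gaussian_emission(490.0, 50.0, grid, name="dye1_polar"),
        gaussian_emission(580.0, 55.0, grid, name="dye2_apolar"),
        gaussian_emission(630.0, 60.0, grid, name="dye2_polar"),
    ))
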