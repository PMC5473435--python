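"""Flow-cytometry-style band ratios from emission spectra.

A cytometer splits each cell's emission through optical filters instead of
a spectral detector.  The standard configuration for laurdan-family probes
uses a 450/50 bandpass (425-475 nm, the "blue"/apolar window) and a 505
long-pass followed by a 530/30 bandpass (net 515-545 nm, the
"green"/polar window).  The 450/530 intensity ratio behaves like a GP
proxy: it rises with the apolar share of the probe's environment and falls
after cholesterol depletion.  Absolute values are instrument-dependent, so
only within-experiment comparisons are meaningful.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral import ChannelGrid, EmissionSpectrum, ReferenceSet, two_state_references

__all__ = [
    "BandFilter",
    "CellEnsemble",
    "band_intensity",
    "ratio_450_530",
    "ensemble_summary",
    "synthetic_cell_ensemble",
    "BAND_450_50",
    "BAND_530_30_505LP",
]


def _merge_intervals(intervals):
    ivs = sorted((float(lo), float(hi)) for lo, hi in intervals)
    merged = [ivs[0]]
    for lo, hi in ivs[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return tuple(merged)


@dataclass(frozen=True)
class BandFilter:
    """A set of closed wavelength passbands (nm); overlaps are merged."""

    passbands: tuple
    name: str = ""

    def __post_init__(self) -> None:
        bands = tuple(self.passbands)
        if len(bands) == 0:
            raise ValueError("filter needs at least one passband")
        for lo, hi in bands:
            if not lo <= hi:
                raise ValueError(f"invalid passband ({lo}, {hi}): lo must be <= hi")
        object.__setattr__(self, "passbands", _merge_intervals(bands))

    @classmethod
    def bandpass(cls, center_nm: float, width_nm: float, name: str = "") -> "BandFilter":
        """Decode center/width notation, e.g. 450/50 -> [425, 475] nm."""
        half = width_nm / 2.0
        return cls(((center_nm - half, center_nm + half),),
                   name=name or f"{center_nm:g}/{width_nm:g}")

    @classmethod
    def longpass(cls, cut_nm: float, name: str = "") -> "BandFilter":
        return cls(((cut_nm, math.inf),), name=name or f"{cut_nm:g}LP")

    def intersect(self, other: "BandFilter", name: str = "") -> "BandFilter":
        pieces = []
        for alo, ahi in self.passbands:
            for blo, bhi in other.passbands:
                lo, hi = max(alo, blo), min(ahi, bhi)
                if lo < hi:
                    pieces.append((lo, hi))
        if not pieces:
            raise ValueError("filters do not overlap")
        return BandFilter(tuple(pieces), name=name or f"{self.name}*{other.name}")


#: 450/50 bandpass — the blue (apolar) detection window, 425-475 nm
BAND_450_50 = BandFilter.bandpass(450, 50, name="450/50")
#: 505 long-pass in series with a 530/30 bandpass — net 515-545 nm green window
BAND_530_30_505LP = BandFilter.longpass(505).intersect(
    BandFilter.bandpass(530, 30), name="505LP+530/30")


def band_intensity(spec: EmissionSpectrum, band: BandFilter) -> float:
    """Intensity transmitted through a filter: each channel contributes its
    value times the fraction of its wavelength bin covered by the passbands.

    Returns 0 (with a warning) when the filter misses the grid entirely.
    """
    edges = spec.grid.edges
    step = spec.grid.step_nm
    weights = np.zeros(spec.grid.n_channels)
    for lo, hi in band.passbands:
        overlap = np.clip(np.minimum(hi, edges[1:]) - np.maximum(lo, edges[:-1]),
                          0.0, None)
        weights += overlap / step
    if not np.any(weights > 0):
        warnings.warn(f"filter {band.name!r} does not overlap the spectral grid",
                      stacklevel=2)
        return 0.0
    return float((spec.values * weights).sum())


def ratio_450_530(spec: EmissionSpectrum) -> float:
    """The 450/530 ratio: blue-window over green-window band intensity.

    Scale-invariant and increasing in the apolar share of the emission.
    """
    num = band_intensity(spec, BAND_450_50)
    den = band_intensity(spec, BAND_530_30_505LP)
    if den <= 0:
        raise ZeroDivisionError("no intensity in the 530 nm window; ratio undefined")
    return num / den


@dataclass
class CellEnsemble:
    """Per-cell emission spectra on a shared grid, with optional per-cell
    intensity scale factors and condition labels."""

    spectra: list
    scales: np.ndarray | None = None
    conditions: list | None = None
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.spectra) < 1:
            raise ValueError("ensemble needs at least one cell")
        grid0 = self.spectra[0].grid
        if any(s.grid != grid0 for s in self.spectra):
            raise ValueError("all cells must share one channel grid")
        n = len(self.spectra)
        if self.scales is None:
            self.scales = np.ones(n)
        self.scales = np.asarray(self.scales, dtype=float)
        if self.scales.shape != (n,):
            raise ValueError("one scale factor per cell required")
        if self.conditions is not None and len(self.conditions) != n:
            raise ValueError("one condition label per cell required")

    @property
    def grid(self) -> ChannelGrid:
        return self.spectra[0].grid

    def __len__(self) -> int:
        return len(self.spectra)


def ensemble_summary(cells: CellEnsemble) -> pd.DataFrame:
    """Per-condition mean band intensities and 450/530 ratios.

    Reports both the mean of per-cell ratios (the primary statistic) and the
    ratio of mean intensities; per-cell scale factors cancel in each cell's
    ratio but not in the mean intensities.
    """
    if len(cells) < 1:
        raise ValueError("empty ensemble")
    i450 = np.array([band_intensity(s, BAND_450_50) for s in cells.spectra])
    i530 = np.array([band_intensity(s, BAND_530_30_505LP) for s in cells.spectra])
    i450 = i450 * cells.scales
    i530 = i530 * cells.scales
    if np.any(i530 <= 0):
        raise ZeroDivisionError("a cell has no intensity in the 530 nm window")
    ratios = i450 / i530
    cond = cells.conditions if cells.conditions is not None else ["all"] * len(cells)
    df = pd.DataFrame({"condition": cond, "I450": i450, "I530": i530,
                       "ratio_450_530": ratios})
    grouped = df.groupby("condition", sort=True)
    out = grouped.agg(n_cells=("ratio_450_530", "size"),
                      mean_I450=("I450", "mean"),
                      mean_I530=("I530", "mean"),
                      mean_ratio=("ratio_450_530", "mean"))
    out["ratio_of_means"] = out["mean_I450"] / out["mean_I530"]
    return out.reset_index()


def synthetic_cell_ensemble(grid: ChannelGrid, n_cells: int, apolar_fraction: float,
                            *, mean_total: float = 1.0e4, total_cv: float = 0.25,
                            fraction_jitter: float = 0.03, shot_noise: bool = True,
                            references: ReferenceSet | None = None,
                            condition: str | None = None, seed: int = 0) -> CellEnsemble:
    """Simulate whole-cell spectra of a two-state probe at a given apolar share.

    Each cell's expected spectrum is ``total * (f * apolar + (1-f) * polar)``
    with a log-normal total (CV ``total_cv``), a small Gaussian jitter on the
    per-cell fraction, and optional Poisson shot noise on the channel counts.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0.0 <= apolar_fraction <= 1.0:
        raise ValueError("apolar_fraction must be in [0, 1]")
    refs = references if references is not None else two_state_references(grid)
    if len(refs) != 2:
        raise ValueError("two-state ensemble needs exactly two reference spectra")
    S = refs.matrix()
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + total_cv**2))
    totals = mean_total * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n_cells))
    fracs = np.clip(rng.normal(apolar_fraction, fraction_jitter, size=n_cells), 0, 1)
    spectra = []
    for t, f in zip(totals, fracs):
        expected = t * (S[:, 0] * f + S[:, 1] * (1.0 - f))
        vals = rng.poisson(expected).astype(float) if shot_noise else expected
        if not np.any(vals > 0):  # pathological draw at tiny totals
            vals = expected
        spectra.append(EmissionSpectrum(grid, vals, name=f"cell_{len(spectra)}"))
    labels = [condition or f"f={apolar_fraction:g}"] * n_cells
    return CellEnsemble(spectra=spectra, conditions=labels, seed=seed,
                        params=dict(n_cells=n_cells, apolar_fraction=apolar_fraction,
                                    mean_total=mean_total, total_cv=total_cv,
                                    fraction_jitter=fraction_jitter,
                                    shot_noise=shot_noise))
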