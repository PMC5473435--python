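"""Fractional-intensity maps, discrete-LUT rendering, GP conversion, 2D
intensity histograms and gating.

Given a two-component decomposition (apolar first, polar second by
convention), every pixel's *fraction* is the first component's share of the
total unmixed intensity, ``f = I1 / (I1 + I2)``.  The two fractional
intensities always sum to 1, so one number per pixel carries the full
two-component information.  The classic generalised polarisation is an
affine relabelling of the same quantity: ``GP = 2 f - 1``, identical to the
two-channel formula ``(I_blue - I_green) / (I_blue + I_green)``.

Pixels with zero total intensity (or flagged as background upstream) have
an *undefined* fraction — stored as NaN, rendered black, and excluded from
histograms and statistics.  They are never silently mapped to 0 or 0.5.

Rendering assigns each defined pixel the colour of its fraction bin in a
discrete LUT and scales that colour linearly with total intensity (clipped
at a ceiling).  The default LUT has six colours with relative bin widths
2,3,3,3,3,2 over a denominator of 16, oriented so that *blue marks high
(apolar/ordered) fractions* and red marks low ones — flipping this
orientation inverts the meaning of every rendered image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely

from .scenes import LambdaStack
from .unmix import AbundanceMaps

__all__ = [
    "FractionMap",
    "DiscreteLUT",
    "Gate",
    "fraction_map",
    "fraction_to_gp",
    "gp_map_from_channels",
    "colorize_fraction",
    "intensity_histogram_2d",
    "gate_to_image",
]


@dataclass
class FractionMap:
    """Per-pixel fraction of the first component plus total intensity.

    ``fraction`` is NaN exactly where ``defined`` is False (zero total or
    background-masked pixels).
    """

    fraction: np.ndarray
    total_intensity: np.ndarray
    defined: np.ndarray

    def __post_init__(self) -> None:
        f, t, d = (np.asarray(a) for a in (self.fraction, self.total_intensity,
                                           self.defined))
        if not (f.shape == t.shape == d.shape):
            raise ValueError("fraction, total_intensity and defined must share a shape")
        if np.any((f[d] < 0) | (f[d] > 1)):
            raise ValueError("defined fractions must lie in [0, 1]")

    def gp(self) -> np.ndarray:
        """Generalised-polarisation view of the map (NaN where undefined)."""
        return fraction_to_gp(self.fraction)


def fraction_map(two_maps: AbundanceMaps) -> FractionMap:
    """Fractional intensity of the first component, ``I1 / (I1 + I2)``.

    Undefined (NaN) where the total unmixed intensity is zero or the pixel
    was background-masked during unmixing.
    """
    if two_maps.n_components != 2:
        raise ValueError(f"fraction mapping needs exactly 2 components, "
                         f"got {two_maps.n_components}")
    i1, i2 = two_maps.values
    total = i1 + i2
    defined = (total > 0) & ~np.asarray(two_maps.background_mask, dtype=bool)
    frac = np.full(total.shape, np.nan)
    frac[defined] = i1[defined] / total[defined]
    return FractionMap(fraction=frac, total_intensity=total, defined=defined)


def fraction_to_gp(fraction):
    """``GP = 2 * fraction - 1``; maps [0, 1] onto [-1, 1], NaN passes through."""
    f = np.asarray(fraction, dtype=float)
    finite = np.isfinite(f)
    if np.any((f[finite] < 0) | (f[finite] > 1)):
        raise ValueError("fraction must lie in [0, 1]")
    out = 2.0 * f - 1.0
    return float(out) if np.isscalar(fraction) else out


def gp_map_from_channels(stack: LambdaStack, ch_blue_index: int,
                         ch_green_index: int) -> np.ndarray:
    """Classic two-channel GP image, ``(I_blue - I_green) / (I_blue + I_green)``.

    This is the baseline the spectral-decomposition route improves on: it
    uses only two of the recorded channels (typically those containing
    440 nm and 490 nm).  NaN where both channels are zero.
    """
    if ch_blue_index == ch_green_index:
        raise ValueError("blue and green channel indices must differ")
    n = stack.grid.n_channels
    for idx in (ch_blue_index, ch_green_index):
        if not 0 <= idx < n:
            raise ValueError(f"channel index {idx} outside [0, {n})")
    blue = stack.counts[ch_blue_index].astype(float)
    green = stack.counts[ch_green_index].astype(float)
    total = blue + green
    gp = np.full(total.shape, np.nan)
    ok = total > 0
    gp[ok] = (blue[ok] - green[ok]) / total[ok]
    return gp


@dataclass(frozen=True)
class DiscreteLUT:
    """Discrete colour lookup table over [0, 1] with relative bin widths.

    ``colours`` are RGB triples (0-255) listed from low fraction to high;
    ``bin_widths`` are positive integers whose sum is the partition
    denominator.  Bins are half-open ``[lo, hi)`` except the last, which is
    closed at 1, so every fraction maps to exactly one colour.
    """

    colours: tuple
    bin_widths: tuple

    def __post_init__(self) -> None:
        cols = tuple(tuple(int(v) for v in c) for c in self.colours)
        widths = tuple(int(w) for w in self.bin_widths)
        object.__setattr__(self, "colours", cols)
        object.__setattr__(self, "bin_widths", widths)
        if len(cols) != len(widths):
            raise ValueError("need one width per colour")
        if len(cols) == 0:
            raise ValueError("LUT must have at least one colour")
        if any(w <= 0 for w in widths):
            raise ValueError("bin widths must be positive integers")
        for c in cols:
            if len(c) != 3 or any(not 0 <= v <= 255 for v in c):
                raise ValueError(f"invalid RGB triple {c}")

    @property
    def edges(self) -> np.ndarray:
        """Bin edges in [0, 1]: cumulative widths over their sum."""
        w = np.asarray(self.bin_widths, dtype=float)
        return np.concatenate([[0.0], np.cumsum(w) / w.sum()])

    def bin_index(self, fraction) -> np.ndarray:
        """Bin of each fraction; half-open bins, last bin closed at 1."""
        f = np.asarray(fraction, dtype=float)
        idx = np.searchsorted(self.edges[1:-1], f, side="right")
        return idx

    def colour_array(self) -> np.ndarray:
        return np.asarray(self.colours, dtype=float)

    @classmethod
    def six_colours_233332(cls) -> "DiscreteLUT":
        """The default six-colour LUT (widths 2,3,3,3,3,2 over 16).

        Oriented red -> blue with increasing fraction: dark blue marks the
        most apolar/ordered pixels.
        """
        return cls(
            colours=((200, 0, 0), (255, 128, 0), (255, 255, 0),
                     (0, 200, 0), (0, 255, 255), (0, 0, 200)),
            bin_widths=(2, 3, 3, 3, 3, 2),
        )

    @classmethod
    def from_file(cls, path) -> "DiscreteLUT":
        """Read a plain-text LUT: one ``R,G,B,width`` line per colour,
        low-fraction bin first."""
        colours, widths = [], []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                r, g, b, w = (int(x) for x in line.split(","))
                colours.append((r, g, b))
                widths.append(w)
        return cls(tuple(colours), tuple(widths))

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# R,G,B,width  (low-fraction bin first)\n")
            for (r, g, b), w in zip(self.colours, self.bin_widths):
                fh.write(f"{r},{g},{b},{w}\n")


def colorize_fraction(fmap: FractionMap, lut: DiscreteLUT | None = None,
                      intensity_ceiling="auto") -> np.ndarray:
    """Render a fraction map: LUT colour of the fraction bin, scaled linearly
    by total intensity clipped at the ceiling.  Undefined pixels are black.

    ``intensity_ceiling='auto'`` uses the maximum total intensity over
    defined pixels.  Returns an (H, W, 3) uint8 image.
    """
    lut = lut or DiscreteLUT.six_colours_233332()
    defined = fmap.defined
    rgb = np.zeros((*fmap.fraction.shape, 3), dtype=np.uint8)
    if not defined.any():
        warnings.warn("fraction map has no defined pixels; rendering all black",
                      stacklevel=2)
        return rgb
    if intensity_ceiling == "auto":
        ceiling = float(fmap.total_intensity[defined].max())
    else:
        ceiling = float(intensity_ceiling)
    if ceiling <= 0:
        warnings.warn("nonpositive intensity ceiling; rendering all black",
                      stacklevel=2)
        return rgb
    bins = lut.bin_index(fmap.fraction[defined])
    scale = np.clip(fmap.total_intensity[defined] / ceiling, 0.0, 1.0)
    rgb[defined] = np.rint(lut.colour_array()[bins] * scale[:, None]).astype(np.uint8)
    return rgb


def intensity_histogram_2d(two_maps: AbundanceMaps, n_bins: int = 64,
                           scale: str = "linear") -> tuple:
    """2D histogram of per-pixel unmixed intensities (I1 on axis 0, I2 on 1).

    Background-masked and zero-total (undefined) pixels are omitted, so the
    histogram total equals the number of included pixels.  ``scale='log'``
    places bin edges uniformly in log1p(intensity) but reports them in
    intensity units.  Returns ``(hist, i1_edges, i2_edges)``.
    """
    if two_maps.n_components != 2:
        raise ValueError("2D intensity histograms need exactly 2 components")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if scale not in ("linear", "log"):
        raise ValueError(f"scale must be 'linear' or 'log', got {scale!r}")
    i1, i2 = two_maps.values
    include = ((i1 + i2) > 0) & ~np.asarray(two_maps.background_mask, dtype=bool)
    x = i1[include].ravel()
    y = i2[include].ravel()
    if scale == "log":
        edges = []
        for v in (x, y):
            lo, hi = np.log1p(v.min()), np.log1p(v.max())
            if hi <= lo:
                hi = lo + 1.0
            edges.append(np.expm1(np.linspace(lo, hi, n_bins + 1)))
        hist, xe, ye = np.histogram2d(x, y, bins=edges)
    else:
        hist, xe, ye = np.histogram2d(x, y, bins=n_bins)
    return hist, xe, ye


@dataclass(frozen=True)
class Gate:
    """A polygonal region of interest in (I1, I2) intensity space."""

    vertices: tuple
    name: str = "gate"

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise ValueError("a gate polygon needs at least 3 vertices")
        poly = shapely.Polygon(verts)
        if not poly.is_valid or poly.area == 0:
            raise ValueError("gate polygon must be simple and non-degenerate")

    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    def contains(self, i1, i2) -> np.ndarray:
        """Membership of intensity points; the boundary counts as inside."""
        return shapely.intersects_xy(self.polygon(),
                                     np.asarray(i1, dtype=float),
                                     np.asarray(i2, dtype=float))


def gate_to_image(two_maps: AbundanceMaps, gate: Gate, fmap: FractionMap,
                  lut: DiscreteLUT | None = None,
                  intensity_ceiling="auto") -> tuple:
    """Project a 2D-plot gate back onto the image, flow-cytometry style.

    Returns ``(rgb, mask)``: the fraction-map rendering restricted to pixels
    whose (I1, I2) lie inside the gate polygon (boundary inclusive), all
    other pixels black.
    """
    if two_maps.n_components != 2:
        raise ValueError("gating needs exactly 2 components")
    i1, i2 = two_maps.values
    include = ((i1 + i2) > 0) & ~np.asarray(two_maps.background_mask, dtype=bool)
    mask = np.zeros(i1.shape, dtype=bool)
    mask[include] = gate.contains(i1[include], i2[include])
    rgb = colorize_fraction(fmap, lut, intensity_ceiling)
    rgb = rgb.copy()
    rgb[~mask] = 0
    return rgb, mask
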