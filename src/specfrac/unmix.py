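"""Per-pixel nonnegative spectral decomposition under a Poisson likelihood.

Each pixel's channel vector ``y`` is modelled as ``y ~ Poisson(S a + b)``
where the columns of ``S`` are unit-area component spectra, ``a`` the
nonnegative per-pixel abundances and ``b`` an optional background spectrum.
Maximising the Poisson likelihood is equivalent to minimising the
generalised Kullback-Leibler divergence

    D(y | m) = sum_c [ y_c ln(y_c / m_c) - y_c + m_c ],   m = S a + b,

which is minimised by the classic multiplicative KL-NMF updates.  Two modes
are provided:

* **fixed** — the spectra are known references; only abundances are updated
  (ten sweeps by default, which is the recommended practice for
  fixed-spectra decomposition of lambda stacks);
* **blind** — spectra and abundances are updated alternately, discovering
  the components from the data; spectrum updates use a strided pixel
  subsample (stride 2 by default) for speed.

Masking defaults follow common practice for two-photon lambda stacks: a
pixel is *background* when its channel sum is below 50 counts (strictly),
and *saturated* when any channel reaches 4000 counts.  Background pixels
are excluded from fitting and reported with zero abundances; saturated
pixels are flagged and excluded from spectrum estimation but still receive
abundances.  The optional background component is the per-channel minimum
over non-saturated pixels ("minimal values"), fitted as one extra fixed
column and dropped from the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .scenes import LambdaStack
from .spectral import EmissionSpectrum, ReferenceSet

__all__ = [
    "UnmixParams",
    "AbundanceMaps",
    "kl_divergence",
    "pixel_masks",
    "background_spectrum",
    "unmix_fixed",
    "unmix_blind",
]

_EPS = 1e-12  # zero-protection inside logarithms and denominators


@dataclass(frozen=True)
class UnmixParams:
    """Knobs of the decomposition.

    ``background_threshold`` applies to the per-pixel channel *sum*;
    ``saturation_threshold`` to individual channels.  ``subsample_stride``
    only affects spectrum updates in blind mode.  ``segregation_bias``
    weights an optional spatial-segregation penalty and is inert at its
    default of 0.
    """

    n_iterations: int = 10
    background_threshold: float = 50.0
    saturation_threshold: float = 4000.0
    subsample_stride: int = 2
    segregation_bias: float = 0.0
    background_spectrum_mode: str = "minimal-values"  # or "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.background_threshold < 0 or self.saturation_threshold < 0:
            raise ValueError("thresholds must be nonnegative")
        if self.subsample_stride < 1:
            raise ValueError("subsample_stride must be >= 1")
        if self.background_spectrum_mode not in ("minimal-values", "none"):
            raise ValueError(f"unknown background_spectrum_mode "
                             f"{self.background_spectrum_mode!r}")


@dataclass
class AbundanceMaps:
    """Per-component abundance images plus the masks used during fitting.

    ``values`` is (components, H, W); background-masked pixels are all-zero.
    ``objective_history`` holds the KL objective per sweep when the
    decomposition recorded it (blind mode).
    """

    values: np.ndarray
    component_names: list
    background_mask: np.ndarray
    saturation_mask: np.ndarray
    objective_history: list | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[0] != len(self.component_names):
            raise ValueError("values must be (components, H, W) matching names")
        if np.any(v < 0):
            raise ValueError("abundances must be nonnegative")
        self.values = v

    @property
    def n_components(self) -> int:
        return self.values.shape[0]

    def pair(self, i: int = 0, j: int = 1) -> "AbundanceMaps":
        """Two-component view (for fraction mapping of a multi-dye result)."""
        return AbundanceMaps(self.values[[i, j]],
                             [self.component_names[i], self.component_names[j]],
                             self.background_mask, self.saturation_mask)


def kl_divergence(observed, model) -> float:
    """Generalised KL divergence ``sum[o ln(o/m) - o + m]`` with 0 ln 0 = 0.

    This is the Poisson deviance (up to a factor of two) between observed
    counts and model intensities; it is nonnegative and zero iff they agree.
    """
    o = np.asarray(observed, dtype=float)
    m = np.asarray(model, dtype=float)
    if np.any(m < 0):
        raise ValueError("model intensities must be nonnegative")
    if np.any((o > 0) & (m == 0)):
        raise ValueError("model is zero where observed counts are positive")
    pos = o > 0
    term = np.zeros_like(o)
    term[pos] = o[pos] * np.log(o[pos] / m[pos]) - o[pos]
    return float(term.sum() + m.sum())


def pixel_masks(stack: LambdaStack, params: UnmixParams | None = None) -> tuple:
    """Background and saturation masks.

    Background: channel sum strictly below ``background_threshold`` (a pixel
    summing exactly to the threshold is kept).  Saturated: any channel at or
    above ``saturation_threshold``.  The masks are independent.
    """
    params = params or UnmixParams()
    total = stack.counts.sum(axis=0)
    background = total < params.background_threshold
    saturated = (stack.counts >= params.saturation_threshold).any(axis=0)
    return background, saturated


def background_spectrum(stack: LambdaStack, saturation_mask: np.ndarray) -> np.ndarray | None:
    """Per-channel minimum over non-saturated pixels ("minimal values").

    Returns ``None`` when the minimum is identically zero (no background
    component is needed then) or when every pixel is saturated.
    """
    usable = ~saturation_mask
    if not usable.any():
        return None
    mins = stack.counts[:, usable].min(axis=1).astype(float)
    if not np.any(mins > 0):
        return None
    return mins


def _update_abundances(S: np.ndarray, Y: np.ndarray, A: np.ndarray,
                       segregation_bias: float = 0.0) -> np.ndarray:
    """One multiplicative KL update of abundances (columns of A), in place."""
    model = S @ A
    ratio = Y / (model + _EPS)
    num = S.T @ ratio
    den = S.sum(axis=0)[:, None]
    if segregation_bias > 0:
        # penalty beta * sum_n sum_{k != l} a_kn a_ln discourages co-localised
        # components; its gradient beta * (total_n - a_kn) joins the denominator
        den = den + segregation_bias * (A.sum(axis=0, keepdims=True) - A)
    A *= num / (den + _EPS)
    return A


def _prepare(stack: LambdaStack, params: UnmixParams):
    C = stack.grid.n_channels
    bg_mask, sat_mask = pixel_masks(stack, params)
    Y = stack.counts.reshape(C, -1).astype(float)
    usable = ~bg_mask.ravel()
    bspec = None
    if params.background_spectrum_mode == "minimal-values":
        bspec = background_spectrum(stack, sat_mask)
    return Y, usable, bg_mask, sat_mask, bspec


def _finish(A: np.ndarray, K: int, usable: np.ndarray, shape, names,
            bg_mask, sat_mask, history=None) -> AbundanceMaps:
    out = np.zeros((K, usable.size), dtype=float)
    out[:, usable] = A[:K]
    return AbundanceMaps(out.reshape(K, *shape), list(names), bg_mask, sat_mask,
                         objective_history=history)


def unmix_fixed(stack: LambdaStack, refs: ReferenceSet,
                params: UnmixParams | None = None, *,
                record_objective: bool = False) -> AbundanceMaps:
    """Fixed-reference decomposition: abundances only, multiplicative KL updates.

    References are unit-area normalised internally and must live on the
    stack's grid (resample first otherwise).  The optional minimal-values
    background spectrum joins the basis as a fixed extra column and its
    abundance is dropped from the output.  With ``record_objective`` the KL
    objective is evaluated after each sweep (costs an extra pass per sweep).
    """
    params = params or UnmixParams()
    if refs.grid != stack.grid:
        raise ValueError("reference spectra are not on the stack's channel grid; "
                         "resample them first")
    S = refs.matrix()
    C, K = S.shape
    Y, usable, bg_mask, sat_mask, bspec = _prepare(stack, params)
    if bspec is not None:
        S = np.column_stack([S, bspec / bspec.sum()])
    if S.shape[1] > C:
        raise ValueError(f"{S.shape[1]} components exceed {C} channels")
    if not usable.any():
        warnings.warn("every pixel is below the background threshold; "
                      "returning all-zero abundances", stacklevel=2)
        return _finish(np.zeros((S.shape[1], 0)), K, usable,
                       stack.counts.shape[1:], refs.names, bg_mask, sat_mask)
    Yu = Y[:, usable]
    A = np.full((S.shape[1], Yu.shape[1]), 1.0) * (Yu.sum(axis=0) / S.shape[1])
    history: list | None = [] if record_objective else None
    for _ in range(params.n_iterations):
        _update_abundances(S, Yu, A, params.segregation_bias)
        if history is not None:
            history.append(kl_divergence(Yu, S @ A + _EPS))
    return _finish(A, K, usable, stack.counts.shape[1:], refs.names,
                   bg_mask, sat_mask, history=history)


def unmix_blind(stack: LambdaStack, n_components: int,
                params: UnmixParams | None = None) -> tuple:
    """Blind decomposition: alternating multiplicative KL updates of spectra
    and abundances.

    Spectra are initialised from randomly chosen usable seed pixels
    (channel-smoothed), abundances uniformly.  Each sweep updates all-pixel
    abundances, then the spectra using every ``subsample_stride``-th usable
    pixel, renormalises spectra to unit area (pushing scale into the
    abundances) and records the KL objective over the spectrum-update pixel
    set — the quantity the coupled updates provably never increase (the
    full-image objective when the stride is 1).  Deterministic given the seed.
    Returns ``(discovered_references, abundance_maps)`` with components in
    discovered order (no canonical ordering is attempted).
    """
    params = params or UnmixParams()
    C = stack.grid.n_channels
    if not 1 <= n_components <= C:
        raise ValueError(f"n_components must be in [1, {C}], got {n_components}")
    Y, usable, bg_mask, sat_mask, bspec = _prepare(stack, params)
    update_ok = usable & ~sat_mask.ravel()
    if int(update_ok.sum()) < n_components:
        raise ValueError(f"only {int(update_ok.sum())} usable pixels for "
                         f"{n_components} components")

    from scipy.ndimage import uniform_filter1d

    rng = np.random.default_rng(params.seed)
    seed_px = rng.choice(np.flatnonzero(update_ok), size=n_components, replace=False)
    S = Y[:, seed_px].copy()
    S = uniform_filter1d(S, size=3, axis=0, mode="nearest")
    S = np.clip(S, _EPS, None)
    S /= S.sum(axis=0, keepdims=True)
    n_free = n_components
    if bspec is not None:
        S = np.column_stack([S, bspec / bspec.sum()])
    if S.shape[1] > C:
        raise ValueError(f"{S.shape[1]} components exceed {C} channels")

    Yu = Y[:, usable]
    A = np.full((S.shape[1], Yu.shape[1]), 1.0) * (Yu.sum(axis=0) / S.shape[1])
    # spectrum updates use a strided subsample of the non-background,
    # non-saturated pixels; abundance updates always use every usable pixel
    sub = np.flatnonzero(update_ok[usable])[:: params.subsample_stride]
    history: list = []
    for _ in range(params.n_iterations):
        _update_abundances(S, Yu, A, params.segregation_bias)
        Ys, As = Yu[:, sub], A[:, sub]
        model = S @ As
        num = (Ys / (model + _EPS)) @ As.T
        den = As.sum(axis=1)
        S[:, :n_free] *= num[:, :n_free] / (den[None, :n_free] + _EPS)
        S[:, :n_free] = np.clip(S[:, :n_free], _EPS, None)
        scale = S[:, :n_free].sum(axis=0)
        S[:, :n_free] /= scale
        A[:n_free] *= scale[:, None]
        # the objective both update steps provably descend: abundance updates
        # decrease every pixel's KL term individually, spectrum updates
        # decrease the KL over the subsampled pixels; at stride 1 this is the
        # full-image objective
        history.append(kl_divergence(Yu[:, sub], S @ A[:, sub] + _EPS))

    names = [f"component_{k + 1}" for k in range(n_components)]
    grid = stack.grid
    discovered = ReferenceSet(tuple(
        EmissionSpectrum(grid, S[:, k], name=names[k]) for k in range(n_components)
    ))
    maps = _finish(A, n_components, usable, stack.counts.shape[1:], names,
                   bg_mask, sat_mask, history=history)
    return discovered, maps
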