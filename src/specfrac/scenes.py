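"""Ground-truthed synthetic lambda-stack scenes.

Every downstream stage (unmixing, fraction mapping, band ratios) is tested
against phantoms whose per-pixel component abundances are exactly known.
Scenes follow the acquisition geometry of a two-photon spectral microscope:
100 nm pixels, 9.8 nm channels starting at 418 nm, and Poisson shot noise.

Geometry is deliberately simple — filled disks and annuli — so the truth
maps are exact by construction.  The expected (noiseless) stack always obeys
the linear mixing identity ``expected[c] = sum_k abundance[k] * spectrum[c, k]``
with unit-area spectra, so a component's abundance is its total expected
photon count at that pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .spectral import ChannelGrid, ReferenceSet

__all__ = [
    "LambdaStack",
    "ScenePhantom",
    "make_mlv_scene",
    "make_cell_scene",
    "make_two_dye_scene",
    "add_poisson_noise",
]

#: compartment label codes used by the cell-like phantoms
CELL_LABELS = {"background": 0, "plasma_membrane": 1, "cytoplasm": 2,
               "droplet": 3, "nucleus": 4, "internal_membrane": 5}


@dataclass
class LambdaStack:
    """A (channels, H, W) nonnegative image stack with its spectral grid.

    ``counts`` are integers for acquired/noised stacks and floats for
    noiseless expected stacks.
    """

    counts: np.ndarray
    grid: ChannelGrid
    pixel_size_nm: float = 100.0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 3:
            raise ValueError(f"counts must be (channels, H, W), got shape {c.shape}")
        if c.shape[0] != self.grid.n_channels:
            raise ValueError(f"stack has {c.shape[0]} channels but grid declares "
                             f"{self.grid.n_channels}")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        self.counts = c

    @property
    def shape(self):
        return self.counts.shape

    def channel_sum(self) -> np.ndarray:
        """Total intensity image (sum over channels)."""
        return self.counts.sum(axis=0)


@dataclass
class ScenePhantom:
    """Ground truth behind a synthetic stack.

    ``true_abundances`` is (components, H, W) in expected-photon units;
    ``compartments`` (when present) labels each pixel with a code from
    :data:`CELL_LABELS`.
    """

    true_abundances: np.ndarray
    component_names: list
    references: ReferenceSet
    pixel_size_nm: float
    seed: int
    params: dict = field(default_factory=dict)
    compartments: np.ndarray | None = None

    def compartment_mask(self, label: str) -> np.ndarray:
        if self.compartments is None:
            raise ValueError("this phantom has no compartment labels")
        return self.compartments == CELL_LABELS[label]

    def true_fraction(self, component: int = 0) -> np.ndarray:
        """Ground-truth fractional abundance of one component (NaN where empty)."""
        total = self.true_abundances.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, self.true_abundances[component] / total, np.nan)


def _expected_stack(abundances: np.ndarray, refs: ReferenceSet,
                    background_level: float = 0.0, blur_sigma: float = 0.0) -> np.ndarray:
    S = refs.matrix()  # (C, K), unit-area columns
    expected = np.einsum("ck,khw->chw", S, abundances) + background_level
    if blur_sigma > 0:
        expected = ndimage.gaussian_filter(expected, sigma=(0, blur_sigma, blur_sigma))
    return expected


def _disk_mask(shape, center, radius) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _place_disjoint_disks(rng, shape, n, radius, *, allowed=None, max_tries=500):
    """Centres of ``n`` non-overlapping disks, optionally confined to a mask."""
    centers = []
    for _ in range(n):
        for _try in range(max_tries):
            cy = rng.uniform(radius + 1, shape[0] - radius - 1)
            cx = rng.uniform(radius + 1, shape[1] - radius - 1)
            if allowed is not None:
                disk = _disk_mask(shape, (cy, cx), radius + 1)
                if not allowed[disk].all():
                    continue
            if all((cy - oy) ** 2 + (cx - ox) ** 2 > (2 * radius + 2) ** 2
                   for oy, ox in centers):
                centers.append((cy, cx))
                break
        else:
            raise RuntimeError(f"could not place {n} disjoint disks of radius "
                               f"{radius} in a {shape} image")
    return centers


def make_mlv_scene(grid: ChannelGrid, n_vesicles: int, component_spectra: ReferenceSet,
                   intensity_scale: float = 500.0, seed: int = 0, *,
                   shape: tuple = (64, 64), vesicle_radius_px: float = 6.0,
                   pixel_size_nm: float = 100.0,
                   background_level: float = 0.0) -> tuple:
    """Vesicle phantom: disjoint filled disks, each carrying one pure component.

    Mirrors reference-spectrum acquisition on multilamellar vesicles of
    defined composition: averaging the noiseless stack over one vesicle and
    normalising to unit area recovers the assigned reference spectrum
    exactly.  Components are assigned to vesicles round-robin.  Returns the
    noiseless expected stack and the phantom truth.
    """
    if n_vesicles < 1:
        raise ValueError("n_vesicles must be >= 1")
    if component_spectra.grid != grid:
        raise ValueError("component spectra must be defined on the scene grid")
    rng = np.random.default_rng(seed)
    K = len(component_spectra)
    abundances = np.zeros((K, *shape), dtype=float)
    centers = _place_disjoint_disks(rng, shape, n_vesicles, vesicle_radius_px)
    for i, c in enumerate(centers):
        abundances[i % K][_disk_mask(shape, c, vesicle_radius_px)] = intensity_scale
    expected = _expected_stack(abundances, component_spectra, background_level)
    stack = LambdaStack(expected, grid, pixel_size_nm)
    phantom = ScenePhantom(
        true_abundances=abundances, component_names=component_spectra.names,
        references=component_spectra, pixel_size_nm=pixel_size_nm, seed=seed,
        params=dict(kind="mlv", n_vesicles=n_vesicles, intensity_scale=intensity_scale,
                    shape=tuple(shape), vesicle_radius_px=vesicle_radius_px,
                    background_level=background_level),
    )
    return stack, phantom


def make_cell_scene(grid: ChannelGrid, *, pm_apolar_fraction: float = 0.75,
                    cytoplasm_apolar_fraction: float = 0.30,
                    droplet_apolar_fraction: float = 0.95,
                    shape: tuple = (512, 512), pixel_size_nm: float = 100.0,
                    references: ReferenceSet | None = None,
                    pm_thickness_px: int = 2, n_droplets: int = 8,
                    droplet_radius_px: float = 5.0,
                    pm_total: float = 500.0, cytoplasm_total: float = 250.0,
                    droplet_total: float = 900.0,
                    background_level: float = 0.0, blur_sigma: float = 0.0,
                    seed: int = 0) -> tuple:
    """Single-cell phantom with the compartment polarities seen in live cells.

    An annular plasma membrane (default thickness 2 px at 100 nm/px), a
    cytoplasm, bright apolar lipid droplets and an empty nucleus.  Each
    compartment is a two-component mixture at its configured apolar
    fraction; the PM default of 0.75 reflects the literature estimate that
    about three quarters of the plasma membrane is in ordered domains, while
    the cytoplasm (0.30) and droplet (0.95) defaults are plausible
    placeholders for the polar intracellular membranes and the very apolar
    droplet core.  Returns the noiseless expected stack and the phantom.
    """
    for name, f in (("pm", pm_apolar_fraction), ("cytoplasm", cytoplasm_apolar_fraction),
                    ("droplet", droplet_apolar_fraction)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name}_apolar_fraction must be in [0, 1], got {f}")
    refs = references if references is not None else _default_two_state(grid)
    if len(refs) != 2:
        raise ValueError("cell scene needs exactly two reference components")
    if refs.grid != grid:
        raise ValueError("references must be defined on the scene grid")

    m = min(shape)
    cell_r = 0.42 * m
    nucleus_r = 0.30 * cell_r
    pm_inner_r = cell_r - pm_thickness_px
    if pm_inner_r <= nucleus_r + 2 * droplet_radius_px + 4:
        raise ValueError(f"geometry does not fit a {shape} image: cytoplasm too thin")

    center = (shape[0] / 2.0, shape[1] / 2.0)
    cell = _disk_mask(shape, center, cell_r)
    interior = _disk_mask(shape, center, pm_inner_r)
    nucleus = _disk_mask(shape, center, nucleus_r)
    pm = cell & ~interior
    cytoplasm = interior & ~nucleus

    labels = np.zeros(shape, dtype=np.uint8)
    labels[pm] = CELL_LABELS["plasma_membrane"]
    labels[cytoplasm] = CELL_LABELS["cytoplasm"]
    labels[nucleus] = CELL_LABELS["nucleus"]

    rng = np.random.default_rng(seed)
    droplet_zone = _disk_mask(shape, center, pm_inner_r - droplet_radius_px - 2) & \
        ~_disk_mask(shape, center, nucleus_r + droplet_radius_px + 2)
    droplet_centers = _place_disjoint_disks(rng, shape, n_droplets, droplet_radius_px,
                                            allowed=droplet_zone)
    droplets = np.zeros(shape, dtype=bool)
    for c in droplet_centers:
        droplets |= _disk_mask(shape, c, droplet_radius_px)
    labels[droplets] = CELL_LABELS["droplet"]

    abundances = np.zeros((2, *shape), dtype=float)
    for mask, frac, total in (
        (labels == CELL_LABELS["plasma_membrane"], pm_apolar_fraction, pm_total),
        (labels == CELL_LABELS["cytoplasm"], cytoplasm_apolar_fraction, cytoplasm_total),
        (labels == CELL_LABELS["droplet"], droplet_apolar_fraction, droplet_total),
    ):
        abundances[0][mask] = frac * total
        abundances[1][mask] = (1.0 - frac) * total

    expected = _expected_stack(abundances, refs, background_level, blur_sigma)
    stack = LambdaStack(expected, grid, pixel_size_nm)
    phantom = ScenePhantom(
        true_abundances=abundances, component_names=refs.names, references=refs,
        pixel_size_nm=pixel_size_nm, seed=seed, compartments=labels,
        params=dict(kind="cell", shape=tuple(shape),
                    pm_apolar_fraction=pm_apolar_fraction,
                    cytoplasm_apolar_fraction=cytoplasm_apolar_fraction,
                    droplet_apolar_fraction=droplet_apolar_fraction,
                    pm_total=pm_total, cytoplasm_total=cytoplasm_total,
                    droplet_total=droplet_total, n_droplets=n_droplets,
                    droplet_radius_px=droplet_radius_px,
                    pm_thickness_px=pm_thickness_px,
                    background_level=background_level, blur_sigma=blur_sigma),
    )
    return stack, phantom


def make_two_dye_scene(grid: ChannelGrid, four_component_refs: ReferenceSet,
                       seed: int = 0, *, shape: tuple = (128, 128),
                       pixel_size_nm: float = 100.0,
                       pm_total: float = 400.0, membrane_total: float = 300.0,
                       droplet_total: float = 800.0,
                       background_level: float = 0.0) -> tuple:
    """Double-stain phantom for four-component decomposition.

    Component order must be (dye1_apolar, dye1_polar, dye2_apolar,
    dye2_polar).  Lipid droplets carry the apolar state of both dyes (both
    probes partition into the very hydrophobic droplet core), internal
    membranes carry the polar states of both dyes, and the plasma membrane
    carries dye1's apolar state only — the red-shifted second dye does not
    detectably stain the PM.  Requires a wide spectral grid (the full
    418-700 nm 29-channel acquisition, or similar) so that the red dye's
    emission actually lands on recorded channels.
    """
    refs = four_component_refs
    if len(refs) != 4:
        raise ValueError(f"two-dye scene requires exactly 4 components, got {len(refs)}")
    if refs.grid != grid:
        raise ValueError("references must be defined on the scene grid")

    m = min(shape)
    cell_r = 0.42 * m
    nucleus_r = 0.30 * cell_r
    pm_thickness = 2
    pm_inner_r = cell_r - pm_thickness
    center = (shape[0] / 2.0, shape[1] / 2.0)
    cell = _disk_mask(shape, center, cell_r)
    interior = _disk_mask(shape, center, pm_inner_r)
    nucleus = _disk_mask(shape, center, nucleus_r)
    pm = cell & ~interior
    cytoplasm = interior & ~nucleus

    rng = np.random.default_rng(seed)
    r_small = max(2.0, m / 32.0)
    zone = _disk_mask(shape, center, pm_inner_r - r_small - 2) & \
        ~_disk_mask(shape, center, nucleus_r + r_small + 2)
    centers = _place_disjoint_disks(rng, shape, 8, r_small, allowed=zone)
    droplets = np.zeros(shape, dtype=bool)
    membranes = np.zeros(shape, dtype=bool)
    for i, c in enumerate(centers):
        (droplets if i % 2 == 0 else membranes)[_disk_mask(shape, c, r_small)] = True
    membranes |= cytoplasm & ~droplets & \
        _disk_mask(shape, center, nucleus_r + 3) & ~nucleus  # perinuclear membranes

    labels = np.zeros(shape, dtype=np.uint8)
    labels[cytoplasm] = CELL_LABELS["cytoplasm"]
    labels[pm] = CELL_LABELS["plasma_membrane"]
    labels[nucleus] = CELL_LABELS["nucleus"]
    labels[membranes] = CELL_LABELS["internal_membrane"]
    labels[droplets] = CELL_LABELS["droplet"]

    abundances = np.zeros((4, *shape), dtype=float)
    abundances[0][pm] = pm_total                       # dye1 apolar only on the PM
    abundances[0][droplets] = droplet_total / 2.0
    abundances[2][droplets] = droplet_total / 2.0
    mem = labels == CELL_LABELS["internal_membrane"]
    abundances[1][mem] = membrane_total / 2.0
    abundances[3][mem] = membrane_total / 2.0

    expected = _expected_stack(abundances, refs, background_level)
    stack = LambdaStack(expected, grid, pixel_size_nm)
    phantom = ScenePhantom(
        true_abundances=abundances, component_names=refs.names, references=refs,
        pixel_size_nm=pixel_size_nm, seed=seed, compartments=labels,
        params=dict(kind="two_dye", shape=tuple(shape), pm_total=pm_total,
                    membrane_total=membrane_total, droplet_total=droplet_total,
                    background_level=background_level),
    )
    return stack, phantom


def add_poisson_noise(expected, seed: int = 0) -> LambdaStack:
    """Independent Poisson shot noise per voxel around the expected counts.

    Accepts a :class:`LambdaStack` (noiseless expected stack).  Reproducible:
    the same seed yields a bit-identical stack.
    """
    if not isinstance(expected, LambdaStack):
        raise TypeError("add_poisson_noise expects a LambdaStack of expected counts")
    lam = np.asarray(expected.counts, dtype=float)
    if not np.all(np.isfinite(lam)) or np.any(lam < 0):
        raise ValueError("expected counts must be finite and nonnegative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam).astype(np.int64)
    return LambdaStack(counts, expected.grid, expected.pixel_size_nm)


def _default_two_state(grid: ChannelGrid) -> ReferenceSet:
    from .spectral import two_state_references

    return two_state_references(grid)
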