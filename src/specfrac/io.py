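"""Readers, writers, run manifests and the end-to-end pipeline.

File dialects
-------------
* Lambda stacks: multi-page TIFF, channel-major pages, 16-bit unsigned for
  count data and 32-bit float for noiseless/derived maps, written with
  ImageJ-style hyperstack metadata so they open correctly in common viewers.
  The channel grid travels in a plain-text YAML sidecar
  (``<stack>.grid.yaml`` with ``start_nm``, ``step_nm``, ``n_channels``,
  ``pixel_size_nm``); on read, an explicit override takes precedence over
  the sidecar, which takes precedence over metadata embedded in the TIFF.
* Spectra: CSV with header ``wavelength_nm,<name1>,<name2>,...``, one row
  per channel centre, UTF-8, ``.`` decimal separator.
* Gates: JSON with ``name`` and ``vertices`` (list of [I1, I2] pairs).
* Every run emits exactly one ``manifest.json`` recording the tool version,
  command, parameters, seeds, input digests and a timestamp; all randomness
  flows from the recorded seeds, so outputs are re-derivable from
  (inputs, manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .fractions import (DiscreteLUT, Gate, colorize_fraction, fraction_map,
                        intensity_histogram_2d)
from .scenes import (LambdaStack, add_poisson_noise, make_cell_scene,
                     make_mlv_scene, make_two_dye_scene)
from .spectral import (ChannelGrid, EmissionSpectrum, ReferenceSet,
                       build_channel_grid, four_component_references,
                       two_state_references)
from .unmix import UnmixParams, unmix_blind, unmix_fixed

__all__ = [
    "read_lambda_stack",
    "write_lambda_stack",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_gate_json",
    "write_outputs",
    "run_pipeline",
]

log = logging.getLogger("specfrac")

GRID_SIDECAR_SUFFIX = ".grid.yaml"


def _sidecar_path(path) -> Path:
    return Path(str(path) + GRID_SIDECAR_SUFFIX)


def write_lambda_stack(stack: LambdaStack, path, *, sidecar: bool = True) -> Path:
    """Write a stack as a channel-major multi-page TIFF plus grid sidecar.

    Integer counts go out as uint16, float (expected/derived) stacks as
    float32.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    counts = stack.counts
    if np.issubdtype(counts.dtype, np.integer):
        if counts.max(initial=0) > np.iinfo(np.uint16).max:
            raise ValueError("counts exceed the 16-bit range")
        data = counts.astype(np.uint16)
    else:
        data = counts.astype(np.float32)
    meta = {"start_nm": stack.grid.start_nm, "step_nm": stack.grid.step_nm,
            "n_channels": stack.grid.n_channels,
            "pixel_size_nm": stack.pixel_size_nm}
    tifffile.imwrite(path, data, imagej=True,
                     metadata={"axes": "CYX", "Info": json.dumps(meta)})
    if sidecar:
        with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
            yaml.safe_dump(meta, fh)
    return path


def _grid_from_mapping(meta: dict) -> ChannelGrid:
    return ChannelGrid(start_nm=float(meta["start_nm"]),
                       step_nm=float(meta["step_nm"]),
                       n_channels=int(meta["n_channels"]))


def read_lambda_stack(path, grid_override: ChannelGrid | None = None) -> LambdaStack:
    """Read a channel-major TIFF stack; grid precedence is
    override > sidecar > embedded metadata."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = np.asarray(tifffile.imread(path))
    data = data.reshape((-1, *data.shape[-2:]))  # drop singleton Z/T axes

    grid = grid_override
    pixel_size = 100.0
    meta = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar, "r", encoding="utf-8") as fh:
            meta = yaml.safe_load(fh)
    else:
        with tifffile.TiffFile(path) as tf:
            info = (tf.imagej_metadata or {}).get("Info")
        if info:
            try:
                meta = json.loads(info)
            except (TypeError, json.JSONDecodeError):
                meta = None
    if meta:
        pixel_size = float(meta.get("pixel_size_nm", 100.0))
        if grid is None:
            grid = _grid_from_mapping(meta)
    if grid is None:
        raise ValueError(f"no channel grid for {path}: provide an override, a "
                         f"{GRID_SIDECAR_SUFFIX} sidecar, or embedded metadata")
    if data.shape[0] != grid.n_channels:
        raise ValueError(f"format error: {path} has {data.shape[0]} channel pages "
                         f"but the grid declares {grid.n_channels}")
    if np.any(data < 0):
        raise ValueError("stack contains negative counts")
    return LambdaStack(data, grid, pixel_size_nm=pixel_size)


def write_spectra_csv(refs: ReferenceSet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"wavelength_nm": refs.grid.centers})
    for s in refs:
        df[s.name] = s.values
    df.to_csv(path, index=False)
    return path


def read_spectra_csv(path, grid: ChannelGrid | None = None) -> ReferenceSet:
    """Read reference spectra; the grid is reconstructed from the wavelength
    column (channel centres, uniform spacing) unless given explicitly."""
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise ValueError(f"{path}: first column must be 'wavelength_nm'")
    centers = df["wavelength_nm"].to_numpy(dtype=float)
    if grid is None:
        if centers.size < 2:
            raise ValueError("cannot infer a grid from a single wavelength row")
        steps = np.diff(centers)
        if not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("wavelength column is not uniformly spaced")
        step = float(steps[0])
        grid = ChannelGrid(start_nm=float(centers[0]) - step / 2.0,
                           step_nm=step, n_channels=centers.size)
    names = [c for c in df.columns if c != "wavelength_nm"]
    if not names:
        raise ValueError(f"{path}: no spectrum columns")
    return ReferenceSet(tuple(
        EmissionSpectrum(grid, df[n].to_numpy(dtype=float), name=n) for n in names
    ))


def read_gate_json(path) -> Gate:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return Gate(vertices=tuple((v[0], v[1]) for v in payload["vertices"]),
                name=payload.get("name", "gate"))


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: Path, command: str, params: dict, seed,
                    inputs: dict | None) -> Path:
    manifest = {
        "tool": "specfrac",
        "version": __version__,
        "command": command,
        "parameters": params,
        "seed": seed,
        "input_digests": {k: _digest(v) for k, v in (inputs or {}).items()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path


def write_outputs(bundle: dict, out_dir, *, command: str = "", params: dict | None = None,
                  seed=None, inputs: dict | None = None) -> dict:
    """Write a bundle of results with deterministic names plus a manifest.

    Dispatch by value type: :class:`LambdaStack` and float arrays to 32-bit
    TIFF, uint8 RGB and boolean masks to PNG, DataFrames and reference sets
    to CSV, plain mappings to JSON.  Returns ``{name: path}`` including the
    manifest, which is always written (an empty bundle yields manifest only).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict = {}
    for name in sorted(bundle):
        value = bundle[name]
        if isinstance(value, LambdaStack):
            paths[name] = write_lambda_stack(value, out_dir / f"{name}.tif")
        elif isinstance(value, ReferenceSet):
            paths[name] = write_spectra_csv(value, out_dir / f"{name}.csv")
        elif isinstance(value, pd.DataFrame):
            p = out_dir / f"{name}.csv"
            value.to_csv(p, index=False, float_format="%.4f")
            paths[name] = p
        elif isinstance(value, np.ndarray) and value.dtype == bool:
            p = out_dir / f"{name}.png"
            iio.imwrite(p, (value.astype(np.uint8) * 255))
            paths[name] = p
        elif isinstance(value, np.ndarray) and value.dtype == np.uint8:
            p = out_dir / f"{name}.png"
            iio.imwrite(p, value)
            paths[name] = p
        elif isinstance(value, np.ndarray):
            p = out_dir / f"{name}.tif"
            tifffile.imwrite(p, np.asarray(value, dtype=np.float32))
            paths[name] = p
        elif isinstance(value, dict):
            p = out_dir / f"{name}.json"
            with open(p, "w", encoding="utf-8") as fh:
                json.dump(value, fh, indent=2, sort_keys=True, default=str)
                fh.write("\n")
            paths[name] = p
        else:
            raise TypeError(f"do not know how to write {name!r} "
                            f"({type(value).__name__})")
    paths["manifest"] = _write_manifest(out_dir, command, params or {}, seed, inputs)
    return paths


def save_histogram_png(hist: np.ndarray, xedges: np.ndarray, yedges: np.ndarray,
                       path, title: str = "2D intensity histogram") -> Path:
    """Render a frequency-colour-coded 2D intensity histogram to PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.2))
    mesh = ax.pcolormesh(xedges, yedges, hist.T, cmap="viridis")
    fig.colorbar(mesh, ax=ax, label="pixels")
    ax.set_xlabel("component 1 intensity")
    ax.set_ylabel("component 2 intensity")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _parse_grid(cfg: dict) -> ChannelGrid:
    if "n_channels" in cfg:
        return _grid_from_mapping(cfg)
    return build_channel_grid(cfg["start_nm"], cfg["end_nm"], cfg["step_nm"])


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _make_scene(scene_cfg: dict, seed: int):
    kind = scene_cfg.get("kind", "cell")
    grid = _parse_grid(scene_cfg.get("grid", {"start_nm": 418, "end_nm": 584,
                                              "step_nm": 9.8}))
    params = dict(scene_cfg.get("params", {}))
    if "shape" in params:
        params["shape"] = tuple(params["shape"])
    if kind == "cell":
        stack, phantom = make_cell_scene(grid, seed=seed, **params)
        refs = phantom.references
    elif kind == "mlv":
        refs = two_state_references(grid)
        n = params.pop("n_vesicles", 4)
        stack, phantom = make_mlv_scene(grid, n, refs, seed=seed, **params)
    elif kind == "two_dye":
        refs = four_component_references(grid)
        stack, phantom = make_two_dye_scene(grid, refs, seed=seed, **params)
    else:
        raise ValueError(f"unknown scene kind {kind!r}")
    if scene_cfg.get("noise", "none") == "poisson":
        stack = add_poisson_noise(stack, seed=seed + 1)
    return stack, phantom, refs


def run_pipeline(config, out_dir=None, seed: int | None = None) -> dict:
    """Run synth (optional) -> unmix -> fraction map -> render and write outputs.

    ``config`` is a mapping or a path to a YAML file; see the package README
    for the schema.  Returns a dict with the written ``paths`` and the key
    in-memory results (stack, abundances, fraction map, phantom when
    synthetic).  Raises a stage-named error on the first failure; a fixed-
    mode config with a file stack but no reference spectra fails validation
    before any computation.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    out_dir = Path(out_dir or cfg.get("out", "specfrac_out"))

    unmix_cfg = dict(cfg.get("unmix", {}))
    mode = unmix_cfg.pop("mode", "fixed")
    n_components = int(unmix_cfg.pop("n_components", 2))
    if mode not in ("fixed", "blind"):
        raise ValueError(f"config: unmix mode must be 'fixed' or 'blind', got {mode!r}")
    if "scene" not in cfg and "stack" not in cfg:
        raise ValueError("config: provide either a 'scene' or a 'stack'")
    if mode == "fixed" and "scene" not in cfg and "refs" not in cfg:
        raise ValueError("config: fixed-mode unmixing of a file stack requires "
                         "a 'refs' spectra CSV")

    phantom = None
    if "scene" in cfg:
        stack, phantom, refs = _make_scene(cfg["scene"], seed)
        log.info("synth: %s scene %s, %d channels", cfg["scene"].get("kind", "cell"),
                 stack.counts.shape[1:], stack.grid.n_channels)
    else:
        grid_override = _parse_grid(cfg["grid"]) if "grid" in cfg else None
        stack = read_lambda_stack(cfg["stack"], grid_override)
        refs = read_spectra_csv(cfg["refs"], grid=stack.grid) if "refs" in cfg else None
        log.info("load: %s, %d channels", cfg["stack"], stack.grid.n_channels)
    if "refs" in cfg and "scene" in cfg:
        refs = read_spectra_csv(cfg["refs"], grid=stack.grid)

    params = UnmixParams(seed=seed, **unmix_cfg)
    if mode == "fixed":
        maps = unmix_fixed(stack, refs, params)
        discovered = None
    else:
        discovered, maps = unmix_blind(stack, n_components, params)
    log.info("unmix(%s): %d components, %d background / %d saturated of %d pixels",
             mode, maps.n_components, int(maps.background_mask.sum()),
             int(maps.saturation_mask.sum()), maps.background_mask.size)

    result = {"stack": stack, "abundances": maps, "phantom": phantom,
              "references": discovered if discovered is not None else refs}
    bundle: dict = {"abundances": maps.values,
                    "background_mask": maps.background_mask,
                    "saturation_mask": maps.saturation_mask}
    if discovered is not None:
        bundle["discovered_spectra"] = discovered
    elif refs is not None:
        bundle["reference_spectra"] = refs

    frac_cfg = dict(cfg.get("fraction", {}))
    if maps.n_components == 2:
        fmap = fraction_map(maps)
        lut_cfg = frac_cfg.get("lut", "default")
        lut = (DiscreteLUT.six_colours_233332() if lut_cfg in ("default", None)
               else DiscreteLUT.from_file(lut_cfg))
        ceiling = frac_cfg.get("ceiling", "auto")
        rgb = colorize_fraction(fmap, lut, ceiling)
        hist, xe, ye = intensity_histogram_2d(maps, n_bins=int(frac_cfg.get("n_bins", 64)),
                                              scale=frac_cfg.get("scale", "linear"))
        result["fraction_map"] = fmap
        bundle["fraction_map"] = fmap.fraction.astype(np.float32)
        bundle["fraction_rgb"] = rgb
        bundle["histogram_2d"] = pd.DataFrame(hist)
        n_def = int(fmap.defined.sum())
        log.info("fraction: %d defined pixels, median %.4f", n_def,
                 float(np.nanmedian(fmap.fraction)) if n_def else float("nan"))
    else:
        log.info("fraction: skipped (%d components)", maps.n_components)

    inputs = {k: cfg[k] for k in ("stack", "refs") if k in cfg}
    paths = write_outputs(bundle, out_dir, command="pipeline", params=cfg,
                          seed=seed, inputs=inputs)
    if maps.n_components == 2:
        paths["histogram_png"] = save_histogram_png(hist, xe, ye,
                                                    out_dir / "histogram_2d.png")
    result["paths"] = paths
    return result
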