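"""Helper functionality around the simulator: synthetic bead samples,
convolution with a PSF, TIFF export with embedded parameters, and batch
parameter sweeps."""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import signal

from .config import SimulationConfig, set_by_path, validate
from .integrator import PSFVolume, psf_metrics, simulate_psf

__all__ = [
    "SyntheticSample",
    "SweepSpec",
    "generate_sample",
    "convolve",
    "export_tiff",
    "load_tiff",
    "run_sweep",
    "load_phase_mask",
]


@dataclass
class SyntheticSample:
    """Specification of an artificial point sample.

    ``size_um`` are full physical extents (x, y, z) in micrometers (kept as
    metadata for pitch bookkeeping), ``shape`` the voxel counts, and
    ``n_points`` single-voxel unit-intensity emitters placed uniformly at
    random (collisions re-drawn, reproducible from ``seed``).  ``structure``
    optionally adds a deterministic test pattern in the central z slab.
    """

    shape: tuple[int, int, int] = (100, 100, 10)
    size_um: tuple[float, float, float] = (100.0, 100.0, 10.0)
    n_points: int = 1000
    seed: int = 0
    structure: Optional[str] = None  # None | "line_grid" | "concentric_circles"
    bead_radius: int = 0  # voxels; 0 = single-voxel points


def generate_sample(spec: SyntheticSample) -> np.ndarray:
    """Generate the synthetic sample volume (float64, shape = spec.shape).

    Emitters are unit-intensity voxels at seeded uniform-random positions;
    drawing more points than voxels is an error.
    """
    nx, ny, nz = spec.shape
    n_vox = nx * ny * nz
    if spec.n_points > n_vox:
        raise ValueError(f"n_points={spec.n_points} exceeds voxel count {n_vox}")
    rng = np.random.default_rng(spec.seed)
    vol = np.zeros(spec.shape)
    # draw without replacement over flattened indices: exactly n_points voxels
    flat = rng.choice(n_vox, size=spec.n_points, replace=False)
    vol.ravel()[flat] = 1.0

    if spec.structure == "line_grid":
        k = nz // 2
        step = max(nx // 10, 2)
        vol[::step, :, k] = 1.0
        vol[:, ::step, k] = 1.0
    elif spec.structure == "concentric_circles":
        k = nz // 2
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
        yy, xx = np.meshgrid(np.arange(ny), np.arange(nx))
        r = np.hypot(xx - cx, yy - cy)
        for radius in np.arange(min(nx, ny) / 10.0, min(nx, ny) / 2.0,
                                min(nx, ny) / 10.0):
            vol[np.abs(r - radius) < 0.5, k] = 1.0
    elif spec.structure is not None:
        raise ValueError(f"unknown structure {spec.structure!r}")

    if spec.bead_radius > 0:
        from scipy import ndimage

        ball = _ball(spec.bead_radius)
        vol = np.minimum(ndimage.grey_dilation(vol, footprint=ball), 1.0)
    return vol


def _ball(radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return (x**2 + y**2 + z**2) <= radius**2


def convolve(sample: np.ndarray, psf) -> np.ndarray:
    """Linear 3-D convolution of a sample volume with a PSF, zero-padded
    edges, output cropped to the sample shape.

    The PSF voxel pitch is taken to match the sample pitch (caller's
    responsibility; check metadata when loading from TIFF).
    """
    kernel = psf.intensity if isinstance(psf, PSFVolume) else np.asarray(psf)
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 3 or kernel.ndim != 3:
        raise ValueError("convolve expects two 3-D volumes")
    return signal.fftconvolve(sample, kernel, mode="same")


def export_tiff(volume, path, config=None, extra_metadata: dict | None = None) -> None:
    """Write a volume as a 32-bit float multi-page TIFF, axis order Z, Y, X,
    with the full parameter snapshot serialized as JSON in the image
    description tag.  Values are stored in float32; reading the file back
    restores the written pages bit-exactly and the config losslessly.
    """
    if isinstance(volume, PSFVolume):
        data = volume.intensity
        meta = dict(volume.provenance or {})
        meta.setdefault("normalized", volume.normalized)
        grid = volume.grid
        meta.setdefault(
            "pitch_nm",
            {
                "x": 2 * grid.extent_xy / max(grid.nx - 1, 1),
                "y": 2 * grid.extent_xy / max(grid.ny - 1, 1),
                "z": 2 * grid.extent_z / max(grid.nz - 1, 1),
            },
        )
    else:
        data = np.asarray(volume)
        meta = {}
    if config is not None:
        meta["config"] = validate(config).model_dump(mode="json")
    if extra_metadata:
        meta.update(extra_metadata)
    if not np.all(np.isfinite(data)):
        raise ValueError("refusing to export non-finite volume")
    # (x, y, z) in memory -> (z, y, x) pages on disk
    pages = np.transpose(data, (2, 1, 0)).astype(np.float32)
    # shaped=False: the description tag holds our own JSON, not tifffile's
    # shaped-series metadata
    tifffile.imwrite(path, pages, photometric="minisblack", shaped=False,
                     description=json.dumps(meta))


def load_tiff(path) -> tuple[np.ndarray, dict]:
    """Read a volume written by :func:`export_tiff`; returns the (x, y, z)
    float32 array and the metadata dict (empty if none embedded)."""
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if pages.ndim == 2:
        pages = pages[None]
    return np.transpose(pages, (2, 1, 0)), meta


def load_phase_mask(path) -> np.ndarray:
    """Load a custom phase mask: a single-page float TIFF or a plain-text
    matrix of phase values (radians) on a square pupil grid spanning the
    pupil square [-1, 1]^2."""
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        mask = tifffile.imread(path).astype(float)
    else:
        mask = np.loadtxt(path)
    if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
        raise ValueError("custom phase mask must be a square 2-D matrix")
    return mask


@dataclass
class SweepSpec:
    """One- or two-parameter batch sweep over dotted config keys.

    ``parameters`` holds 1 or 2 (name, values) pairs, e.g.
    ``[("system.na", [0.8, 1.0, 1.2])]``; every combination is simulated and
    all :func:`psf_metrics` columns are recorded.
    """

    parameters: Sequence[tuple[str, Sequence[float]]]
    metric: Optional[str] = None  # restrict output to one metric column
    max_combinations: int = 1000


def run_sweep(base, sweep: SweepSpec,
              evaluate: Callable[[SimulationConfig], PSFVolume] | None = None,
              csv_path=None) -> pd.DataFrame:
    """Run the Cartesian product of the sweep values and tabulate metrics.

    *evaluate* maps a config to a PSF volume (default: full simulation via
    :func:`simulate_psf`); rows follow lexicographic order in the given
    value lists, so a single-value sweep reproduces the base run exactly.
    If *csv_path* is given the table is also written as CSV (comma
    separator, header row, '.' decimal).
    """
    if not (1 <= len(sweep.parameters) <= 2):
        raise ValueError("sweep supports one or two parameters")
    for name, values in sweep.parameters:
        if len(values) == 0:
            raise ValueError(f"empty value list for sweep parameter {name!r}")
    n_comb = int(np.prod([len(v) for _, v in sweep.parameters]))
    if n_comb > sweep.max_combinations:
        raise ValueError(
            f"{n_comb} combinations exceed the cap {sweep.max_combinations}"
        )
    evaluate = evaluate or simulate_psf
    # plain-dict bases (with a custom evaluate) support sweeping quantities
    # outside the simulation config, e.g. the STED saturation factor
    plain = isinstance(base, dict) and evaluate is not simulate_psf
    if not plain:
        base = validate(base)

    names = [name for name, _ in sweep.parameters]
    rows = []
    for combo in itertools.product(*(values for _, values in sweep.parameters)):
        cfg = dict(base) if plain else base
        for name, value in zip(names, combo):
            if plain:
                node = cfg
                parts = name.split(".")
                for p in parts[:-1]:
                    node = node.setdefault(p, {})
                node[parts[-1]] = value
            else:
                cfg = set_by_path(cfg, name, value)
        metrics = psf_metrics(evaluate(cfg))
        metrics.pop("argmax", None)
        row = dict(zip(names, combo))
        if sweep.metric is not None:
            if sweep.metric not in metrics:
                raise KeyError(f"unknown metric {sweep.metric!r}")
            row[sweep.metric] = metrics[sweep.metric]
        else:
            row.update(metrics)
        rows.append(row)
    table = pd.DataFrame(rows)
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    return table
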