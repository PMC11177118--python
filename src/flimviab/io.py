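"""Dataset reading and writing.

On-disk layout of one simulated (or measured) fragment dataset:

* ``<stem>_nadh.tif`` / ``<stem>_fad.tif`` — decay cubes as multi-page
  TIFF, one page per time bin, 16-bit counts;
* ``<stem>_irf.tif`` — the IRF measurement, same format;
* ``<stem>_pi.tif`` — the extrinsic-label intensity image (32-bit int);
* ``<stem>_acquisition.json`` — the acquisition sidecar (period, bins,
  IRF parameters, seed);
* ``<stem>_centroids.csv`` — nucleus centroids (cell_id, row, col);
* ``<stem>_truth_cells.csv`` / ``<stem>_truth_*.tif`` — simulator ground
  truth (per-cell states; float32 fraction maps).

All images are row-major with 0-based pixel coordinates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import tifffile

from .config import AcquisitionConfig
from .pipeline import FragmentData
from .simulate import DecayImage, FragmentLayout, GroundTruth

__all__ = ["write_dataset", "read_dataset", "write_mask", "write_metric_map",
           "write_kde_csv", "write_manifest", "file_checksum"]


def _write_cube(path: Path, cube: np.ndarray) -> None:
    data = np.clip(np.rint(cube), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")


def write_dataset(outdir: str | Path, data: FragmentData,
                  config: AcquisitionConfig, stem: str = "fragment") -> Path:
    """Write a fragment dataset; returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_cube(outdir / f"{stem}_nadh.tif", data.decay_nadh.counts)
    _write_cube(outdir / f"{stem}_fad.tif", data.decay_fad.counts)
    _write_cube(outdir / f"{stem}_irf.tif", data.irf.counts)
    tifffile.imwrite(outdir / f"{stem}_pi.tif",
                     np.asarray(data.pi_image, dtype=np.int32))
    with open(outdir / f"{stem}_acquisition.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2)
    pd.DataFrame({
        "cell_id": np.arange(1, len(data.centroids) + 1),
        "row": data.centroids[:, 0], "col": data.centroids[:, 1],
    }).to_csv(outdir / f"{stem}_centroids.csv", index=False)
    if data.layout is not None:
        tifffile.imwrite(outdir / f"{stem}_mask.tif",
                         data.layout.mask.astype(np.uint8) * 255)
    if data.truth is not None:
        truth = data.truth
        pd.DataFrame({
            "cell_id": np.arange(1, len(truth.cell_state) + 1),
            "cell_state": truth.cell_state,
            "pi_positive": truth.pi_positive,
        }).to_csv(outdir / f"{stem}_truth_cells.csv", index=False)
        tifffile.imwrite(outdir / f"{stem}_truth_free_nadh.tif",
                         truth.free_fraction_nadh.astype(np.float32))
        tifffile.imwrite(outdir / f"{stem}_truth_free_fad.tif",
                         truth.free_fraction_fad.astype(np.float32))
    return outdir


def read_dataset(outdir: str | Path, stem: str = "fragment",
                 fragment_id: str = "", timepoint: str = "t0") -> Tuple[
                     FragmentData, AcquisitionConfig]:
    """Read a dataset written by :func:`write_dataset`."""
    outdir = Path(outdir)
    with open(outdir / f"{stem}_acquisition.json") as fh:
        config = AcquisitionConfig(**json.load(fh))
    period = config.period_ns

    def cube(name: str, channel: str) -> DecayImage:
        arr = tifffile.imread(outdir / f"{stem}_{name}.tif").astype(float)
        if arr.ndim == 2:
            arr = arr[None]
        return DecayImage(counts=arr, period_ns=period, channel=channel)

    cents = pd.read_csv(outdir / f"{stem}_centroids.csv")
    centroids = cents[["row", "col"]].to_numpy(dtype=int)
    pi = tifffile.imread(outdir / f"{stem}_pi.tif").astype(np.int64)

    layout = None
    truth = None
    mask_path = outdir / f"{stem}_mask.tif"
    truth_path = outdir / f"{stem}_truth_cells.csv"
    if truth_path.exists():
        tcells = pd.read_csv(truth_path)
        state = tcells["cell_state"].to_numpy(dtype=object)
        truth = GroundTruth(
            free_fraction_nadh=tifffile.imread(
                outdir / f"{stem}_truth_free_nadh.tif").astype(float),
            free_fraction_fad=tifffile.imread(
                outdir / f"{stem}_truth_free_fad.tif").astype(float),
            cell_state=state,
            pi_positive=tcells["pi_positive"].to_numpy(dtype=bool))
        if mask_path.exists():
            layout = FragmentLayout(mask=tifffile.imread(mask_path) > 0,
                                    centroids=centroids, cell_state=state)
    data = FragmentData(decay_nadh=cube("nadh", "nadh"),
                        decay_fad=cube("fad", "fad"), pi_image=pi,
                        irf=cube("irf", "irf"), centroids=centroids,
                        layout=layout, truth=truth,
                        fragment_id=fragment_id or stem, timepoint=timepoint)
    return data, config


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(mask, dtype=bool).astype(np.uint8) * 255)


def write_metric_map(path: str | Path, values: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(values, dtype=np.float32))


def write_kde_csv(path: str | Path, grid_points: np.ndarray,
                  density: np.ndarray) -> None:
    pd.DataFrame({"grid": grid_points, "density": density}).to_csv(
        Path(path), index=False)


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(path: str | Path, config: dict, seed: int,
                   inputs: Optional[dict] = None,
                   outputs: Optional[dict] = None) -> None:
    """Run manifest: config, seed, software version, input checksums."""
    from . import __version__

    manifest = {"software": "flimviab", "version": __version__,
                "seed": seed, "config": config,
                "input_checksums": inputs or {}, "outputs": outputs or {}}
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
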