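"""HDF5/TIFF persistence for every pipeline artifact.

HDF5 is the primary container (axis order z, y, x; 0-based indexing);
TIFF stacks are written for interoperability with volume-rendering tools.
Every file self-describes: configuration JSON, seed and voxel size are
stored as attributes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .forward import InterferometerConfig, ProjectionGeometry, SteppingScan
from .phantom import PhantomSpec, PhantomVolumes
from .recon import ReconVolume
from .retrieval import ContrastSinograms
from .segment import SegmentationResult


def _config_json(obj) -> str:
    return json.dumps(dataclasses.asdict(obj), sort_keys=True)


def _config_from_json(cls, text: str):
    return cls(**json.loads(text))


# -- phantom ----------------------------------------------------------------

def save_phantom(path, volumes: PhantomVolumes) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=volumes.labels, compression="gzip")
        for name in ("delta", "beta", "epsilon"):
            f.create_dataset(name, data=getattr(volumes, name), compression="gzip")
        f.attrs["voxel_size"] = volumes.voxel_size
        f.attrs["spec"] = volumes.spec.to_json()


def load_phantom(path) -> PhantomVolumes:
    with h5py.File(path, "r") as f:
        spec = PhantomSpec.from_json(f.attrs["spec"])
        return PhantomVolumes(
            labels=f["labels"][()],
            delta=f["delta"][()],
            beta=f["beta"][()],
            epsilon=f["epsilon"][()],
            voxel_size=float(f.attrs["voxel_size"]),
            spec=spec,
        )


def save_phantom_tiff(directory, volumes: PhantomVolumes) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "labels.tif", volumes.labels.astype(np.uint8),
                     photometric="minisblack")
    for name in ("delta", "beta", "epsilon"):
        tifffile.imwrite(directory / f"{name}.tif",
                         getattr(volumes, name).astype(np.float32),
                         photometric="minisblack")


# -- stepping scan ----------------------------------------------------------

def save_scan(path, scan: SteppingScan) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("sample_frames", data=scan.sample_frames, compression="gzip")
        f.create_dataset("reference_frames", data=scan.reference_frames, compression="gzip")
        f.attrs["config"] = _config_json(scan.config)
        f.attrs["geometry"] = _config_json(scan.geometry)


def load_scan(path) -> SteppingScan:
    with h5py.File(path, "r") as f:
        return SteppingScan(
            sample_frames=f["sample_frames"][()],
            reference_frames=f["reference_frames"][()],
            config=_config_from_json(InterferometerConfig, f.attrs["config"]),
            geometry=_config_from_json(ProjectionGeometry, f.attrs["geometry"]),
        )


# -- contrast sinograms -----------------------------------------------------

def save_sinograms(path, sinos: ContrastSinograms) -> None:
    with h5py.File(path, "w") as f:
        for name in ("attenuation", "dpc", "darkfield"):
            f.create_dataset(name, data=getattr(sinos, name), compression="gzip")
        f.attrs["config"] = _config_json(sinos.config)
        f.attrs["geometry"] = _config_json(sinos.geometry)


def load_sinograms(path) -> ContrastSinograms:
    with h5py.File(path, "r") as f:
        return ContrastSinograms(
            attenuation=f["attenuation"][()],
            dpc=f["dpc"][()],
            darkfield=f["darkfield"][()],
            geometry=_config_from_json(ProjectionGeometry, f.attrs["geometry"]),
            config=_config_from_json(InterferometerConfig, f.attrs["config"]),
        )


# -- reconstructions --------------------------------------------------------

_UNITS = {"mu": "1/mm", "epsilon": "1/mm", "delta": "dimensionless"}


def save_recon(directory, recons: dict[str, ReconVolume]) -> None:
    """One HDF5 bundle plus a 32-bit TIFF stack and JSON sidecar per channel."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with h5py.File(directory / "recon.h5", "w") as f:
        for channel, vol in recons.items():
            ds = f.create_dataset(channel, data=vol.data, compression="gzip")
            ds.attrs["units"] = _UNITS[channel]
        f.attrs["voxel_size"] = next(iter(recons.values())).voxel_size
    for channel, vol in recons.items():
        tifffile.imwrite(directory / f"{channel}.tif", vol.data.astype(np.float32),
                         photometric="minisblack")
        sidecar = {
            "channel": channel,
            "voxel_size_mm": vol.voxel_size,
            "units": _UNITS[channel],
        }
        (directory / f"{channel}.json").write_text(json.dumps(sidecar, indent=2))


def load_recon(directory) -> dict[str, ReconVolume]:
    directory = Path(directory)
    out = {}
    with h5py.File(directory / "recon.h5", "r") as f:
        voxel = float(f.attrs["voxel_size"])
        for channel in f:
            out[channel] = ReconVolume(f[channel][()], channel, voxel)
    return out


# -- segmentation -----------------------------------------------------------

def save_segmentation(path, seg: SegmentationResult) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=seg.labels.astype(np.uint8), compression="gzip")
        f.attrs["voxel_size"] = seg.voxel_size
        f.attrs["provenance"] = json.dumps(seg.provenance)
    tifffile.imwrite(Path(path).with_suffix(".tif"), seg.labels.astype(np.uint8),
                     photometric="minisblack")


def load_segmentation(path) -> SegmentationResult:
    with h5py.File(path, "r") as f:
        return SegmentationResult(
            labels=f["labels"][()],
            provenance=json.loads(f.attrs["provenance"]),
            voxel_size=float(f.attrs["voxel_size"]),
        )


def load_mask(path) -> np.ndarray:
    """Read a boolean mask from a TIFF stack or an HDF5 file ('mask' dataset)."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        return tifffile.imread(path) > 0
    with h5py.File(path, "r") as f:
        return f["mask"][()] > 0
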