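"""Dataset, image and report IO.

Datasets are written as HDF5 with one group per slice
(``/slice_i/{clean,noisy}/{counts,dark,flat}`` plus
``/slice_i/phantom``) and a JSON sidecar carrying the geometry and
generation parameters.  Single images export as 32-bit float TIFF;
tables as CSV; manifests and selections as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .acquisition import PairedDataset, PhotonSinogram, SlicePair
from .geometry import AcquisitionParams, ScanGeometry
from .phantoms import Phantom

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_tiff",
    "load_tiff",
    "write_json",
    "read_json",
]


def _geometry_dict(g: ScanGeometry) -> dict:
    return dataclasses.asdict(g)


def save_dataset(dataset: PairedDataset, path) -> Path:
    """Write a paired dataset to HDF5 with a JSON sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for pair in dataset:
            grp = f.create_group(f"slice_{pair.index}")
            for role, sino in (("clean", pair.clean), ("noisy", pair.noisy)):
                sub = grp.create_group(role)
                sub.create_dataset("counts", data=sino.counts)
                sub.create_dataset("dark", data=sino.dark)
                sub.create_dataset("flat", data=sino.flat)
                sub.attrs["provenance"] = sino.provenance
            grp.create_dataset("phantom", data=pair.phantom.attenuation)
            grp.attrs["pixel_size"] = pair.phantom.pixel_size
    sidecar = {
        "geometry": _geometry_dict(dataset.geometry),
        "surrogate_mode": dataset.surrogate_mode,
        "clean_params": dataclasses.asdict(dataset.clean_params),
        "noisy_params": dataclasses.asdict(dataset.noisy_params),
        "master_seed": dataset.master_seed,
        "n_slices": len(dataset),
    }
    write_json(sidecar, path.with_suffix(path.suffix + ".json"))
    return path


def load_dataset(path) -> PairedDataset:
    """Read a paired dataset written by :func:`save_dataset`."""
    path = Path(path)
    sidecar = read_json(path.with_suffix(path.suffix + ".json"))
    geometry = ScanGeometry(**sidecar["geometry"])
    pairs = []
    with h5py.File(path, "r") as f:
        indices = sorted(int(k.split("_")[1]) for k in f.keys())
        for i in indices:
            grp = f[f"slice_{i}"]
            sinos = {}
            for role in ("clean", "noisy"):
                sub = grp[role]
                sinos[role] = PhotonSinogram(
                    counts=sub["counts"][...],
                    dark=sub["dark"][...],
                    flat=sub["flat"][...],
                    geometry=geometry,
                    provenance=sub.attrs["provenance"],
                )
            phantom = Phantom(
                attenuation=grp["phantom"][...],
                pixel_size=float(grp.attrs["pixel_size"]),
            )
            pairs.append(SlicePair(phantom=phantom, clean=sinos["clean"],
                                   noisy=sinos["noisy"], index=i))
    return PairedDataset(
        pairs=tuple(pairs),
        geometry=geometry,
        surrogate_mode=sidecar["surrogate_mode"],
        clean_params=AcquisitionParams(**sidecar["clean_params"]),
        noisy_params=AcquisitionParams(**sidecar["noisy_params"]),
        master_seed=sidecar["master_seed"],
    )


def save_tiff(values: np.ndarray, path, **metadata) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32),
                     metadata={k: str(v) for k, v in metadata.items()})
    return path


def load_tiff(path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_json(obj, path) -> Path:
    path = Path(path)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default) + "\n")
    return path


def read_json(path):
    return json.loads(Path(path).read_text())
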