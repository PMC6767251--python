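"""Serialisation: float TIFF / NPY rasters and HDF5 dataset bundles."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile

from .geometry import ImageGrid, ScanGeometry, Sinogram
from .phantoms import DeletionWindow, PairedSample

__all__ = ["read_image", "write_image", "read_sinogram", "write_sinogram",
           "save_dataset", "load_dataset"]

_GEOM_FIELDS = ("mode", "n_views", "angular_range_deg", "n_bins", "bin_size",
                "source_to_object", "source_to_detector")


def write_image(path, image: np.ndarray) -> None:
    """32-bit float raster; format chosen by extension (.tif/.tiff or .npy)."""
    path = Path(path)
    arr = np.asarray(image, dtype=np.float32)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".npy":
        np.save(path, arr)
    else:
        raise ValueError(f"unsupported raster format {path.suffix!r}")


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path), dtype=np.float64)
    if path.suffix.lower() == ".npy":
        return np.asarray(np.load(path), dtype=np.float64)
    raise ValueError(f"unsupported raster format {path.suffix!r}")


def write_sinogram(path, sino: Sinogram) -> None:
    write_image(path, sino.values)


def read_sinogram(path, geometry: ScanGeometry,
                  valid_mask: np.ndarray | None = None) -> Sinogram:
    return Sinogram(read_image(path), geometry, valid_mask)


def _geometry_attrs(geometry: ScanGeometry) -> dict:
    return {f: getattr(geometry, f) for f in _GEOM_FIELDS}


def _geometry_from_attrs(attrs) -> ScanGeometry:
    kw = {f: attrs[f] for f in _GEOM_FIELDS}
    kw["mode"] = kw["mode"] if isinstance(kw["mode"], str) else kw["mode"].decode()
    kw["n_views"], kw["n_bins"] = int(kw["n_views"]), int(kw["n_bins"])
    return ScanGeometry(**kw)


def save_dataset(path, samples: list[PairedSample]) -> None:
    """HDF5 bundle: per-sample groups {image, input, label, mask, angles}."""
    if not samples:
        raise ValueError("nothing to save")
    with h5py.File(path, "w") as f:
        for key, val in _geometry_attrs(samples[0].label_sino.geometry).items():
            f.attrs[key] = val
        f.attrs["n_samples"] = len(samples)
        for i, s in enumerate(samples):
            grp = f.create_group(f"samples/{i:06d}")
            grp.create_dataset("image", data=s.source_image.astype(np.float32))
            grp.create_dataset("input", data=s.input_sino.values.astype(np.float32))
            grp.create_dataset("label", data=s.label_sino.values.astype(np.float32))
            grp.create_dataset("mask", data=s.input_sino.valid_mask)
            grp.create_dataset("angles", data=s.input_sino.angles_deg)
            grp.attrs["sino_scale"] = s.sino_scale
            if s.window is not None:
                grp.attrs["window_start_deg"] = s.window.start_deg
                grp.attrs["window_span_deg"] = s.window.span_deg
            for k, v in s.meta.items():
                grp.attrs[f"meta_{k}"] = v


def load_dataset(path) -> list[PairedSample]:
    samples: list[PairedSample] = []
    with h5py.File(path, "r") as f:
        geometry = _geometry_from_attrs(f.attrs)
        for name in sorted(f["samples"]):
            grp = f[f"samples/{name}"]
            mask = np.asarray(grp["mask"], dtype=bool)
            angles = np.asarray(grp["angles"], dtype=np.float64)
            window = None
            if "window_start_deg" in grp.attrs:
                window = DeletionWindow(float(grp.attrs["window_start_deg"]),
                                        float(grp.attrs["window_span_deg"]))
            samples.append(PairedSample(
                input_sino=Sinogram(np.asarray(grp["input"], dtype=np.float64),
                                    geometry, mask, angles),
                label_sino=Sinogram(np.asarray(grp["label"], dtype=np.float64),
                                    geometry, None, angles),
                source_image=np.asarray(grp["image"], dtype=np.float64),
                window=window,
                sino_scale=float(grp.attrs.get("sino_scale", 1.0)),
                meta={k[5:]: v for k, v in grp.attrs.items()
                      if k.startswith("meta_")},
            ))
    return samples
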