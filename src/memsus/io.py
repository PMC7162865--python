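"""Readers and writers for raw RF, images, volumes and reports.

Raw RF uses the toolkit's own format: a little-endian float32 binary of
concatenated line-major frames plus a JSON sidecar (format tag
``sems-us/1``) holding the geometry, transducer, simulation config and
per-frame timestamps.  Images go out as float32 TIFF or 8-bit PNG, volumes
as NIfTI or multi-page TIFF, traces as CSV and reports as JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
import yaml
from imageio.v3 import imwrite as iio_imwrite

from .acoustics import TransducerSpec
from .phantom_sim import RFFrame, RFSequence, SimulationConfig
from .scan_convert import BModeImage
from .scan_geometry import ScanGeometry

__all__ = [
    "FORMAT_TAG",
    "write_rf",
    "read_rf",
    "config_hash",
    "write_provenance",
    "write_bmode_png",
    "write_bmode_tiff",
    "write_volume_nifti",
    "read_volume_nifti",
    "write_volume_tiff",
    "write_trace_csv",
    "write_json_report",
]

FORMAT_TAG = "sems-us/1"


def _canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def config_hash(obj: dict) -> str:
    """sha256 over the canonical JSON form of a config mapping."""
    return hashlib.sha256(_canonical_json(obj).encode()).hexdigest()


def write_rf(path: str | Path, seq: RFSequence) -> tuple[Path, Path]:
    """Write an RF sequence as <path>.bin + <path>.json.

    Samples are stored little-endian float32, line-major, frames
    concatenated in sequence order.  Returns (binary path, sidecar path).
    """
    path = Path(path)
    bin_path = path.with_suffix(".bin")
    json_path = path.with_suffix(".json")
    data = np.concatenate(
        [f.samples.astype("<f4", copy=False).reshape(-1) for f in seq.frames]
    )
    data.tofile(bin_path)
    sidecar = {
        "format": FORMAT_TAG,
        "dtype": "<f4",
        "order": "line-major",
        "n_frames": len(seq.frames),
        "lines_per_frame": seq.geometry.lines_per_frame,
        "samples_per_line": seq.geometry.samples_per_line,
        "frame_indices": [f.frame_index for f in seq.frames],
        "timestamps_s": [f.timestamp for f in seq.frames],
        "transducer": seq.spec.to_yaml_dict(),
        "scan": seq.geometry.to_yaml_dict(),
        "sim": seq.sim.to_yaml_dict(),
        "seed": seq.sim.rng_seed,
    }
    sidecar["config_sha256"] = config_hash(
        {k: sidecar[k] for k in ("transducer", "scan", "sim")}
    )
    json_path.write_text(json.dumps(sidecar, indent=2))
    return bin_path, json_path


def read_rf(path: str | Path) -> RFSequence:
    """Read an RF sequence written by :func:`write_rf` (bit-exact)."""
    path = Path(path)
    json_path = path.with_suffix(".json")
    bin_path = path.with_suffix(".bin")
    sidecar = json.loads(json_path.read_text())
    if sidecar.get("format") != FORMAT_TAG:
        raise ValueError(
            f"unsupported RF format tag {sidecar.get('format')!r}; "
            f"expected {FORMAT_TAG!r}"
        )
    geom = ScanGeometry.from_yaml_dict(sidecar["scan"])
    spec = TransducerSpec.from_yaml_dict(sidecar["transducer"])
    sim = SimulationConfig.from_yaml_dict(sidecar["sim"])
    n = sidecar["n_frames"]
    shape = (n, sidecar["lines_per_frame"], sidecar["samples_per_line"])
    data = np.fromfile(bin_path, dtype="<f4").reshape(shape)
    frames = [
        RFFrame(
            samples=data[i].astype(float),
            geometry=geom,
            timestamp=sidecar["timestamps_s"][i],
            frame_index=sidecar["frame_indices"][i],
        )
        for i in range(n)
    ]
    return RFSequence(frames=frames, geometry=geom, spec=spec, sim=sim)


def write_provenance(path: str | Path, config: dict, seed: int) -> Path:
    """Write a run-provenance JSON (config hash, seed, format version)."""
    import memsus

    path = Path(path)
    payload = {
        "format": FORMAT_TAG,
        "memsus_version": memsus.__version__,
        "seed": seed,
        "config": config,
        "config_sha256": config_hash(config),
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


# -- images -----------------------------------------------------------------

def write_bmode_png(path: str | Path, img: BModeImage) -> Path:
    """8-bit grayscale PNG: [-dynamic_range, 0] dB mapped to [0, 255].

    Pixel rows run along depth (z) and columns along x, the usual display
    orientation.
    """
    path = Path(path)
    dyn = img.dynamic_range
    gray = np.clip((img.pixels + dyn) / dyn, 0.0, 1.0) * 255.0
    iio_imwrite(path, gray.T.astype(np.uint8))
    _write_image_sidecar(path, img)
    return path


def write_bmode_tiff(path: str | Path, img: BModeImage) -> Path:
    path = Path(path)
    tifffile.imwrite(path, img.pixels.T.astype(np.float32))
    _write_image_sidecar(path, img)
    return path


def _write_image_sidecar(path: Path, img: BModeImage) -> None:
    sidecar = {
        "format": FORMAT_TAG,
        "pixel_spacing_m": list(img.pixel_spacing),
        "origin_m": list(img.origin),
        "dynamic_range_db": img.dynamic_range,
        "axes": "rows=z, cols=x",
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )


# -- volumes ----------------------------------------------------------------

def write_volume_nifti(path: str | Path, voxels: np.ndarray,
                       voxel_spacing, offset=(0.0, 0.0, 0.0)) -> Path:
    path = Path(path)
    affine = np.diag([*(s * 1e3 for s in voxel_spacing), 1.0])
    affine[:3, 3] = [o * 1e3 for o in offset]  # mm, NIfTI convention
    nib.save(nib.Nifti1Image(voxels.astype(np.float32), affine), str(path))
    return path


def read_volume_nifti(path: str | Path):
    img = nib.load(str(path))
    voxels = np.asarray(img.dataobj, dtype=np.float32)
    spacing = tuple(float(s) / 1e3 for s in img.header.get_zooms()[:3])
    offset = tuple(float(v) / 1e3 for v in img.affine[:3, 3])
    return voxels, spacing, offset


def write_volume_tiff(path: str | Path, voxels: np.ndarray) -> Path:
    path = Path(path)
    # pages along Y so each page is an XZ B-mode plane
    tifffile.imwrite(path, np.moveaxis(voxels, 1, 0).astype(np.float32))
    return path


# -- traces and reports ------------------------------------------------------

def write_trace_csv(path: str | Path, time_s: np.ndarray,
                    series: np.ndarray, label: str = "value") -> Path:
    path = Path(path)
    header = f"time_s,{label}"
    np.savetxt(path, np.column_stack([time_s, series]), delimiter=",",
               header=header, comments="")
    return path


def write_json_report(path: str | Path, report: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2))
    return path


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(path: str | Path, obj: dict) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
    return path
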