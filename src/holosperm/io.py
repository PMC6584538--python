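"""File formats: float32 multi-page TIFF + JSON sidecars, CSV records.

Tomograms, hologram stacks and phase maps are stored as multi-page TIFF
(pages = z-slices or frames) with a JSON sidecar next to the image file
carrying the physical metadata (voxel size, medium RI, wavelength,
illumination directions, ...).  Round trips are lossless for float32 data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import RITomogram, ValidationError
from .forward import HologramSet
from .morphometry2d import PhaseMap
from .groupstats import records_to_frame

__all__ = [
    "sidecar_path",
    "write_tomogram",
    "read_tomogram",
    "write_hologram_set",
    "read_hologram_set",
    "write_phase_map",
    "read_phase_map",
    "write_records_csv",
    "read_records_csv",
]


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def _read_sidecar(path, required: tuple[str, ...]) -> dict:
    sp = sidecar_path(path)
    if not sp.exists():
        raise ValidationError(
            f"missing sidecar {sp.name}; required keys: {', '.join(required)}"
        )
    meta = json.loads(sp.read_text())
    missing = [k for k in required if k not in meta]
    if missing:
        raise ValidationError(f"sidecar {sp.name} missing keys: {', '.join(missing)}")
    return meta


def _write_sidecar(path, meta: dict) -> None:
    sidecar_path(path).write_text(json.dumps(meta, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_tomogram(path, tomogram: RITomogram) -> None:
    tifffile.imwrite(path, tomogram.values.astype(np.float32), photometric="minisblack")
    _write_sidecar(
        path,
        {
            "kind": "ri_tomogram",
            "voxel_size_um": list(tomogram.voxel_size),
            "medium_ri": tomogram.medium_ri,
            "origin_um": list(tomogram.origin),
            "metadata": _jsonable(tomogram.metadata),
        },
    )


def read_tomogram(path) -> RITomogram:
    meta = _read_sidecar(path, ("voxel_size_um", "medium_ri"))
    values = tifffile.imread(path)
    return RITomogram(
        values,
        tuple(meta["voxel_size_um"]),
        float(meta["medium_ri"]),
        origin=tuple(meta.get("origin_um", (0.0, 0.0, 0.0))),
        metadata=meta.get("metadata", {}),
    )


def write_hologram_set(path, hset: HologramSet) -> None:
    tifffile.imwrite(path, hset.frames.astype(np.float32), photometric="minisblack")
    _write_sidecar(
        path,
        {
            "kind": "hologram_set",
            "illum_dirs": hset.illum_dirs.tolist(),
            "pixel_size_um": hset.pixel_size,
            "wavelength_um": hset.wavelength,
            "medium_ri": hset.medium_ri,
            "carrier_cycles_per_um": list(hset.carrier),
            "metadata": _jsonable(hset.metadata),
        },
    )


def read_hologram_set(path) -> HologramSet:
    meta = _read_sidecar(
        path, ("illum_dirs", "pixel_size_um", "wavelength_um", "medium_ri", "carrier_cycles_per_um")
    )
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return HologramSet(
        frames=frames,
        illum_dirs=np.asarray(meta["illum_dirs"], dtype=float),
        pixel_size=float(meta["pixel_size_um"]),
        wavelength=float(meta["wavelength_um"]),
        medium_ri=float(meta["medium_ri"]),
        carrier=tuple(meta["carrier_cycles_per_um"]),
        metadata=meta.get("metadata", {}),
    )


def write_phase_map(path, pm: PhaseMap) -> None:
    tifffile.imwrite(path, pm.phase.astype(np.float32), photometric="minisblack")
    _write_sidecar(
        path,
        {"kind": "phase_map", "pixel_size_um": pm.pixel_size, "source": pm.source},
    )


def read_phase_map(path) -> PhaseMap:
    meta = _read_sidecar(path, ("pixel_size_um",))
    return PhaseMap(
        phase=tifffile.imread(path),
        pixel_size=float(meta["pixel_size_um"]),
        source=meta.get("source", "measured"),
    )


def write_records_csv(path, records) -> None:
    """Records (list of :class:`MorphometricRecord` or DataFrame) → CSV.

    Columns carry unit suffixes (``volume_um3``, ``dry_mass_pg``, ...).
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.to_csv(path, index=False)


def read_records_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _jsonable(obj):
    try:
        json.dumps(obj, default=_json_default)
        return obj
    except TypeError:
        return {k: str(v) for k, v in obj.items()} if isinstance(obj, dict) else str(obj)
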