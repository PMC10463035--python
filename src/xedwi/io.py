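"""NIfTI, JSON-sidecar and CSV reading/writing.

Every volume writer produces a JSON sidecar carrying the quantities a NIfTI
header cannot (b-values and their units, diffusion time, seeds, config hash),
and every reader validates what it loads before handing it to the rest of the
pipeline.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .data import B_VALUE_UNITS, DWVolumeSet, ParameterMap
from .errors import FormatError

__all__ = [
    "read_dw_series",
    "write_dw_series",
    "read_parameter_map",
    "write_parameter_map",
    "read_table",
    "write_table",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    p = Path(path)
    if not p.exists():
        raise FormatError(f"file not found: {p}")
    img = nib.load(str(p))
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine, dtype=float)


def read_dw_series(source, b_values=None, sidecar=None) -> DWVolumeSet:
    """Read a diffusion-weighted series.

    Parameters
    ----------
    source
        Either a list of per-b-value NIfTI paths (in b-value order) or a
        single 4-D NIfTI path.
    b_values
        Explicit b-value list in s·cm⁻². If omitted, a JSON sidecar is
        consulted (``sidecar`` path, or ``<source>.json`` next to the file).
    """
    if isinstance(source, (str, Path)):
        data, affine = _load_nifti(source)
        if data.ndim == 3:
            data = data[..., None]
        if data.ndim != 4:
            raise FormatError(f"{source}: expected a 4-D volume, got {data.ndim}-D")
        sidecar = Path(sidecar) if sidecar else _sidecar_path(Path(source))
        meta = {}
        if b_values is None:
            if not sidecar.exists():
                raise FormatError(f"no b-values given and no sidecar at {sidecar}")
            meta = json.loads(sidecar.read_text())
            b_values = meta.get("b_values")
            if b_values is None:
                raise FormatError(f"sidecar {sidecar} has no 'b_values' entry")
        elif sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return DWVolumeSet(data, np.asarray(b_values, float), affine, meta=dict(meta))

    paths = [Path(p) for p in source]
    if b_values is None:
        if sidecar is None:
            raise FormatError("b_values (or a sidecar) required with a list of volumes")
        b_values = json.loads(Path(sidecar).read_text())["b_values"]
    b_values = np.asarray(b_values, float)
    if len(paths) != b_values.size:
        raise FormatError(f"{len(paths)} files for {b_values.size} b-values")
    vols, affine = [], None
    for p in paths:
        d, a = _load_nifti(p)
        if d.ndim != 3:
            raise FormatError(f"{p}: expected a 3-D volume per b-value")
        if affine is None:
            affine = a
            shape = d.shape
        elif d.shape != shape:
            raise FormatError(f"{p}: grid shape {d.shape} != {shape} of {paths[0]}")
        elif not np.allclose(a, affine, atol=1e-4):
            raise FormatError(f"{p}: affine differs from {paths[0]}")
        vols.append(d)
    meta = json.loads(Path(sidecar).read_text()) if sidecar and Path(sidecar).exists() else {}
    return DWVolumeSet(np.stack(vols, axis=-1), b_values, affine, meta=dict(meta))


def write_dw_series(dw: DWVolumeSet, out_dir, basename: str = "dwi", fourd: bool = False) -> dict:
    """Write a DW series as NIfTI plus a JSON sidecar.

    With ``fourd=True`` a single 4-D file is written, otherwise one 3-D file
    per b-value (``<basename>_b<value>.nii``). Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    if fourd:
        p = out / f"{basename}.nii"
        nib.save(nib.Nifti1Image(dw.data, dw.affine), str(p))
        written["4d"] = p
    else:
        for i, b in enumerate(dw.b_values):
            p = out / f"{basename}_b{b:g}.nii"
            nib.save(nib.Nifti1Image(dw.data[..., i], dw.affine), str(p))
            written[f"b{b:g}"] = p
    sidecar = out / f"{basename}.json"
    payload = {
        "b_values": [float(b) for b in dw.b_values],
        "b_value_units": B_VALUE_UNITS,
        "voxel_size_mm": [float(v) for v in dw.voxel_size],
        **{k: v for k, v in dw.meta.items() if _jsonable(v)},
    }
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))
    written["sidecar"] = sidecar
    return written


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def write_parameter_map(pmap: ParameterMap, path) -> Path:
    """Write a parameter map as NIfTI; NaN marks invalid voxels.

    The units are recorded in the NIfTI ``descrip`` field and in a JSON
    sidecar together with the valid-voxel count.
    """
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(pmap.data, pmap.affine)
    img.header["descrip"] = f"{pmap.name} [{pmap.units}]".encode()[:79]
    nib.save(img, str(p))
    _sidecar_path(p).write_text(
        json.dumps({"name": pmap.name, "units": pmap.units, "n_valid": pmap.n_valid}, indent=2)
    )
    return p


def read_parameter_map(path) -> ParameterMap:
    data, affine = _load_nifti(path)
    sidecar = _sidecar_path(Path(path))
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        name, units = meta["name"], meta.get("units") or None
    else:  # fall back to the header description "<name> [<units>]"
        descrip = bytes(nib.load(str(path)).header["descrip"]).decode(errors="ignore")
        name = descrip.split("[", 1)[0].strip().strip("\x00")
        units = None
    return ParameterMap(name=name, data=data, affine=affine, units=units)


def read_table(path) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise FormatError(f"file not found: {p}")
    df = pd.read_csv(p)
    if df.columns.str.contains("Unnamed").all():
        raise FormatError(f"{p}: CSV must carry a header row")
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(p, index=False)
    return p
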