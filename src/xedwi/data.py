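"""Core in-memory containers for diffusion-weighted volume sets and parameter maps.

Unit conventions
----------------
* b-values are in **s·cm⁻²** throughout (the hyperpolarised-gas convention).
  Clinical proton DWI usually quotes s·mm⁻²; the conversion factor is 100
  (``b[s·cm⁻²] = b[s·mm⁻²] / 100``).
* Diffusivities (ADC, DDC) are in cm²·s⁻¹.
* Length scales (Lm_D) are in µm; voxel sizes in mm.
* The diffusion time Δ is quoted in ms.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

B_VALUE_UNITS = "s/cm^2"

#: canonical units per parameter-map name
MAP_UNITS = {
    "ADC": "cm^2/s",
    "DDC": "cm^2/s",
    "alpha": "",
    "LmD": "um",
    "S0": "a.u.",
    "rmse": "a.u.",
}


def _voxel_size_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.sqrt((np.asarray(affine, float)[:3, :3] ** 2).sum(axis=0))


@dataclass
class DWVolumeSet:
    """A stack of 3-D magnitude volumes, one per diffusion weighting.

    Parameters
    ----------
    data
        Signal array indexed ``(x, y, z, b)``, arbitrary units, non-negative.
    b_values
        Diffusion weightings in s·cm⁻², strictly increasing and starting at 0.
    affine
        NIfTI-style 4×4 voxel-to-world affine (mm). The cranio-caudal axis is
        derived from this affine, never assumed from array order.
    meta
        Free-form acquisition metadata (e.g. ``delta_ms``, ``snr``, ``seed``).
    """

    data: np.ndarray
    b_values: np.ndarray
    affine: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(f"expected 4-D (x,y,z,b) array, got {self.data.ndim}-D")
        if self.b_values.ndim != 1 or self.b_values.size != self.data.shape[3]:
            raise FormatError(
                f"{self.b_values.size} b-values for {self.data.shape[3]} volumes"
            )
        if self.b_values[0] != 0.0:
            raise FormatError("b-value list must start at 0 (no b=0 volume found)")
        if np.any(np.diff(self.b_values) <= 0):
            raise FormatError(f"b-values must be strictly increasing, got {self.b_values}")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if np.any(_voxel_size_from_affine(self.affine) <= 0):
            raise FormatError("non-positive voxel size in affine")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("signal contains non-finite values")
        if self.data.min() < 0:
            raise FormatError("magnitude signal must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_b(self) -> int:
        return int(self.b_values.size)

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm, derived from the affine."""
        return _voxel_size_from_affine(self.affine)

    def volume(self, b: float) -> np.ndarray:
        """Return the 3-D volume acquired at b-value ``b``."""
        idx = np.nonzero(np.isclose(self.b_values, b))[0]
        if idx.size == 0:
            raise KeyError(f"no volume at b={b}")
        return self.data[..., idx[0]]


@dataclass
class ParameterMap:
    """A named per-voxel scalar field with a validity mask.

    Values are finite inside the validity mask and NaN outside it; the mask is
    therefore implicit in the data and reconstructed on load.
    """

    name: str
    data: np.ndarray
    affine: np.ndarray
    units: str | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise FormatError("parameter map must be 3-D")
        if self.name not in MAP_UNITS:
            raise FormatError(f"unknown map name {self.name!r}; expected one of {sorted(MAP_UNITS)}")
        canonical = MAP_UNITS[self.name]
        if self.units is None:
            self.units = canonical
        elif self.units != canonical:
            raise FormatError(
                f"units {self.units!r} inconsistent with map {self.name!r} (expected {canonical!r})"
            )

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of voxels with a successful fit."""
        return np.isfinite(self.data)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def values(self) -> np.ndarray:
        """1-D array of the valid voxel values."""
        return self.data[self.valid]
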