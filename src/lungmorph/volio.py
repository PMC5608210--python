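"""Volume I/O, geometry metadata, configuration and the entrance-dose utility.

Conventions used throughout the package:

* axis order is ``(z, y, x)``, 0-based, half-open crop intervals;
* all physical lengths are micrometres (µm) and voxel spacing is isotropic;
* binary foreground (``True``) is *tissue*, background is air — the thickness
  analysis inverts internally because it measures the air phase.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import tomllib
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

logger = logging.getLogger("lungmorph")
if not logger.handlers:  # stderr provenance lines, one per operation
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("lungmorph %(levelname)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


def _validate_geometry(data: np.ndarray, spacing: float) -> None:
    if data.ndim != 3 or min(data.shape) < 1:
        raise ValueError(f"volume must be 3D (z, y, x) with non-empty axes, got shape {data.shape}")
    if not np.isfinite(spacing) or spacing <= 0:
        raise ValueError(f"voxel spacing must be a positive number of µm, got {spacing}")


@dataclasses.dataclass
class GrayVolume:
    """3D scalar image with isotropic voxel spacing in µm.

    ``meta['history']`` is an append-only list of per-operation provenance
    records; every operation in the package appends to it via :meth:`record`.
    """

    data: np.ndarray
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _validate_geometry(self.data, self.spacing)
        self.meta.setdefault("history", [])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def record(self, op: str, **params: Any) -> None:
        """Append a provenance record (append-only history)."""
        self.meta["history"].append({"op": op, **params})
        logger.info("%s %s", op, params)

    def replace(self, data: np.ndarray, op: str | None = None, **params: Any) -> "GrayVolume":
        """New volume with the same geometry, copied history and new data."""
        out = GrayVolume(data, self.spacing, self.origin, {**self.meta, "history": list(self.meta["history"])})
        if op is not None:
            out.record(op, **params)
        return out


@dataclasses.dataclass
class BinaryVolume:
    """3D boolean mask, ``True`` = tissue, sharing the GrayVolume geometry contract."""

    data: np.ndarray
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != bool:
            uniq = np.unique(self.data)
            if uniq.size > 2:
                raise ValueError("binary volume must have exactly two value states")
            self.data = self.data != self.data.min() if uniq.size == 2 else self.data.astype(bool)
        _validate_geometry(self.data, self.spacing)
        self.meta.setdefault("history", [])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def tissue_fraction(self) -> float:
        return float(self.data.mean())

    def record(self, op: str, **params: Any) -> None:
        self.meta["history"].append({"op": op, **params})
        logger.info("%s %s", op, params)

    def replace(self, data: np.ndarray, op: str | None = None, **params: Any) -> "BinaryVolume":
        out = BinaryVolume(data, self.spacing, self.origin, {**self.meta, "history": list(self.meta["history"])})
        if op is not None:
            out.record(op, **params)
        return out


@dataclasses.dataclass
class DoseParams:
    """Parameters of the entrance-dose formula.

    flux
        I0, photons/µm² (≥ 0).
    photon_energy
        hν, eV.
    attenuation_length
        µ⁻¹, µm (the 1/e attenuation length of the medium).
    density
        ρ, g/cm³.
    """

    flux: float
    photon_energy: float
    attenuation_length: float
    density: float

    def __post_init__(self) -> None:
        if self.flux < 0:
            raise ValueError("flux I0 must be >= 0")
        for name in ("photon_energy", "attenuation_length", "density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def entrance_dose(params: DoseParams) -> float:
    """Entrance dose D in Gy.

    ``D = 1.602e-4 * I0 * hν / (µ⁻¹ * ρ)`` evaluated verbatim on the unit
    scale above (photons/µm², eV, µm, g/cm³); no unit auto-conversion.
    """
    return 1.602e-4 * params.flux * params.photon_energy / (params.attenuation_length * params.density)


def read_volume(path: str | Path, spacing: float) -> GrayVolume:
    """Read a multi-page TIFF stack (page index = z) or a raw+JSON-sidecar pair.

    Gray values are preserved bit-exact for integer inputs.  A raw volume is a
    flat binary file ``<name>.raw`` with a sidecar ``<name>.json`` holding
    ``{"shape": [z, y, x], "dtype": "...", "spacing_um": ...}``.
    """
    path = Path(path)
    if not np.isfinite(spacing) or spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    if path.suffix.lower() == ".raw":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"raw volume {path} has no JSON sidecar {sidecar}")
        info = json.loads(sidecar.read_text())
        data = np.fromfile(path, dtype=np.dtype(info["dtype"])).reshape(info["shape"])
        if "spacing_um" in info and not np.isclose(info["spacing_um"], spacing):
            raise ValueError(f"sidecar spacing {info['spacing_um']} µm disagrees with requested {spacing} µm")
    else:
        if not path.exists():
            raise FileNotFoundError(str(path))
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    if data.ndim != 3 or data.size == 0:
        raise ValueError(f"{path} does not contain a non-empty 3D stack (shape {data.shape})")
    vol = GrayVolume(data, spacing, meta={"source": str(path)})
    vol.record("read_volume", path=str(path), spacing=spacing)
    return vol


def write_volume(vol: GrayVolume | BinaryVolume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF; binary masks become 8-bit 0/255.

    Refuses volumes containing NaN (silent corruption on round-trip).
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    data = vol.data
    if isinstance(vol, BinaryVolume):
        data = data.astype(np.uint8) * 255
    elif np.issubdtype(data.dtype, np.floating) and not np.isfinite(data).all():
        raise ValueError("volume contains NaN/inf voxels; refusing to write")
    tifffile.imwrite(path, data)
    logger.info("write_volume %s shape=%s dtype=%s", path, data.shape, data.dtype)


def write_raw(vol: GrayVolume, path: str | Path) -> None:
    """Write a volume as raw binary + JSON sidecar (lossless for any dtype)."""
    path = Path(path).with_suffix(".raw")
    vol.data.tofile(path)
    path.with_suffix(".json").write_text(
        json.dumps({"shape": list(vol.shape), "dtype": vol.data.dtype.str, "spacing_um": vol.spacing})
    )


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a TOML configuration file holding default parameters per module."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)
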