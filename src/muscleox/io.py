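"""NIfTI I/O for 4-D BOLD series and coregistered muscle label maps.

A BOLD acquisition is stored as one NIfTI-1 file with time as the fourth
axis (one volume per TR).  Muscle volumes of interest (VOIs) come as a 3-D
integer label image sharing the spatial grid of the series, plus a legend
mapping label integers to muscle names.  Coregistration is an upstream
responsibility: this module only *checks* that the two grids agree, it never
resamples.

Frame ``i`` covers the acquisition window ``[i*TR, (i+1)*TR)`` and is
timestamped at the window center ``(i + 0.5)*TR`` so that event times
derived from the series (time to peak, time to recovery) are unbiased.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import yaml

from .errors import AlignmentError, DataError, MaskError, NotATimeSeriesError

#: Canonical calf muscle names used throughout the package.
MUSCLES = ("gastrocnemius", "soleus", "anterior_tibialis", "peroneus_longus")

_VOXEL_TOL_MM = 1e-6


@dataclass(frozen=True)
class BoldSeries:
    """A 4-D BOLD signal-intensity series.

    Parameters
    ----------
    voxels:
        Array of shape ``(nx, ny, nz, nt)`` in arbitrary scanner units.
    voxel_size:
        In-plane and through-plane voxel edge lengths in mm.
    tr:
        Repetition time (seconds per volume).
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    tr: float

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        object.__setattr__(self, "voxels", vox)
        if vox.ndim != 4:
            raise NotATimeSeriesError(
                f"expected a 4-D (x, y, z, t) array, got {vox.ndim}-D"
            )
        if min(vox.shape) < 1 or vox.shape[3] < 2:
            raise DataError(f"degenerate series shape {vox.shape}; need nt >= 2")
        if not np.isfinite(vox).all():
            raise DataError("series contains non-finite intensities")
        if len(self.voxel_size) != 3 or min(self.voxel_size) <= 0:
            raise DataError(f"voxel size must be 3 positive mm values, got {self.voxel_size}")
        if not self.tr > 0:
            raise DataError(f"nonpositive TR: {self.tr}")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[3]

    @property
    def frame_times(self) -> np.ndarray:
        """Center timestamps of the acquisition windows, in seconds."""
        return (np.arange(self.n_frames) + 0.5) * self.tr


@dataclass(frozen=True)
class VoiLabelMap:
    """Integer label volume marking muscle VOIs; 0 is background."""

    labels: np.ndarray
    legend: Mapping[int, str]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        object.__setattr__(self, "labels", lab)
        if lab.ndim != 3:
            raise MaskError(f"label map must be 3-D, got {lab.ndim}-D")
        if not np.issubdtype(lab.dtype, np.integer):
            raise MaskError(f"label map must be integer-typed, got dtype {lab.dtype}")
        legend = {int(k): str(v) for k, v in dict(self.legend).items()}
        object.__setattr__(self, "legend", legend)
        if any(k <= 0 for k in legend):
            raise MaskError("legend labels must be positive integers (0 is background)")
        present = set(np.unique(lab).tolist())
        missing = sorted(k for k in legend if k not in present)
        if missing:
            raise MaskError(f"legend references labels absent from the array: {missing}")
        if len(self.voxel_size) != 3 or min(self.voxel_size) <= 0:
            raise MaskError(f"voxel size must be 3 positive mm values, got {self.voxel_size}")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def label_of(self, muscle: str) -> int:
        """Label integer for a muscle name; raises ``MaskError`` if absent."""
        for k, v in self.legend.items():
            if v == muscle:
                return k
        raise MaskError(f"muscle {muscle!r} not in legend {sorted(self.legend.values())}")

    def voxel_count(self, muscle: str) -> int:
        return int((self.labels == self.label_of(muscle)).sum())


@dataclass(frozen=True)
class AcquisitionMeta:
    """Descriptive acquisition metadata (never used in computation)."""

    te_ms: float | None = None
    flip_angle_deg: float | None = None
    field_strength_t: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        for name in ("te_ms", "flip_angle_deg", "field_strength_t"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise DataError(f"{name} must be positive when present, got {v}")


def read_bold_series(path: str | Path, tr: float | None = None) -> BoldSeries:
    """Read a 4-D BOLD series from a NIfTI file.

    The repetition time is taken from the header time step unless ``tr``
    is given.  Intensities are returned as stored (header scale factors
    applied, no further rescaling).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    if img.ndim != 4:
        raise NotATimeSeriesError(
            f"{path.name}: expected a 4-D time series, got {img.ndim}-D (not a time series)"
        )
    data = img.get_fdata(dtype=np.float32)
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    if tr is None:
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if not tr > 0:
        raise DataError(f"{path.name}: nonpositive TR {tr}; pass tr= explicitly")
    return BoldSeries(voxels=data, voxel_size=voxel_size, tr=float(tr))


def write_bold_series(series: BoldSeries, path: str | Path) -> Path:
    """Write a series to NIfTI-1 (float32 on disk, TR stored in the header)."""
    path = Path(path)
    affine = np.diag(list(series.voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(series.voxels, dtype=np.float32), affine)
    img.header.set_zooms(tuple(series.voxel_size) + (series.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, path)
    return path


def read_legend(path: str | Path) -> dict[int, str]:
    """Read a ``{label_int: muscle_name}`` legend from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict) or not raw:
        raise MaskError(f"{path.name}: legend must be a non-empty mapping")
    return {int(k): str(v) for k, v in raw.items()}


def write_legend(legend: Mapping[int, str], path: str | Path) -> Path:
    path = Path(path)
    payload = {str(int(k)): str(v) for k, v in legend.items()}
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def read_voi_labels(path: str | Path, legend: Mapping[int, str]) -> VoiLabelMap:
    """Read a 3-D integer label image and pair it with a legend.

    Float-typed masks are rejected, never rounded: a non-integral mask is
    evidence of resampling, which must not happen downstream of manual
    segmentation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    if img.ndim != 3:
        raise MaskError(f"{path.name}: label map must be 3-D, got {img.ndim}-D")
    if not np.issubdtype(img.get_data_dtype(), np.integer):
        raise MaskError(
            f"{path.name}: float-valued mask (on-disk dtype {img.get_data_dtype()}); "
            "masks must be integer-typed"
        )
    labels = np.asanyarray(img.dataobj).astype(np.int32)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoiLabelMap(labels=labels, legend=dict(legend), voxel_size=voxel_size)


def write_voi_labels(mask: VoiLabelMap, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag(list(mask.voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(mask.labels, dtype=np.int16), affine)
    img.header.set_zooms(tuple(mask.voxel_size))
    img.header.set_xyzt_units("mm")
    nib.save(img, path)
    return path


def validate_alignment(series: BoldSeries, mask: VoiLabelMap) -> tuple[BoldSeries, VoiLabelMap]:
    """Check that series and mask share spatial dims and voxel sizes.

    Alignment itself (coregistration) is assumed; only the grids are
    compared, to within 1e-6 mm.  Returns the pair for downstream use.
    """
    if series.spatial_shape != mask.spatial_shape:
        raise AlignmentError(
            f"dimension mismatch: series {series.spatial_shape} vs mask {mask.spatial_shape}"
        )
    dv = np.abs(np.subtract(series.voxel_size, mask.voxel_size))
    if (dv > _VOXEL_TOL_MM).any():
        raise AlignmentError(
            f"voxel-size mismatch: series {series.voxel_size} vs mask {mask.voxel_size} mm"
        )
    return series, mask
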