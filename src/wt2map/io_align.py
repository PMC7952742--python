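"""Reading MESE series and fat-fraction volumes, header-based alignment,
and parameter-map output.

The multi-echo spin-echo input may be a DICOM series (per-image echo
times, orientation/position metadata) or a 4D NIfTI volume with a JSON
sidecar listing the echo times. The fat-fraction volume from an
independent water-fat acquisition may have arbitrary resolution and
field of view: it is resampled onto the MESE voxel grid purely through
the affine (voxel-to-world) transforms of the two images — no image
registration is performed, mirroring a workflow where both acquisitions
share a frame of reference.

Conventions: world coordinates in mm, RAS; voxel indices 0-based with
voxel centers as sampling points; the in-memory MESE array is
(slices, rows, cols, echoes) and its affine maps (slice, row, col)
indices to world coordinates.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from scipy.ndimage import map_coordinates

from .matching import ParameterMaps

__all__ = [
    "MESESeries",
    "FFVolume",
    "read_mese",
    "read_ff_volume",
    "align_ff_to_mese",
    "write_maps",
]

logger = logging.getLogger(__name__)


@dataclass
class MESESeries:
    """A 4D multi-echo spin-echo magnitude series with geometry."""

    volume: np.ndarray  # (slices, rows, cols, echoes)
    echo_times: np.ndarray  # ms, ascending
    affine: np.ndarray  # (slice, row, col) voxel index -> RAS mm
    source: str = ""

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, float)
        self.echo_times = np.asarray(self.echo_times, float)
        if self.volume.ndim != 4:
            raise ValueError("volume must be 4D: slices x rows x cols x echoes")
        if self.echo_times.size != self.volume.shape[3]:
            raise ValueError(
                f"{self.echo_times.size} echo times for {self.volume.shape[3]} echo images"
            )
        if np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo times must be strictly increasing")
        spacings = np.diff(self.echo_times)
        if spacings.size and (spacings.max() - spacings.min()) > 0.01 * spacings.mean():
            warnings.warn("echo spacing is not uniform (>1% variation)")

    @property
    def echo_spacing(self) -> float:
        return float(np.mean(np.diff(self.echo_times))) if self.echo_times.size > 1 else float(self.echo_times[0])

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.volume.shape[:3]


@dataclass
class FFVolume:
    """A fat-fraction volume in [0, 1] with its own geometry."""

    values: np.ndarray
    affine: np.ndarray
    percent_input: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, float)
        if not np.all(np.isfinite(values)):
            raise ValueError("fat-fraction values must be finite")
        # Maps stored as percent (0-100) are auto-detected and rescaled.
        if values.size and np.nanmax(values) > 1.5:
            values = values / 100.0
            self.percent_input = True
        self.values = np.clip(values, 0.0, 1.0)


def _read_sidecar_echo_times(nifti_path: Path) -> np.ndarray:
    stem = nifti_path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    sidecar = nifti_path.parent / f"{stem}.json"
    if not sidecar.exists():
        raise FileNotFoundError(
            f"echo-time sidecar {sidecar} not found next to {nifti_path}"
        )
    meta = json.loads(sidecar.read_text())
    for key in ("echo_times_ms", "EchoTimes", "EchoTime"):
        if key in meta:
            return np.atleast_1d(np.asarray(meta[key], float))
    raise KeyError(f"{sidecar}: no echo-time entry (echo_times_ms / EchoTimes)")


def _nifti_sra_affine(img) -> np.ndarray:
    """Affine mapping (slice, row, col) indices to RAS, from a NIfTI image.

    The on-disk NIfTI voxel order is taken as (slice, row, col) for the
    first three axes, so the NIfTI affine applies directly.
    """
    return np.asarray(img.affine, float)


def _read_mese_nifti(path: Path) -> MESESeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got shape {data.shape}")
    echo_times = _read_sidecar_echo_times(path)
    order = np.argsort(echo_times)
    return MESESeries(
        volume=data[..., order],
        echo_times=echo_times[order],
        affine=_nifti_sra_affine(img),
        source=str(path),
    )


def _dicom_slice_affine(datasets: list) -> np.ndarray:
    """Build the (slice, row, col) -> RAS affine from DICOM geometry tags."""
    ds0 = datasets[0]
    iop = np.asarray(ds0.ImageOrientationPatient, float)
    row_dir, col_dir = iop[:3], iop[3:]  # along increasing col / row index (LPS)
    row_spacing, col_spacing = (float(v) for v in ds0.PixelSpacing)
    origin = np.asarray(ds0.ImagePositionPatient, float)
    if len(datasets) > 1:
        step = np.asarray(datasets[1].ImagePositionPatient, float) - origin
    else:
        normal = np.cross(row_dir, col_dir)
        step = normal * float(getattr(ds0, "SliceThickness", 1.0))
    lps = np.eye(4)
    lps[:3, 0] = step  # slice index
    lps[:3, 1] = col_dir * row_spacing  # row index
    lps[:3, 2] = row_dir * col_spacing  # col index
    lps[:3, 3] = origin
    return np.diag([-1.0, -1.0, 1.0, 1.0]) @ lps  # LPS -> RAS


def _read_mese_dicom(path: Path) -> MESESeries:
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() != ".json")
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if not hasattr(ds, "PixelData"):
            continue
        if not hasattr(ds, "EchoTime") or ds.EchoTime is None:
            raise ValueError(f"{f}: missing EchoTime metadata")
        datasets.append((f, ds))
    if not datasets:
        raise ValueError(f"{path}: no readable DICOM images found")

    shape0 = datasets[0][1].pixel_array.shape
    for f, ds in datasets:
        if ds.pixel_array.shape != shape0:
            raise ValueError(f"{f}: matrix size {ds.pixel_array.shape} differs from {shape0}")

    # Group by slice position along the stack normal, sort echoes within.
    by_slice: dict[tuple, list] = {}
    for f, ds in datasets:
        pos = tuple(np.round(np.asarray(ds.ImagePositionPatient, float), 3))
        by_slice.setdefault(pos, []).append((float(ds.EchoTime), f, ds))

    ds_any = datasets[0][1]
    iop = np.asarray(ds_any.ImageOrientationPatient, float)
    normal = np.cross(iop[:3], iop[3:])
    slice_keys = sorted(by_slice, key=lambda p: float(np.dot(p, normal)))

    echo_counts = {len(by_slice[k]) for k in slice_keys}
    if len(echo_counts) != 1:
        bad = [k for k in slice_keys if len(by_slice[k]) != max(echo_counts)]
        raise ValueError(f"incomplete echo train at slice position(s) {bad}")

    slices = []
    echo_times_ref = None
    for key in slice_keys:
        group = sorted(by_slice[key], key=lambda t: t[0])
        tes = np.array([g[0] for g in group])
        if echo_times_ref is None:
            echo_times_ref = tes
        elif not np.allclose(tes, echo_times_ref):
            raise ValueError(f"echo times differ across slices (slice at {key})")
        slices.append(np.stack([g[2].pixel_array.astype(float) for g in group], axis=-1))

    first_per_slice = [sorted(by_slice[k], key=lambda t: t[0])[0][2] for k in slice_keys]
    affine = _dicom_slice_affine(first_per_slice)
    return MESESeries(
        volume=np.stack(slices, axis=0),
        echo_times=echo_times_ref,
        affine=affine,
        source=str(path),
    )


def read_mese(path) -> MESESeries:
    """Read a MESE series from a DICOM directory or a NIfTI + JSON sidecar."""
    path = Path(path)
    if path.is_dir():
        return _read_mese_dicom(path)
    return _read_mese_nifti(path)


def read_ff_volume(path) -> FFVolume:
    """Read a fat-fraction volume (NIfTI). Percent-scaled input (max > 1.5)
    is detected and divided by 100."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D fat-fraction volume, got shape {data.shape}")
    return FFVolume(values=data, affine=_nifti_sra_affine(img))


def align_ff_to_mese(
    ff: FFVolume,
    mese: MESESeries,
    interpolation: str = "linear",
) -> np.ndarray:
    """Resample the fat-fraction volume onto the MESE voxel grid.

    Every MESE voxel center is mapped to world coordinates through the
    MESE affine and back into FF voxel indices through the inverse FF
    affine; the value is interpolated there (``linear`` default,
    ``nearest`` for label-like inputs). Voxels falling outside the FF
    volume become NaN, to be treated as unconstrained downstream; their
    count is logged.
    """
    if interpolation not in ("nearest", "linear"):
        raise ValueError("interpolation must be 'nearest' or 'linear'")
    try:
        inv_ff = np.linalg.inv(ff.affine)
    except np.linalg.LinAlgError as err:
        raise ValueError("fat-fraction affine is singular") from err
    transform = inv_ff @ mese.affine

    shape = mese.spatial_shape
    idx = np.indices(shape, dtype=float).reshape(3, -1)
    coords = transform[:3, :3] @ idx + transform[:3, 3:4]

    # map_coordinates cannot emit NaN for out-of-bounds; mask explicitly.
    upper = np.array(ff.values.shape, float) - 1.0
    eps = 1e-9
    inside = np.all((coords >= -eps) & (coords <= upper[:, None] + eps), axis=0)

    order = 0 if interpolation == "nearest" else 1
    sampled = map_coordinates(ff.values, coords, order=order, mode="nearest")
    sampled[~inside] = np.nan
    out = sampled.reshape(shape)

    n_out = int((~inside).sum())
    if n_out:
        logger.warning("%d MESE voxels fall outside the fat-fraction volume", n_out)
    return out


_MAP_FILES = {
    "wt2": "wt2_ms.nii.gz",
    "ff": "ff_fraction.nii.gz",
    "b1": "b1_fraction.nii.gz",
    "correlation": "correlation.nii.gz",
}


def write_maps(maps: ParameterMaps, out_dir, config: dict | None = None) -> dict[str, Path]:
    """Write parameter maps as float32 NIfTI plus a provenance sidecar.

    The MESE affine is copied verbatim onto every map; the JSON sidecar
    records the full run configuration so a run can be reproduced.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for attr, fname in _MAP_FILES.items():
        data = np.asarray(getattr(maps, attr), dtype=np.float32)
        img = nib.Nifti1Image(data, maps.affine)
        path = out_dir / fname
        nib.save(img, str(path))
        written[attr] = path
    from . import __version__

    sidecar = {"software": "wt2map", "version": __version__}
    if config:
        sidecar.update(config)
    sidecar_path = out_dir / "run_config.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, default=str))
    written["sidecar"] = sidecar_path
    return written
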