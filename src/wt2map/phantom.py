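"""Digital MESE phantom with known water-T2, fat-fraction and B1 fields.

Generates a multi-slice multi-echo spin-echo dataset of elliptical
"tissue" regions whose voxel signals follow the same two-compartment
EPG forward model used for dictionary construction, corrupted by Rician
noise (the magnitude-MRI noise law: |S + n1 + i*n2| with i.i.d. Gaussian
n1, n2), plus a fat-fraction volume that can be deliberately shifted to
exercise the header-based alignment. The default layout mimics a muscle
imaging regime: water T2 between 25 and 45 ms, fat fractions from 0 to
0.6, a linear left-right B1 gradient from 0.8 to 1.2, 17 echoes at
10.9 ms spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import nibabel as nib
import numpy as np

from .epg import (
    DEFAULT_FAT_T2_MS,
    FAT_T1_MS,
    WATER_T1_MS,
    SequenceParams,
    epg_cpmg_batch,
)
from .io_align import FFVolume, MESESeries
from .rf_profiles import SliceProfileTable

__all__ = ["PhantomRegion", "PhantomSpec", "PhantomTruth", "make_phantom", "write_phantom", "default_regions"]


@dataclass(frozen=True)
class PhantomRegion:
    """An elliptical homogeneous tissue region on every slice.

    Center and semi-axes are in fractional image coordinates (0..1 of
    rows/cols). Overlapping regions resolve last-listed-wins.
    """

    center: tuple[float, float]
    semiaxes: tuple[float, float]
    wt2: float  # ms
    ff: float  # fraction

    def __post_init__(self) -> None:
        if not 20.0 <= self.wt2 <= 80.0:
            raise ValueError("region wT2 must lie within [20, 80] ms")
        if not 0.0 <= self.ff <= 1.0:
            raise ValueError("region FF must lie within [0, 1]")


def default_regions() -> list[PhantomRegion]:
    """Eight circular inserts spanning wT2 25-45 ms and FF 0-0.6."""
    params = [
        (25.0, 0.00), (30.0, 0.10), (35.0, 0.20), (40.0, 0.30),
        (45.0, 0.40), (30.0, 0.50), (35.0, 0.60), (40.0, 0.05),
    ]
    centers = [
        (0.25, 0.25), (0.25, 0.50), (0.25, 0.75), (0.50, 0.25),
        (0.50, 0.75), (0.75, 0.25), (0.75, 0.50), (0.75, 0.75),
    ]
    return [
        PhantomRegion(center=c, semiaxes=(0.10, 0.10), wt2=w, ff=f)
        for c, (w, f) in zip(centers, params)
    ]


@dataclass(frozen=True)
class PhantomSpec:
    """Layout, noise and geometry of the synthetic dataset."""

    shape: tuple[int, int, int] = (3, 64, 64)  # slices, rows, cols
    regions: list[PhantomRegion] = dc_field(default_factory=default_regions)
    b1_field: str = "linear_gradient"  # or "constant"
    b1_range: tuple[float, float] = (0.8, 1.2)
    noise_sigma: float | None = None  # fraction of M0; overrides snr
    snr: float | None = 50.0  # first-echo object SNR; sets sigma if noise_sigma is None
    noise_model: str = "rician"  # or "gaussian"
    ff_map_shift: int = 0  # voxels, along the column axis
    seed: int = 0
    voxel_size: tuple[float, float, float] = (40.0, 1.2, 1.2)  # mm (slice, row, col)

    def __post_init__(self) -> None:
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.b1_field not in ("constant", "linear_gradient"):
            raise ValueError("b1_field must be 'constant' or 'linear_gradient'")
        if self.noise_model not in ("rician", "gaussian"):
            raise ValueError("noise_model must be 'rician' or 'gaussian'")


@dataclass
class PhantomTruth:
    """Ground-truth fields plus the synthesized noisy acquisition."""

    wt2_true: np.ndarray
    ff_true: np.ndarray
    b1_true: np.ndarray
    region_labels: np.ndarray  # 0 = background, 1..n = regions
    mese: MESESeries
    ff_volume: FFVolume
    spec: PhantomSpec
    noise_sigma: float  # the sigma actually applied


def _region_masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    _, n_rows, n_cols = spec.shape
    rr, cc = np.meshgrid(
        (np.arange(n_rows) + 0.5) / n_rows,
        (np.arange(n_cols) + 0.5) / n_cols,
        indexing="ij",
    )
    labels = np.zeros((n_rows, n_cols), dtype=np.int32)
    wt2 = np.zeros((n_rows, n_cols))
    ff = np.zeros((n_rows, n_cols))
    for i, reg in enumerate(spec.regions, start=1):
        inside = (
            ((rr - reg.center[0]) / reg.semiaxes[0]) ** 2
            + ((cc - reg.center[1]) / reg.semiaxes[1]) ** 2
        ) <= 1.0
        labels[inside] = i
        wt2[inside] = reg.wt2
        ff[inside] = reg.ff
    return labels, wt2, ff


def _b1_field(spec: PhantomSpec) -> np.ndarray:
    _, n_rows, n_cols = spec.shape
    lo, hi = spec.b1_range
    if spec.b1_field == "constant":
        value = 0.5 * (lo + hi)
        return np.full((n_rows, n_cols), value)
    # linear gradient along the column (left-right) axis
    col_profile = np.linspace(lo, hi, n_cols)
    return np.tile(col_profile, (n_rows, 1))


def forward_signals(
    wt2: np.ndarray,
    ff: np.ndarray,
    b1: np.ndarray,
    seq: SequenceParams,
    profile: SliceProfileTable,
    fat_t2: float = DEFAULT_FAT_T2_MS,
) -> np.ndarray:
    """Noiseless two-compartment signals for arrays of voxel parameters.

    Vectorized equivalent of ``simulate_voxel_signal`` over flattened
    parameter arrays; returns shape ``wt2.shape + (n_echoes,)``.
    """
    wt2 = np.asarray(wt2, float)
    ff = np.asarray(ff, float)
    b1 = np.asarray(b1, float)
    exc = profile.exc_flip * b1[..., None]
    ref = profile.ref_flip * b1[..., None]
    water = epg_cpmg_batch(
        WATER_T1_MS, wt2[..., None], exc, ref, seq.n_echoes, seq.echo_spacing
    ).mean(axis=-2)
    fat = epg_cpmg_batch(
        FAT_T1_MS, fat_t2, exc, ref, seq.n_echoes, seq.echo_spacing
    ).mean(axis=-2)
    sat_w = seq.saturation_factor(WATER_T1_MS)
    sat_f = seq.saturation_factor(FAT_T1_MS)
    return (1.0 - ff[..., None]) * sat_w * water + ff[..., None] * sat_f * fat


def _sra_affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = voxel_size
    return affine


def make_phantom(
    spec: PhantomSpec,
    seq: SequenceParams | None = None,
    profile: SliceProfileTable | None = None,
    fat_t2: float = DEFAULT_FAT_T2_MS,
) -> PhantomTruth:
    """Synthesize the noisy MESE series and companion fat-fraction volume.

    The noiseless echo trains are the exact forward model
    (``simulate_voxel_signal``) evaluated at the per-voxel truth; noise
    is then drawn from the chosen model with a sigma given directly or
    derived from the requested first-echo object SNR. The fat-fraction
    volume stores the true FF with an affine translated by
    ``ff_map_shift`` voxels along the column axis, so header-based
    alignment must undo the shift.
    """
    if seq is None:
        seq = SequenceParams()
    if profile is None:
        from .rf_profiles import default_profile

        profile = default_profile(seq)

    n_slices = spec.shape[0]
    labels2d, wt2_2d, ff_2d = _region_masks(spec)
    b1_2d = _b1_field(spec)

    object_mask = labels2d > 0
    signals2d = np.zeros(labels2d.shape + (seq.n_echoes,))
    if object_mask.any():
        signals2d[object_mask] = forward_signals(
            wt2_2d[object_mask], ff_2d[object_mask], b1_2d[object_mask],
            seq, profile, fat_t2,
        )

    noiseless = np.broadcast_to(
        signals2d[None], (n_slices,) + signals2d.shape
    ).copy()

    if spec.noise_sigma is not None:
        sigma = float(spec.noise_sigma)
    elif spec.snr is not None and object_mask.any():
        first_echo_mean = float(signals2d[object_mask][:, 0].mean())
        sigma = first_echo_mean / spec.snr
    else:
        sigma = 0.0

    rng = np.random.default_rng(spec.seed)
    if sigma > 0:
        n1 = rng.normal(0.0, sigma, noiseless.shape)
        if spec.noise_model == "rician":
            n2 = rng.normal(0.0, sigma, noiseless.shape)
            volume = np.abs(noiseless + n1 + 1j * n2)
        else:
            volume = noiseless + n1
    else:
        volume = noiseless

    affine = _sra_affine(spec.voxel_size)
    mese = MESESeries(
        volume=volume,
        echo_times=seq.echo_times,
        affine=affine,
        source="phantom",
    )

    ff_affine = affine.copy()
    # shifting the affine origin by +k voxels along the column axis means
    # the same stored array represents data displaced in world space
    ff_affine[:3, 3] += spec.ff_map_shift * affine[:3, 2]
    ff_volume = FFVolume(
        values=np.broadcast_to(ff_2d[None], (n_slices,) + ff_2d.shape).copy(),
        affine=ff_affine,
    )

    return PhantomTruth(
        wt2_true=np.where(
            np.broadcast_to(labels2d[None] > 0, (n_slices,) + labels2d.shape),
            np.broadcast_to(wt2_2d[None], (n_slices,) + wt2_2d.shape),
            np.nan,
        ),
        ff_true=np.broadcast_to(ff_2d[None], (n_slices,) + ff_2d.shape).copy(),
        b1_true=np.broadcast_to(b1_2d[None], (n_slices,) + b1_2d.shape).copy(),
        region_labels=np.broadcast_to(labels2d[None], (n_slices,) + labels2d.shape).copy(),
        mese=mese,
        ff_volume=ff_volume,
        spec=spec,
        noise_sigma=sigma,
    )


def write_phantom(truth: PhantomTruth, out_dir) -> dict[str, Path]:
    """Write the phantom as NIfTI volumes + JSON sidecars, readable by
    :func:`wt2map.io_align.read_mese`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    mese_path = out_dir / "mese.nii.gz"
    nib.save(nib.Nifti1Image(truth.mese.volume.astype(np.float32), truth.mese.affine), str(mese_path))
    written["mese"] = mese_path
    sidecar = out_dir / "mese.json"
    sidecar.write_text(json.dumps({"echo_times_ms": truth.mese.echo_times.tolist()}, indent=2))
    written["mese_sidecar"] = sidecar

    ff_path = out_dir / "ff.nii.gz"
    nib.save(nib.Nifti1Image(truth.ff_volume.values.astype(np.float32), truth.ff_volume.affine), str(ff_path))
    written["ff"] = ff_path

    for name, data in (
        ("wt2_true", truth.wt2_true),
        ("ff_true", truth.ff_true),
        ("b1_true", truth.b1_true),
        ("labels", truth.region_labels.astype(np.float32)),
    ):
        path = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(data, np.float32), truth.mese.affine), str(path))
        written[name] = path

    spec_path = out_dir / "phantom_spec.json"
    spec_dict = {
        "shape": list(truth.spec.shape),
        "regions": [
            {"center": list(r.center), "semiaxes": list(r.semiaxes), "wt2": r.wt2, "ff": r.ff}
            for r in truth.spec.regions
        ],
        "b1_field": truth.spec.b1_field,
        "b1_range": list(truth.spec.b1_range),
        "noise_sigma": truth.noise_sigma,
        "noise_model": truth.spec.noise_model,
        "ff_map_shift": truth.spec.ff_map_shift,
        "seed": truth.spec.seed,
        "voxel_size": list(truth.spec.voxel_size),
    }
    spec_path.write_text(json.dumps(spec_dict, indent=2))
    written["spec"] = spec_path
    return written
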