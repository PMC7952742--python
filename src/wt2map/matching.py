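"""Voxelwise dictionary matching by normalized inner product.

Each measured echo train (a row of the signal matrix S) is compared with
every simulated dictionary column (D) by computing the correlation
matrix C = S x D after L2-normalizing the signal rows; the argmax of
each row of C identifies the best-fitting (wT2, FF, B1) combination.
The same lookup can be constrained to a fat fraction known per voxel
from an external water-fat acquisition: the search is then restricted to
the contiguous dictionary range of the nearest grid FF value, which both
removes a degree of freedom and stabilizes wT2 at high fat content.

Ties in the argmax are broken deterministically by the lowest entry
index (FF-major, then B1, then wT2 order).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dictionary import SignalDictionary

__all__ = ["SignalMatrix", "ParameterMaps", "match_unconstrained", "match_constrained", "make_mask"]

logger = logging.getLogger(__name__)


@dataclass
class SignalMatrix:
    """Masked voxel echo trains: one voxel per row, one echo per column."""

    matrix: np.ndarray
    voxel_coords: np.ndarray  # (n_voxels, 3) integer (slice, row, col)
    norm: np.ndarray  # per-row L2 norm before normalization

    @classmethod
    def from_volume(cls, volume: np.ndarray, mask: np.ndarray | None = None) -> "SignalMatrix":
        """Extract in-mask voxel rows from a (slices, rows, cols, echoes) volume.

        Voxels with zero signal norm are excluded from the matrix even if
        they fall inside the mask.
        """
        volume = np.asarray(volume, float)
        if volume.ndim != 4:
            raise ValueError("volume must be 4D: slices x rows x cols x echoes")
        if mask is None:
            mask = np.ones(volume.shape[:3], dtype=bool)
        coords = np.argwhere(mask)
        rows = volume[mask]
        norms = np.linalg.norm(rows, axis=1)
        keep = norms > 0
        return cls(matrix=rows[keep], voxel_coords=coords[keep], norm=norms[keep])

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_echoes(self) -> int:
        return self.matrix.shape[1]

    def normalized(self) -> np.ndarray:
        return self.matrix / self.norm[:, None]


@dataclass
class ParameterMaps:
    """Voxelwise parameter images sharing the MESE slice geometry.

    Out-of-mask voxels are NaN in every map.
    """

    wt2: np.ndarray  # ms
    ff: np.ndarray  # fraction
    b1: np.ndarray  # fraction
    correlation: np.ndarray  # best cosine similarity per voxel
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.wt2.shape

    @classmethod
    def empty(cls, shape: tuple[int, ...], affine: np.ndarray | None = None) -> "ParameterMaps":
        nan = lambda: np.full(shape, np.nan)
        return cls(
            wt2=nan(), ff=nan(), b1=nan(), correlation=nan(),
            affine=np.eye(4) if affine is None else np.asarray(affine, float),
        )


def _fill_maps(
    shape: tuple[int, ...],
    affine: np.ndarray | None,
    signals: SignalMatrix,
    dictionary: SignalDictionary,
    best_entry: np.ndarray,
    best_corr: np.ndarray,
) -> ParameterMaps:
    maps = ParameterMaps.empty(shape, affine)
    s, r, c = signals.voxel_coords.T
    params = dictionary.index[best_entry]
    maps.wt2[s, r, c] = params[:, 0]
    maps.ff[s, r, c] = params[:, 1]
    maps.b1[s, r, c] = params[:, 2]
    maps.correlation[s, r, c] = np.clip(best_corr, 0.0, 1.0)
    return maps


def _check_compat(signals: SignalMatrix, dictionary: SignalDictionary) -> None:
    if signals.n_echoes != dictionary.n_echoes:
        raise ValueError(
            f"echo count mismatch: signals have {signals.n_echoes}, "
            f"dictionary has {dictionary.n_echoes}"
        )


def match_unconstrained(
    signals: SignalMatrix,
    dictionary: SignalDictionary,
    shape: tuple[int, ...],
    affine: np.ndarray | None = None,
    batch_size: int = 4096,
) -> ParameterMaps:
    """Full-grid argmax matching, computed in voxel batches.

    The batch size only bounds the size of the intermediate correlation
    block (batch x entries); results are identical for any batch size.
    """
    _check_compat(signals, dictionary)
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    s_norm = signals.normalized()
    n = signals.n_voxels
    best_entry = np.empty(n, dtype=np.int64)
    best_corr = np.empty(n)
    for start in range(0, n, batch_size):
        block = s_norm[start : start + batch_size] @ dictionary.matrix
        idx = np.argmax(block, axis=1)  # first max: lowest-index tie-break
        best_entry[start : start + len(idx)] = idx
        best_corr[start : start + len(idx)] = block[np.arange(len(idx)), idx]
    return _fill_maps(shape, affine, signals, dictionary, best_entry, best_corr)


def match_constrained(
    signals: SignalMatrix,
    dictionary: SignalDictionary,
    ff_voxel: np.ndarray,
    shape: tuple[int, ...],
    affine: np.ndarray | None = None,
    batch_size: int = 4096,
) -> ParameterMaps:
    """Matching restricted to an externally known fat fraction per voxel.

    ``ff_voxel`` carries one fat fraction per signal row (clamped to
    [0, 1]); it is quantized to the nearest grid value and the argmax is
    taken only over that FF's contiguous entry range, so the output FF
    map equals the quantized constraint. Voxels with a NaN constraint
    (e.g. outside the fat-fraction volume's field of view) fall back to
    unconstrained matching; their count is logged.
    """
    _check_compat(signals, dictionary)
    ff_voxel = np.asarray(ff_voxel, float).ravel()
    if ff_voxel.shape[0] != signals.n_voxels:
        raise ValueError(
            f"constraint length {ff_voxel.shape[0]} does not match "
            f"{signals.n_voxels} in-mask voxels"
        )
    nan_mask = np.isnan(ff_voxel)
    if np.any(nan_mask):
        logger.warning(
            "%d voxels have no fat-fraction constraint (outside FF volume); "
            "matched unconstrained",
            int(nan_mask.sum()),
        )
    ff_clamped = np.clip(ff_voxel, 0.0, 1.0)
    ff_grid = dictionary.grid.ff_values
    ff_idx = np.abs(ff_clamped[:, None] - ff_grid[None, :]).argmin(axis=1)

    s_norm = signals.normalized()
    group = dictionary.ff_group_size
    offsets = dictionary.ff_group_offsets
    n = signals.n_voxels
    best_entry = np.empty(n, dtype=np.int64)
    best_corr = np.empty(n)

    for fi in np.unique(ff_idx[~nan_mask]):
        sel = np.flatnonzero((ff_idx == fi) & ~nan_mask)
        start = offsets[fi]
        sub = dictionary.matrix[:, start : start + group]
        for lo in range(0, sel.size, batch_size):
            rows = sel[lo : lo + batch_size]
            block = s_norm[rows] @ sub
            idx = np.argmax(block, axis=1)
            best_entry[rows] = start + idx
            best_corr[rows] = block[np.arange(len(idx)), idx]

    if np.any(nan_mask):
        rows = np.flatnonzero(nan_mask)
        for lo in range(0, rows.size, batch_size):
            rr = rows[lo : lo + batch_size]
            block = s_norm[rr] @ dictionary.matrix
            idx = np.argmax(block, axis=1)
            best_entry[rr] = idx
            best_corr[rr] = block[np.arange(len(idx)), idx]

    return _fill_maps(shape, affine, signals, dictionary, best_entry, best_corr)


def make_mask(first_echo: np.ndarray, threshold_fraction: float = 0.05) -> np.ndarray:
    """Threshold the first-echo image against its robust maximum.

    The robust maximum is the 99th percentile of the image; voxels above
    ``threshold_fraction`` times it (and strictly positive) are in the
    mask. An explicit user mask can always be supplied instead.
    """
    if not 0.0 <= threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in [0, 1)")
    first_echo = np.asarray(first_echo, float)
    robust_max = np.percentile(first_echo, 99)
    mask = (first_echo > threshold_fraction * robust_max) & (first_echo > 0)
    if not mask.any():
        warnings.warn("mask is empty: no voxel exceeds the intensity threshold")
    return mask
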