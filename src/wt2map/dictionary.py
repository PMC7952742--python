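"""Dictionary of simulated MESE echo trains over a (wT2, FF, B1) grid.

Every parameter combination on the grid is simulated with the
slice-profile-integrated two-compartment EPG model and stored as an
L2-normalized column of a matrix; voxel signals are later matched by
normalized inner product (cosine similarity). Entries are ordered
FF-major — all entries sharing a fat-fraction value occupy one
contiguous column range — so that fat-fraction-constrained matching is a
contiguous-range argmax.

The default grid mirrors a typical muscle protocol: 60 wT2 values in
[20, 80] ms, 20 B1 factors in [0.4, 1.4] and 101 fat fractions in
[0, 1], i.e. 121,200 entries. The dictionary is rebuilt at every run
(construction is fast; no cache layer).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .epg import (
    DEFAULT_FAT_T2_MS,
    FAT_T1_MS,
    WATER_T1_MS,
    SequenceParams,
    epg_cpmg_batch,
)
from .rf_profiles import SliceProfileTable

__all__ = [
    "ParameterGrid",
    "SignalDictionary",
    "build_grid",
    "build_dictionary",
    "truncate_echoes",
    "estimate_fat_t2",
]


@dataclass(frozen=True)
class ParameterGrid:
    """Strictly increasing axes of the (wT2, FF, B1) dictionary grid."""

    wt2_values: np.ndarray
    ff_values: np.ndarray
    b1_values: np.ndarray

    def __post_init__(self) -> None:
        for name in ("wt2_values", "ff_values", "b1_values"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), float))
            if arr.size == 0:
                raise ValueError(f"{name} must not be empty")
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, arr)
        if np.any(self.ff_values < 0) or np.any(self.ff_values > 1):
            raise ValueError("ff_values must lie within [0, 1]")
        if np.any(self.wt2_values <= 0) or np.any(self.b1_values <= 0):
            raise ValueError("wt2_values and b1_values must be positive")

    @property
    def n_entries(self) -> int:
        return self.wt2_values.size * self.ff_values.size * self.b1_values.size


def build_grid(
    wt2_range: tuple[float, float] = (20.0, 80.0),
    wt2_steps: int = 60,
    ff_steps: int = 101,
    b1_range: tuple[float, float] = (0.4, 1.4),
    b1_steps: int = 20,
) -> ParameterGrid:
    """Linearly spaced parameter grid (defaults: 60 x 101 x 20 = 121,200)."""
    return ParameterGrid(
        wt2_values=np.linspace(wt2_range[0], wt2_range[1], wt2_steps),
        ff_values=np.linspace(0.0, 1.0, ff_steps),
        b1_values=np.linspace(b1_range[0], b1_range[1], b1_steps),
    )


@dataclass
class SignalDictionary:
    """Normalized simulated echo trains plus the entry -> parameter lookup.

    ``matrix`` has echoes along rows and entries along columns, each
    column unit L2 norm. ``index`` maps the column number to its
    (wT2 ms, FF, B1) triple; entries are FF-major, then B1, then wT2.
    ``ff_group_offsets[i]`` is the first column of the i-th FF value's
    contiguous range (each range has len(b1) * len(wt2) columns).
    """

    matrix: np.ndarray
    index: np.ndarray
    grid: ParameterGrid
    seq: SequenceParams
    fat_t2: float
    ff_group_offsets: np.ndarray

    @property
    def n_echoes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_entries(self) -> int:
        return self.matrix.shape[1]

    @property
    def ff_group_size(self) -> int:
        return self.grid.b1_values.size * self.grid.wt2_values.size

    def entry_parameters(self, entry: int) -> tuple[float, float, float]:
        wt2, ff, b1 = self.index[entry]
        return float(wt2), float(ff), float(b1)


def _normalize_columns(matrix: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(matrix, axis=0)
    norms[norms == 0] = 1.0
    return matrix / norms


def compartment_train_grid(
    t2_values: np.ndarray,
    t1: float,
    seq: SequenceParams,
    profile: SliceProfileTable,
    b1_values: np.ndarray,
) -> np.ndarray:
    """Slice-integrated echo trains for one compartment on a (T2, B1) grid.

    Returns an array of shape (len(t2_values), len(b1_values), n_echoes).
    """
    t2 = np.asarray(t2_values, float)[:, None, None]
    b1 = np.asarray(b1_values, float)[None, :, None]
    exc = profile.exc_flip[None, None, :] * b1
    ref = profile.ref_flip[None, None, :] * b1
    trains = epg_cpmg_batch(t1, t2, exc, ref, seq.n_echoes, seq.echo_spacing)
    return trains.mean(axis=2)


def build_dictionary(
    grid: ParameterGrid,
    seq: SequenceParams,
    profile: SliceProfileTable,
    fat_t2: float = DEFAULT_FAT_T2_MS,
    water_t1: float = WATER_T1_MS,
    fat_t1: float = FAT_T1_MS,
) -> SignalDictionary:
    """Simulate and normalize every grid combination.

    The two-compartment mixture is linear in the fat fraction, so only
    the water trains (per wT2 x B1) and the fat trains (per B1) are
    simulated; columns are their saturation-weighted combinations.
    """
    if fat_t2 <= 0:
        raise ValueError("fat_t2 must be positive")
    n_wt2 = grid.wt2_values.size
    n_ff = grid.ff_values.size
    n_b1 = grid.b1_values.size

    water = compartment_train_grid(grid.wt2_values, water_t1, seq, profile, grid.b1_values)
    fat = compartment_train_grid(np.array([fat_t2]), fat_t1, seq, profile, grid.b1_values)[0]

    sat_w = seq.saturation_factor(water_t1)
    sat_f = seq.saturation_factor(fat_t1)

    # FF-major, then B1, then wT2: entry = (ff_i * n_b1 + b1_i) * n_wt2 + wt2_i
    ff = grid.ff_values[:, None, None, None]
    water_bw = np.transpose(water, (1, 0, 2))  # (n_b1, n_wt2, n_echoes)
    signals = (1.0 - ff) * sat_w * water_bw[None] + ff * sat_f * fat[None, :, None, :]
    matrix = signals.reshape(n_ff * n_b1 * n_wt2, seq.n_echoes).T

    wt2_idx = np.tile(np.arange(n_wt2), n_ff * n_b1)
    b1_idx = np.tile(np.repeat(np.arange(n_b1), n_wt2), n_ff)
    ff_idx = np.repeat(np.arange(n_ff), n_b1 * n_wt2)
    index = np.column_stack(
        [grid.wt2_values[wt2_idx], grid.ff_values[ff_idx], grid.b1_values[b1_idx]]
    )

    return SignalDictionary(
        matrix=_normalize_columns(matrix),
        index=index,
        grid=grid,
        seq=seq,
        fat_t2=float(fat_t2),
        ff_group_offsets=np.arange(n_ff) * (n_b1 * n_wt2),
    )


def truncate_echoes(obj, n_keep: int):
    """Retain only the first ``n_keep`` echoes.

    For a :class:`SignalDictionary` the columns are re-normalized to unit
    L2 norm after truncation; for a plain voxels-by-echoes signal array
    only the first ``n_keep`` columns are kept (matching normalizes rows
    itself).
    """
    if isinstance(obj, SignalDictionary):
        if not 2 <= n_keep <= obj.n_echoes:
            raise ValueError(f"n_keep must be in [2, {obj.n_echoes}], got {n_keep}")
        if n_keep == obj.n_echoes:
            return replace(obj, matrix=obj.matrix.copy())
        return replace(
            obj,
            matrix=_normalize_columns(obj.matrix[:n_keep].copy()),
            seq=replace(obj.seq, n_echoes=n_keep),
        )
    arr = np.asarray(obj)
    if not 2 <= n_keep <= arr.shape[-1]:
        raise ValueError(f"n_keep must be in [2, {arr.shape[-1]}], got {n_keep}")
    return arr[..., :n_keep]


def estimate_fat_t2(
    fat_signals: np.ndarray,
    seq: SequenceParams,
    profile: SliceProfileTable,
    t2_search: np.ndarray | None = None,
    b1_search: np.ndarray | None = None,
    fat_t1: float = FAT_T1_MS,
) -> float:
    """Estimate the fat compartment T2 from subcutaneous-fat echo trains.

    Each signal is matched (by the same cosine-similarity metric used for
    voxel fitting) against single-compartment EPG trains with T1 = 365 ms
    over a (T2, B1) search grid; the median of the per-signal best T2
    values is returned. Intended for a pure-fat ROI, mirroring how a
    fixed fat T2 (default 151 ms) is calibrated from data.
    """
    fat_signals = np.atleast_2d(np.asarray(fat_signals, float))
    if fat_signals.size == 0 or fat_signals.shape[0] == 0:
        raise ValueError("fat_signals must contain at least one echo train")
    if fat_signals.shape[1] != seq.n_echoes:
        raise ValueError("fat_signals echo count must match the sequence")
    if t2_search is None:
        t2_search = np.linspace(80.0, 300.0, 111)
    if b1_search is None:
        b1_search = np.linspace(0.4, 1.4, 20)

    trains = compartment_train_grid(t2_search, fat_t1, seq, profile, b1_search)
    dict_matrix = _normalize_columns(trains.reshape(-1, seq.n_echoes).T)
    norms = np.linalg.norm(fat_signals, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    corr = (fat_signals / norms) @ dict_matrix
    best = np.argmax(corr, axis=1)
    t2_hat = np.asarray(t2_search, float)[best // len(np.atleast_1d(b1_search))]
    return float(np.median(t2_hat))
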