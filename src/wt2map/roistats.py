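"""ROI-level quality indicators for parameter maps.

Summaries are computed per (subject, ROI) row — voxel mean and sample SD
of wT2 and fat fraction — and aggregated with nested, unweighted means:
voxels -> ROI, ROIs -> subject, subjects -> population. On top of the
per-ROI table the module derives:

* ``err_ff`` — population-mean difference (percentage points) between
  the fat fraction estimated from the spin-echo fit and the one from the
  independent water-fat acquisition (the reference direction: positive
  means the spin-echo estimate is higher);
* ``pooled_sd`` — sqrt of the mean squared within-ROI SD, the small-scale
  (noise/tissue-inhomogeneity) variability of the map;
* ``intrasubject_sd`` — sqrt of the mean (across subjects) squared SD of
  ROI means within a subject, the large-scale spatial variability, e.g.
  from field inhomogeneity;
* ``group_mean`` — per-group mean and SD of subject-level means.

Sample SDs use the n-1 denominator throughout; NaN voxels (out of mask)
are excluded everywhere.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["roi_summary", "err_ff", "pooled_sd", "intrasubject_sd", "group_mean"]

_FIELDS = {"wt2": ("mean_wt2", "sd_wt2"), "ff": ("mean_ff", "sd_ff")}


def roi_summary(maps, labels: np.ndarray, subject: str) -> pd.DataFrame:
    """Per-ROI voxel statistics of the wT2 and FF maps.

    ``labels`` is an integer image sharing the map geometry; label 0 is
    background. Labels whose voxels are all NaN are dropped with a
    warning. Returns a tidy table with one row per ROI.
    """
    labels = np.asarray(labels)
    wt2 = np.asarray(maps.wt2, float)
    ff = np.asarray(maps.ff, float)
    if labels.shape != wt2.shape:
        raise ValueError(f"label shape {labels.shape} does not match map shape {wt2.shape}")

    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sel = labels == lab
        w = wt2[sel]
        f = ff[sel]
        valid = np.isfinite(w)
        if not valid.any():
            warnings.warn(f"ROI {lab}: no valid voxels, row dropped")
            continue
        w, f = w[valid], f[valid]
        ddof = 1 if w.size > 1 else 0
        rows.append(
            {
                "subject": subject,
                "roi": int(lab),
                "n_voxels": int(w.size),
                "mean_wt2": float(np.mean(w)),
                "sd_wt2": float(np.std(w, ddof=ddof)),
                "mean_ff": float(np.nanmean(f)),
                "sd_ff": float(np.nanstd(f, ddof=ddof)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["subject", "roi", "n_voxels", "mean_wt2", "sd_wt2", "mean_ff", "sd_ff"],
    )


def _population_mean(table: pd.DataFrame, column: str) -> float:
    """Unweighted nested mean: ROIs -> subject means -> population mean."""
    return float(table.groupby("subject")[column].mean().mean())


def err_ff(table_mese: pd.DataFrame, table_mege: pd.DataFrame) -> float:
    """Population-mean FF difference (spin-echo minus reference), in
    percentage points.

    Both tables must contain exactly matching (subject, roi) rows; the
    nested means are computed independently on each table before the
    difference, so ROI-count differences across subjects do not bias the
    result.
    """
    keys_a = set(map(tuple, table_mese[["subject", "roi"]].itertuples(index=False)))
    keys_b = set(map(tuple, table_mege[["subject", "roi"]].itertuples(index=False)))
    if keys_a != keys_b:
        missing = sorted(keys_a ^ keys_b)
        raise ValueError(f"unmatched (subject, roi) rows: {missing}")
    return (
        _population_mean(table_mese, "mean_ff") - _population_mean(table_mege, "mean_ff")
    ) * 100.0


def pooled_sd(table: pd.DataFrame, field: str = "wt2") -> float:
    """sqrt of the population mean of squared within-ROI SDs.

    The mean of squared SDs is nested (ROIs -> subject -> population,
    unweighted), so it equals the common SD when all ROI SDs agree.
    """
    if len(table) == 0:
        raise ValueError("table must contain at least one ROI row")
    sd_col = _FIELDS[field][1]
    sq = table.assign(_sq=table[sd_col] ** 2)
    return float(np.sqrt(sq.groupby("subject")["_sq"].mean().mean()))


def intrasubject_sd(table: pd.DataFrame, field: str = "wt2") -> float:
    """sqrt of the mean (across subjects) squared SD of a subject's ROI means.

    Subjects with fewer than two ROIs carry no information about
    across-ROI variability; they are excluded with a warning.
    """
    mean_col = _FIELDS[field][0]
    per_subject = []
    for subject, sub in table.groupby("subject"):
        if len(sub) < 2:
            warnings.warn(f"subject {subject!r} has < 2 ROIs; excluded from intrasubject SD")
            continue
        per_subject.append(np.std(sub[mean_col].to_numpy(), ddof=1) ** 2)
    if not per_subject:
        raise ValueError("no subject has >= 2 ROIs")
    return float(np.sqrt(np.mean(per_subject)))


def group_mean(table: pd.DataFrame, groups: dict[str, str], field: str = "wt2") -> pd.DataFrame:
    """Group-level mean and SD of subject means (one row per group).

    ``groups`` maps each subject to a group label. Groups with a single
    subject report SD = NaN.
    """
    mean_col = _FIELDS[field][0]
    subj_means = table.groupby("subject")[mean_col].mean()
    missing = [s for s in subj_means.index if s not in groups]
    if missing:
        raise ValueError(f"subjects without a group assignment: {missing}")
    frame = pd.DataFrame({"value": subj_means, "group": [groups[s] for s in subj_means.index]})
    seen_groups = set(groups.values())
    empty = seen_groups - set(frame["group"])
    if empty:
        raise ValueError(f"groups with no subjects: {sorted(empty)}")
    out = frame.groupby("group")["value"].agg(
        mean="mean", sd=lambda v: np.std(v, ddof=1) if len(v) > 1 else np.nan, n_subjects="size"
    )
    return out.reset_index()
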