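"""Windowed copy-number profiles from per-window read counts.

Desk-scale emulation of read-depth CNV calling on fixed windows (10 kb by
default): windows below 85% mappability are excluded; expected depth is a
degree-3 polynomial of GC content fitted on windows with GC in [0.30, 0.45];
the depth ratio (median-rescaled to 1.0) times the sample's baseline ploidy
gives the normalized copy number, and rounding it against the ploidy yields
gain/neutral/loss status.  Simple run-merging with a minimum segment length
replaces full segmentation, which suffices for comparing shared CNVs across
samples.

All operations take and return pandas DataFrames with the window-table
columns (chrom, start, end, count, gc, mappability) plus the columns they
add (excluded, ratio, cn, status).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ValidationError

__all__ = [
    "filter_windows",
    "gc_normalize",
    "call_status",
    "segment_status",
    "windows_with_segment_status",
    "shared_cnv",
    "cnv_pipeline",
]

MIN_MAPPABILITY = 0.85
GC_FIT_MIN = 0.30
GC_FIT_MAX = 0.45
GC_FIT_DEGREE = 3
MIN_SEGMENT_WINDOWS = 5


def filter_windows(
    windows: pd.DataFrame, min_mappability: float = MIN_MAPPABILITY
) -> pd.DataFrame:
    """Flag windows below the mappability threshold as excluded.

    The threshold is inclusive: a window at exactly ``min_mappability`` is
    retained.  Excluded windows get ``status='excluded'`` and are omitted
    from normalization and calling.
    """
    out = windows.copy()
    out["excluded"] = out["mappability"] < min_mappability
    out["status"] = np.where(out["excluded"], "excluded", "")
    return out


def gc_normalize(
    windows: pd.DataFrame,
    gc_min: float = GC_FIT_MIN,
    gc_max: float = GC_FIT_MAX,
    degree: int = GC_FIT_DEGREE,
) -> pd.DataFrame:
    """Fill the ``ratio`` column: observed count over GC-expected count.

    The expected count is a polynomial in GC fitted only on retained windows
    with GC inside [gc_min, gc_max]; windows outside that range still receive
    ratios from the fitted curve.  Ratios are rescaled so their median over
    retained windows is 1.0 (the dominant copy-number state defines the
    baseline).  The polynomial degree drops automatically when the fit
    windows carry fewer distinct GC values than degree + 1.
    """
    out = windows.copy()
    if "excluded" not in out.columns:
        out = filter_windows(out)
    retained = ~out["excluded"]
    if not retained.any():
        raise ValidationError(
            "all windows excluded by the mappability filter; nothing to normalize"
        )
    fit_mask = retained & (out["gc"] >= gc_min) & (out["gc"] <= gc_max)
    gc_fit = out.loc[fit_mask, "gc"].to_numpy(dtype=float)
    count_fit = out.loc[fit_mask, "count"].to_numpy(dtype=float)
    n_unique = len(np.unique(gc_fit))
    if n_unique == 0:
        raise ValidationError(
            f"no retained windows with GC in [{gc_min}, {gc_max}] to fit"
        )
    eff_degree = min(degree, n_unique - 1)
    if len(gc_fit) < eff_degree + 1:
        raise ValidationError(
            "fewer fit windows than polynomial degrees of freedom"
        )
    coeffs = np.polyfit(gc_fit, count_fit, eff_degree)
    expected = np.polyval(coeffs, out["gc"].to_numpy(dtype=float))
    if np.any(expected[retained.to_numpy()] <= 0):
        raise ValidationError("GC fit predicts non-positive expected counts")
    ratio = out["count"].to_numpy(dtype=float) / expected
    med = np.median(ratio[retained.to_numpy()])
    if med <= 0:
        raise ValidationError("median ratio is non-positive; cannot rescale")
    out["ratio"] = ratio / med
    out.loc[out["excluded"], "ratio"] = np.nan
    return out


def call_status(windows: pd.DataFrame, ploidy: int) -> pd.DataFrame:
    """Fill ``cn`` (= ratio x ploidy) and per-window status.

    Status compares the rounded normalized copy number with the baseline
    ploidy: gain above, loss below, neutral at.  Half-integers round half-up
    so cn = ploidy + 0.5 is a gain.
    """
    if ploidy is None or ploidy < 1:
        raise ValidationError("a baseline ploidy >= 1 is required")
    if "ratio" not in windows.columns:
        raise ValidationError("ratios must be filled (run gc_normalize first)")
    out = windows.copy()
    out["cn"] = out["ratio"] * ploidy
    rounded = np.floor(out["cn"].to_numpy(dtype=float) + 0.5)
    status = np.where(
        rounded > ploidy, "gain", np.where(rounded < ploidy, "loss", "neutral")
    )
    out["status"] = status
    if "excluded" in out.columns:
        out.loc[out["excluded"], "status"] = "excluded"
        out.loc[out["excluded"], "cn"] = np.nan
    return out


def segment_status(
    windows: pd.DataFrame, min_windows: int = MIN_SEGMENT_WINDOWS
) -> pd.DataFrame:
    """Merge consecutive same-status windows into segments.

    Non-neutral runs shorter than ``min_windows`` are relabelled neutral and
    re-merged with their neighbors.  Excluded windows break runs but form no
    segments of their own.  Input must be coordinate-sorted within each
    chromosome.  Returns a DataFrame (chrom, start, end, status, n_windows).
    """
    out = windows if "status" in windows.columns else None
    if out is None:
        raise ValidationError("windows must carry a status column")
    for chrom, group in windows.groupby("chrom", sort=False):
        starts = group["start"].to_numpy()
        if np.any(np.diff(starts) <= 0):
            raise ValidationError(f"windows on {chrom} are not coordinate-sorted")

    runs: list[dict] = []
    for chrom, group in windows.groupby("chrom", sort=False):
        current = None
        for _, row in group.iterrows():
            status = row["status"]
            if status == "excluded":
                current = None
                continue
            if current is not None and current["status"] == status:
                current["end"] = row["end"]
                current["n_windows"] += 1
            else:
                current = {
                    "chrom": chrom,
                    "start": row["start"],
                    "end": row["end"],
                    "status": status,
                    "n_windows": 1,
                }
                runs.append(current)

    for run in runs:
        if run["status"] != "neutral" and run["n_windows"] < min_windows:
            run["status"] = "neutral"

    merged: list[dict] = []
    for run in runs:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev["chrom"] == run["chrom"]
            and prev["status"] == run["status"]
            and prev["end"] == run["start"]
        ):
            prev["end"] = run["end"]
            prev["n_windows"] += run["n_windows"]
        else:
            merged.append(dict(run))
    return pd.DataFrame(
        merged, columns=["chrom", "start", "end", "status", "n_windows"]
    )


def windows_with_segment_status(
    windows: pd.DataFrame, min_windows: int = MIN_SEGMENT_WINDOWS
) -> pd.DataFrame:
    """Window table with per-window status replaced by its segment's status
    (isolated noise windows become neutral); excluded windows keep their
    flag."""
    segments = segment_status(windows, min_windows=min_windows)
    out = windows.copy()
    for _, seg in segments.iterrows():
        mask = (
            (out["chrom"] == seg["chrom"])
            & (out["start"] >= seg["start"])
            & (out["end"] <= seg["end"])
            & (out["status"] != "excluded")
        )
        out.loc[mask, "status"] = seg["status"]
    return out


def shared_cnv(
    profiles: Mapping[str, pd.DataFrame], sample_set: Iterable[str]
) -> pd.DataFrame:
    """Intervals of exclusively shared CNV status.

    A window qualifies when every sample in ``sample_set`` has the same
    non-neutral status there and every sample outside the set is neutral.
    All profiles must share an identical window grid.  Consecutive
    qualifying windows merge into intervals; returns (chrom, start, end,
    status).
    """
    inside = sorted(set(sample_set))
    if not inside:
        raise ValidationError("sample_set must be non-empty")
    unknown = [s for s in inside if s not in profiles]
    if unknown:
        raise ValidationError(f"samples not in profiles: {unknown}")
    outside = sorted(set(profiles) - set(inside))

    names = list(profiles)
    grid = profiles[names[0]][["chrom", "start", "end"]].reset_index(drop=True)
    for name in names[1:]:
        other = profiles[name][["chrom", "start", "end"]].reset_index(drop=True)
        if not grid.equals(other):
            raise ValidationError(f"window grid of {name!r} differs")

    status = {
        name: profiles[name]["status"].to_numpy() for name in names
    }
    n = len(grid)
    qualifies = np.zeros(n, dtype=bool)
    shared_status = np.empty(n, dtype=object)
    ref = status[inside[0]]
    inside_same = np.ones(n, dtype=bool)
    for name in inside[1:]:
        inside_same &= status[name] == ref
    eligible = inside_same & (ref != "neutral") & (ref != "excluded")
    outside_neutral = np.ones(n, dtype=bool)
    for name in outside:
        outside_neutral &= status[name] == "neutral"
    qualifies = eligible & outside_neutral
    shared_status[qualifies] = ref[qualifies]

    intervals: list[dict] = []
    current = None
    for i in range(n):
        if not qualifies[i]:
            current = None
            continue
        row = grid.iloc[i]
        if (
            current is not None
            and current["chrom"] == row["chrom"]
            and current["end"] == row["start"]
            and current["status"] == shared_status[i]
        ):
            current["end"] = row["end"]
        else:
            current = {
                "chrom": row["chrom"],
                "start": row["start"],
                "end": row["end"],
                "status": shared_status[i],
            }
            intervals.append(current)
    return pd.DataFrame(intervals, columns=["chrom", "start", "end", "status"])


def cnv_pipeline(
    windows: pd.DataFrame,
    ploidy: int,
    min_mappability: float = MIN_MAPPABILITY,
    gc_min: float = GC_FIT_MIN,
    gc_max: float = GC_FIT_MAX,
    min_segment_windows: int = MIN_SEGMENT_WINDOWS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """filter -> GC-normalize -> call -> segment; returns (windows, segments).

    Window statuses in the returned table are segment-smoothed, so isolated
    single-window blips do not survive as calls.
    """
    out = filter_windows(windows, min_mappability=min_mappability)
    out = gc_normalize(out, gc_min=gc_min, gc_max=gc_max)
    out = call_status(out, ploidy=ploidy)
    segments = segment_status(out, min_windows=min_segment_windows)
    out = windows_with_segment_status(out, min_windows=min_segment_windows)
    return out, segments
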