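"""Unmasked-base windows over a masked assembly.

Windows count only unmasked, non-gap nucleotides: a 1-kub window holds
exactly ``unit`` (default 1000) unmasked bases and its genomic span includes
any interposed masked ones, so spans vary in length. A window that would
cross an assembly gap is discarded and scanning restarts at the first
unmasked base after the gap; trailing partial windows are discarded.

Aggregated windows merge ``k`` (default 5) contiguous 1-kub windows and
slide by one, so successive 5-kub windows share k-1 members. Gaps break
sliding runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .masking import MaskedGenome

__all__ = [
    "build_1kub_windows",
    "build_5kub_windows",
    "masked_percentage_bin",
    "MASKED_BINS",
    "write_windows_bed",
]

MASKED_BINS = ("<20", "20-40", "40-60", "60-80", ">80")

W1_COLUMNS = ["chrom", "start", "end", "index", "run"]


def build_1kub_windows(mg: MaskedGenome, unit: int = 1000) -> pd.DataFrame:
    """Build non-overlapping windows of exactly ``unit`` unmasked bases.

    Returns a DataFrame with columns chrom, start, end, index (per-chromosome
    ordinal), run (gap-delimited run ordinal). Span convention: a window's
    span starts at the previous window's span end within a run, and at the
    first unmasked base at a run start.
    """
    if unit < 1:
        raise ValueError("unit must be >= 1")
    frames = []
    for chrom in mg.chroms:
        n = mg.chrom_size(chrom)
        masked = mg.mask_bool(chrom)
        gap_iv = mg.gap_intervals(chrom)
        gap = np.zeros(n, dtype=bool)
        for s, e in gap_iv:
            gap[s:e] = True
        unmasked_pos = np.flatnonzero(~masked & ~gap)
        if len(unmasked_pos) < unit:
            continue
        # run id: number of gaps starting at or before this position
        seg = np.searchsorted(gap_iv[:, 0], unmasked_pos, side="right") if len(gap_iv) else np.zeros(len(unmasked_pos), dtype=np.int64)
        starts_all, ends_all, runs_all = [], [], []
        run_ord = 0
        bounds = np.flatnonzero(np.diff(seg)) + 1
        for u in np.split(unmasked_pos, bounds):
            m = len(u) // unit
            if m == 0:
                if len(u):
                    run_ord += 1
                continue
            ends = u[np.arange(1, m + 1) * unit - 1] + 1
            starts = np.empty(m, dtype=np.int64)
            starts[0] = u[0]
            starts[1:] = ends[:-1]
            starts_all.append(starts)
            ends_all.append(ends)
            runs_all.append(np.full(m, run_ord, dtype=np.int64))
            run_ord += 1
        if not starts_all:
            continue
        starts = np.concatenate(starts_all)
        ends = np.concatenate(ends_all)
        runs = np.concatenate(runs_all)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "index": np.arange(len(starts)),
                    "run": runs,
                }
            )
        )
    if not frames:
        out = pd.DataFrame(columns=W1_COLUMNS)
    else:
        out = pd.concat(frames, ignore_index=True)
    out.attrs["unit"] = unit
    return out


def build_5kub_windows(w1: pd.DataFrame, k: int = 5, unit: int | None = None) -> pd.DataFrame:
    """Merge every run of ``k`` gap-uninterrupted 1-kub windows, sliding by one.

    ``unit`` (unmasked bases per member window) is inferred from the first
    window if not given; it is needed to compute the masked percentage of the
    span: masked_pct = 100 * (span - k*unit) / span.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(w1) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "first", "run", "masked_pct"]
        )
    frames = []
    for (chrom, run), grp in w1.groupby(["chrom", "run"], sort=False):
        m = len(grp)
        if m < k:
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        idx = grp["index"].to_numpy()
        n5 = m - k + 1
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts[:n5],
                    "end": ends[k - 1:],
                    "first": idx[:n5],
                    "run": run,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "first", "run", "masked_pct"]
        )
    w5 = pd.concat(frames, ignore_index=True)
    if unit is None:
        unit = w1.attrs.get("unit")
    if unit is None:
        # fall back: the smallest observed span cannot exceed the unit
        unit = int((w1["end"] - w1["start"]).min())
    span = (w5["end"] - w5["start"]).to_numpy()
    w5["masked_pct"] = 100.0 * (span - k * unit) / span
    w5.attrs["unit"] = unit
    w5.attrs["k"] = k
    return w5


def masked_percentage_bin(masked_pct) -> np.ndarray:
    """Assign masked-percentage values to the five reporting bins.

    ``<20`` is strict; interior bins are closed-open ([20,40) etc.); ``>80``
    is strict, so exactly 80 falls in ``60-80``.
    """
    pct = np.atleast_1d(np.asarray(masked_pct, dtype=float))
    bins = np.empty(pct.shape, dtype=object)
    bins[pct < 20] = "<20"
    bins[(pct >= 20) & (pct < 40)] = "20-40"
    bins[(pct >= 40) & (pct < 60)] = "40-60"
    bins[(pct >= 60) & (pct <= 80)] = "60-80"
    bins[pct > 80] = ">80"
    if np.isscalar(masked_pct) or np.ndim(masked_pct) == 0:
        return bins[0]
    return bins


def write_windows_bed(windows: pd.DataFrame, path) -> None:
    """Write a window table (1-kub or 5-kub) as BED4+ with extra columns."""
    cols = [c for c in ["chrom", "start", "end", "index", "first", "depth1",
                        "depth", "masked_pct", "label"] if c in windows.columns]
    windows[cols].to_csv(path, sep="\t", index=False, header=True, float_format="%.3f")
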